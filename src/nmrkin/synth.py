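"""Seeded generators emulating every input the analysis pipeline consumes.

Raw spectrometer output and molecular-dynamics trajectories are large and
not redistributable, so each input is emulated by a generator with planted
ground truth: two-field CPMG dispersion curves from a known exchange
network, relaxation tables for isotropic tumbling at a known tau_c,
continuous-time Markov jump trajectories from a known rate matrix,
bond-vector wobble with a known S^2, and toy structure pairs with a known
loop displacement.  ``make_study_bundle`` ties these together into a
two-arm study that mirrors the headline contrast of loop-gated ligand
binding: a ligand-free ("apo") arm whose loop residues exchange between a
rare binding-competent conformation and two binding-incompetent ones, and a
ligand-bound arm in which that exchange is quenched.

Every generator is a pure function of (config, seed); the single study
seed fans out to per-generator substreams so parts of a study can be
regenerated independently.
"""

from __future__ import annotations

import dataclasses
import json
import math
import zlib
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import cpmg, msm, relax, structure
from .cpmg import DispersionCurve, KineticNetwork
from .relax import FieldContext, MotionParams, RelaxationTable
from .structure import Structure

DEFAULT_SEED = 20250101


def substream(seed: int, tag: str) -> np.random.Generator:
    """Derive a named, reproducible child RNG from the study seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(tag.encode())]))


# ---------------------------------------------------------------------------
# planted kinetic network (three states: open / partially closed / closed)

STATE_NAMES = ("open", "partial", "closed")


def default_network(r2_by_field: Mapping[float, float] | None = None) -> KineticNetwork:
    """Three-state loop-exchange network used as the planted apo truth.

    A rare binding-competent "open" state (3%) exchanges with a
    "partially closed" state, which in turn exchanges with the dominant
    fully "closed" state (chain topology); populations (3%, 40%, 57%) and
    inter-state rates in the 10^1-10^3 rad/s range, satisfying detailed
    balance.
    """
    pops = np.array([0.03, 0.40, 0.57])
    k = np.zeros((3, 3))
    # open <-> partial: total exchange rate 800 rad/s split by populations
    k[0, 1] = 800.0 * pops[1] / (pops[0] + pops[1])
    k[1, 0] = 800.0 * pops[0] / (pops[0] + pops[1])
    # partial <-> closed: total exchange rate 700 rad/s
    k[1, 2] = 700.0 * pops[2] / (pops[1] + pops[2])
    k[2, 1] = 700.0 * pops[1] / (pops[1] + pops[2])
    np.fill_diagonal(k, -k.sum(axis=1))
    return KineticNetwork(k, pops, np.zeros(3),
                          dict(r2_by_field or {600.0: 14.0, 950.0: 18.0}),
                          names=STATE_NAMES)


#: planted per-residue 15N shift offsets (ppm) of the three states, chosen
#: so the rare open state is well separated while the two closed forms
#: differ only slightly, as for a loop that is either displaced or packed
LOOP_OFFSETS_PPM: dict[int, tuple[float, float, float]] = {
    96: (3.0, 0.2, 0.0),
    98: (2.4, 0.0, 0.35),
    106: (-2.6, -0.3, 0.0),
    110: (1.8, 0.45, 0.0),
}

DEFAULT_GRID = (25.0, 50.0, 75.0, 100.0, 150.0, 200.0, 300.0,
                400.0, 500.0, 600.0, 800.0, 1000.0)


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic two-arm study."""

    seed: int = DEFAULT_SEED
    n_residues: int = 165
    fields_mhz: tuple[float, ...] = (600.0, 950.0)
    nu_grid: tuple[float, ...] = DEFAULT_GRID
    noise_sigma: float = 0.3          # s^-1, dispersion points
    trelax: float = 0.040             # s
    tau_c_apo_ns: float = 13.24
    tau_c_bound_ns: float = 13.06
    relax_noise_frac: float = 0.02
    dt: float = 2.0e-6                # s per trajectory frame
    n_frames_incompetent: int = 200_000
    n_frames_competent: int = 50_000
    msm_lag: int = 10                 # frames
    micro_split_rate: float = 1.0e4   # fast intra-macrostate micro exchange, 1/s
    loop_displacement: float = 8.0    # Angstrom, toy structure pair
    toy_loop: tuple[int, int] = (95, 105)
    s2_rigid: float = 0.85


# ---------------------------------------------------------------------------
# generators

def simulate_ctmc(K: np.ndarray, dt: float, n_steps: int, seed: int,
                  start: int | None = None) -> np.ndarray:
    """Discretized continuous-time Markov jump trajectory.

    Exact Gillespie sampling (exponential holding times, jump probabilities
    proportional to the off-diagonal rates), then stroboscopic observation
    every ``dt``.  Requires dt * max|K_ii| < 0.1 so the discretization does
    not alias jumps.
    """
    k = np.asarray(K, dtype=float)
    n = k.shape[0]
    exit_rates = -np.diag(k)
    if dt * exit_rates.max() >= 0.1:
        raise ValueError("dt * max|K_ii| must be < 0.1")
    if np.any(exit_rates == 0) and n > 1:
        import warnings
        warnings.warn("absorbing state present; trajectory may not be reversible")
    rng = np.random.default_rng(seed)
    pi = msm.stationary_from_generator(k) if start is None else None
    state = int(rng.choice(n, p=np.clip(pi, 0, None) / np.clip(pi, 0, None).sum()) \
        if start is None else start)
    labels = np.empty(n_steps, dtype=int)
    t_end = n_steps * dt
    t = 0.0
    frame = 0
    while frame < n_steps:
        rate = exit_rates[state]
        t_next = t + (rng.exponential(1.0 / rate) if rate > 0 else np.inf)
        # fill frames observed before the jump
        last = min(n_steps, int(math.floor(t_next / dt - 1e-12)) + 1)
        if last > frame:
            labels[frame:last] = state
            frame = last
        if t_next >= t_end:
            break
        probs = np.clip(k[state].copy(), 0, None)
        probs[state] = 0.0
        probs /= probs.sum()
        state = int(rng.choice(n, p=probs))
        t = t_next
    return labels


def simulate_dispersion(network: KineticNetwork, fields_mhz: Sequence[float],
                        grid: Sequence[float], trelax: float, sigma: float,
                        seed: int, residue: int = 0,
                        nucleus: str = "N15") -> list[DispersionCurve]:
    """Bloch-McConnell forward curves plus i.i.d. Gaussian noise of width
    sigma; the per-point sigma is recorded on the curve."""
    rng = np.random.default_rng(seed)
    out = []
    for mhz in fields_mhz:
        field = FieldContext(mhz)
        nu = np.asarray(grid, dtype=float)
        clean = np.asarray(cpmg.bm_r2eff(network, field, nu, trelax, nucleus))
        noisy = clean + (rng.normal(0.0, sigma, size=nu.shape) if sigma > 0 else 0.0)
        out.append(DispersionCurve(residue, field, nu, noisy,
                                   np.full_like(nu, float(sigma)),
                                   nucleus=nucleus, trelax=trelax))
    return out


def simulate_relaxation_table(tau_c_ns: float, field_mhz: float,
                              noise_frac: float = 0.0, seed: int = DEFAULT_SEED,
                              n_residues: int = 150,
                              s2_map: Mapping[int, tuple[float, float]] | None = None
                              ) -> RelaxationTable:
    """Relaxation table for isotropic tumbling at a planted tau_c.

    ``s2_map`` optionally assigns (S2, tau_e_ns) per residue; unlisted
    residues are rigid (S2=1, tau_e=0), for which the R2/R1 ratio inverts
    exactly to the planted tau_c.  Noise is multiplicative Gaussian with
    fraction ``noise_frac``, which is also recorded as the uncertainty.
    """
    rng = np.random.default_rng(seed)
    field = FieldContext(field_mhz)
    rows = []
    for res in range(1, n_residues + 1):
        s2, tau_e_ns = (s2_map or {}).get(res, (1.0, 0.0))
        motion = MotionParams(tau_c_ns * 1e-9, s2=s2, tau_e=tau_e_ns * 1e-9)
        r1, r2, noe = relax.predict_rates(motion, field)
        e1, e2, en = noise_frac * r1, noise_frac * r2, noise_frac * max(abs(noe), 0.1)
        if noise_frac > 0:
            r1 += rng.normal(0.0, e1)
            r2 += rng.normal(0.0, e2)
            noe += rng.normal(0.0, en)
        rows.append({"residue": res, "R1": r1, "R1_err": e1, "R2": r2,
                     "R2_err": e2, "hetNOE": min(noe, 1.2), "hetNOE_err": en})
    return RelaxationTable(pd.DataFrame(rows), field)


def cone_s2(theta_deg: float) -> float:
    """Wobble-in-a-cone order parameter (cos t (1 + cos t) / 2)^2."""
    c = math.cos(math.radians(theta_deg))
    return (c * (1.0 + c) / 2.0) ** 2


def simulate_nh_wobble(n: int, seed: int, mode: str = "cone",
                       theta_deg: float | None = None,
                       target_s2: float | None = None) -> np.ndarray:
    """Bond-vector series with a planted order parameter.

    mode "cone": uniform directions within a cone of half-angle theta about
    z (S2 given by the closed cone formula); mode "isotropic": uniform on
    the sphere (S2 -> 0).  ``target_s2`` inverts the cone formula.
    """
    rng = np.random.default_rng(seed)
    if mode == "isotropic":
        cos_min = -1.0
    elif mode == "cone":
        if theta_deg is None:
            if target_s2 is None:
                raise ValueError("cone mode needs theta_deg or target_s2")
            from scipy.optimize import brentq
            theta_deg = brentq(lambda t: cone_s2(t) - target_s2, 1e-6, 180.0 - 1e-6)
        cos_min = math.cos(math.radians(theta_deg))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    cos_t = rng.uniform(cos_min, 1.0, size=n)
    phi = rng.uniform(0.0, 2.0 * math.pi, size=n)
    sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, None))
    return np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])


def make_toy_structure_pair(n_residues: int = 160, loop: tuple[int, int] = (95, 105),
                            displacement: float = 8.0, seed: int = DEFAULT_SEED
                            ) -> tuple[Structure, Structure]:
    """Idealized C-alpha trace pair with a planted rigid loop displacement.

    Both structures share the same (seeded) backbone trace; in the second,
    residues within ``loop`` are shifted by one random vector of norm
    ``displacement``, so after superposing on the unchanged residues the
    maximum per-residue deviation equals the planted displacement.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(n_residues, dtype=float)
    # smooth curved trace with ~3.8 A C-alpha spacing plus small jitter
    xyz = np.column_stack([
        10.0 * np.cos(t * 0.35), 10.0 * np.sin(t * 0.35), t * 2.9,
    ]) + rng.normal(0.0, 0.15, size=(n_residues, 3))

    def build(coords: np.ndarray) -> Structure:
        n = len(coords)
        return Structure(
            chain=np.array(["A"] * n), res_id=np.arange(1, n + 1),
            res_name=np.array(["ALA"] * n), atom_name=np.array(["CA"] * n),
            element=np.array(["C"] * n), altloc=np.array([""] * n),
            occupancy=np.ones(n), xyz=coords.copy())

    ref = build(xyz)
    shift = rng.normal(size=3)
    shift *= displacement / np.linalg.norm(shift)
    moved = xyz.copy()
    lo, hi = loop
    mask = (ref.res_id >= lo) & (ref.res_id <= hi)
    moved[mask] += shift
    return ref, build(moved)


# ---------------------------------------------------------------------------
# micro-level simulation blocks

def _micro_network(cfg: GeneratorConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Expand the 3-macrostate truth to 6 microstates (2 per macro).

    Each macrostate splits into two microstates connected by fast exchange
    (``micro_split_rate``); macro-macro rates are distributed evenly over
    the micro pairs so the crisp coarse-grained rates reproduce the planted
    macro rates.  Returns (K_micro, macro_assignment, pi_micro).
    """
    net = default_network()
    km = net.K
    n_macro = 3
    split = cfg.micro_split_rate
    n = 2 * n_macro
    k = np.zeros((n, n))
    macro = np.repeat(np.arange(n_macro), 2)
    for a in range(n_macro):
        i0, i1 = 2 * a, 2 * a + 1
        k[i0, i1] = k[i1, i0] = split
        for b in range(n_macro):
            if a == b or km[a, b] <= 0:
                continue
            for i in (2 * a, 2 * a + 1):
                for j in (2 * b, 2 * b + 1):
                    k[i, j] = km[a, b] / 2.0
    np.fill_diagonal(k, 0.0)
    np.fill_diagonal(k, -k.sum(axis=1))
    pi = np.repeat(net.populations / 2.0, 2)
    return k, macro, pi


def simulation_blocks(cfg: GeneratorConfig
                      ) -> tuple[list[msm.MSM], list[np.ndarray], list[np.ndarray], dict]:
    """Disconnected simulation blocks emulating basin-limited sampling.

    The competent<->incompetent transitions are deleted (never observed in
    the trajectories), leaving one block holding the open state and one
    holding the two closed states; each block is sampled as a microstate
    CTMC and estimated as a reversible MSM.
    """
    k_micro, macro, _ = _micro_network(cfg)
    open_idx = np.where(macro == 0)[0]
    closed_idx = np.where(macro != 0)[0]
    blocks, macros, dtrajs = [], [], []
    for name, idx, n_frames in (
            ("competent", open_idx, cfg.n_frames_competent),
            ("incompetent", closed_idx, cfg.n_frames_incompetent)):
        kb = k_micro[np.ix_(idx, idx)].copy()
        np.fill_diagonal(kb, 0.0)
        np.fill_diagonal(kb, -kb.sum(axis=1))
        rng_seed = substream(cfg.seed, f"ctmc-{name}").integers(0, 2**31 - 1)
        dtraj = simulate_ctmc(kb, cfg.dt, n_frames, int(rng_seed))
        dtrajs.append(dtraj)
        blocks.append(msm.estimate_msm([dtraj], lag=cfg.msm_lag, dt=cfg.dt))
        macros.append(macro[idx])
    manifest = {"micro_rate_matrix": k_micro.tolist(),
                "macro_assignment": macro.tolist(),
                "dt_s": cfg.dt, "msm_lag_frames": cfg.msm_lag,
                "block_names": ["competent", "incompetent"]}
    return blocks, macros, dtrajs, manifest


# ---------------------------------------------------------------------------
# study bundle

@dataclass
class SyntheticStudy:
    """Complete synthetic two-arm study with machine-readable planted truth."""

    config: GeneratorConfig
    relaxation: dict          # arm -> {mhz: RelaxationTable}
    dispersion: dict          # arm -> {residue: [DispersionCurve, ...]}
    blocks: list              # [MSM, ...] for the apo arm
    block_macros: list        # macro assignment arrays per block
    dtrajs: list              # raw discrete trajectories per block
    toy_structures: tuple     # (reference, loop-shifted)
    manifest: dict            # every planted truth

    def curves_for(self, arm: str, residue: int) -> list[DispersionCurve]:
        return self.dispersion[arm][residue]


def make_study_bundle(cfg: GeneratorConfig | None = None) -> SyntheticStudy:
    """Generate the full two-arm study from one seed.

    The apo arm carries the planted three-state loop-exchange network at
    the loop residues; the bound arm has the same residues with a flat,
    single-state model (exchange quenched).  Both arms share tumbling
    times near 13 ns.
    """
    cfg = cfg or GeneratorConfig()
    net = default_network()

    relaxation = {}
    for arm, tau in (("apo", cfg.tau_c_apo_ns), ("bound", cfg.tau_c_bound_ns)):
        relaxation[arm] = {}
        for mhz in cfg.fields_mhz:
            seed = int(substream(cfg.seed, f"relax-{arm}-{mhz}").integers(0, 2**31 - 1))
            relaxation[arm][mhz] = simulate_relaxation_table(
                tau, mhz, cfg.relax_noise_frac, seed, cfg.n_residues)

    dispersion: dict = {"apo": {}, "bound": {}}
    for res, offsets in LOOP_OFFSETS_PPM.items():
        apo_net = KineticNetwork(net.K, net.populations, np.array(offsets),
                                 dict(net.r2_by_field), names=net.names)
        seed = int(substream(cfg.seed, f"disp-apo-{res}").integers(0, 2**31 - 1))
        dispersion["apo"][res] = simulate_dispersion(
            apo_net, cfg.fields_mhz, cfg.nu_grid, cfg.trelax,
            cfg.noise_sigma, seed, residue=res)
        flat = KineticNetwork(np.zeros((1, 1)), np.array([1.0]), np.zeros(1),
                              dict(net.r2_by_field))
        seed = int(substream(cfg.seed, f"disp-bound-{res}").integers(0, 2**31 - 1))
        dispersion["bound"][res] = simulate_dispersion(
            flat, cfg.fields_mhz, cfg.nu_grid, cfg.trelax,
            cfg.noise_sigma, seed, residue=res)

    blocks, block_macros, dtrajs, block_manifest = simulation_blocks(cfg)
    toy = make_toy_structure_pair(
        loop=cfg.toy_loop, displacement=cfg.loop_displacement,
        seed=int(substream(cfg.seed, "toy-structures").integers(0, 2**31 - 1)))

    manifest = {
        "seed": cfg.seed,
        "network": {"states": list(STATE_NAMES),
                    "populations": net.populations.tolist(),
                    "rate_matrix_rad_s": net.K.tolist(),
                    "inter_block_edges": [[0, 1], [1, 0]],
                    "r2_by_field": {str(k): v for k, v in net.r2_by_field.items()}},
        "offsets_ppm": {str(r): list(o) for r, o in LOOP_OFFSETS_PPM.items()},
        "tau_c_ns": {"apo": cfg.tau_c_apo_ns, "bound": cfg.tau_c_bound_ns},
        "noise_sigma": cfg.noise_sigma,
        "nu_grid_hz": list(cfg.nu_grid),
        "trelax_s": cfg.trelax,
        "loop_displacement_A": cfg.loop_displacement,
        "toy_loop": list(cfg.toy_loop),
        "blocks": block_manifest,
    }
    return SyntheticStudy(cfg, relaxation, dispersion, blocks, block_macros,
                          dtrajs, toy, manifest)


def write_study(study: SyntheticStudy, out_dir: str | Path) -> Path:
    """Write a study directory: TSV tables, dtraj text, PDB pair, manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for arm, tables in study.relaxation.items():
        for mhz, table in tables.items():
            table.to_tsv(out / f"relax_{arm}_{mhz:g}.tsv")
    for arm, per_res in study.dispersion.items():
        curves = [c for clist in per_res.values() for c in clist]
        cpmg.write_dispersion_tsv(curves, out / f"dispersion_{arm}.tsv")
    for i, dtraj in enumerate(study.dtrajs):
        msm.write_dtraj(dtraj, out / f"dtraj_block{i}.txt")
    structure.write_pdb(study.toy_structures[0], out / "toy_reference.pdb")
    structure.write_pdb(study.toy_structures[1], out / "toy_shifted.pdb")
    (out / "manifest.json").write_text(json.dumps(study.manifest, indent=2))
    return out
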