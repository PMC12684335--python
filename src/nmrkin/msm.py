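"""Markov state models and experiment-augmented kinetic networks.

Estimates reversible Markov state models from discrete trajectories,
coarse-grains them to a few metastable states by a PCCA-style spectral
assignment, converts transition matrices to rate-matrix generators, and --
the central operation -- reconciles simulation kinetics with CPMG
relaxation dispersion data.  Simulations of a slowly exchanging protein
often sample the individual conformational basins well but never the
transitions between them, leaving two or more mutually disconnected state
blocks.  ``augment_with_experiment`` assembles the blocks into a single
kinetic network whose missing inter-block exchange rates are free
parameters, keeps the simulation-derived intra-block rates close to their
estimates through a log-space penalty, and minimizes the weighted misfit of
Bloch-McConnell-predicted dispersion curves to the experimental ones:

    chi2(K) + lambda * sum_intra (log k_ij - log k_ij,sim)^2

so the result is the smallest perturbation of the simulation kinetics that
agrees with the experimental dispersion data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import scipy.linalg
import scipy.optimize
import scipy.sparse.csgraph

from .cpmg import DispersionCurve, KineticNetwork, _network_A, _bm_decay, DEFAULT_TRELAX
from .relax import FieldContext

DEFAULT_SEED = 20250101


# ---------------------------------------------------------------------------
# estimation

def count_matrix(dtrajs: Sequence[np.ndarray], lag: int, n_states: int | None = None) -> np.ndarray:
    """Sliding-window transition counts at the given lag, summed over
    trajectories."""
    if lag < 1:
        raise ValueError("lag must be >= 1")
    trajs = [np.asarray(d, dtype=int) for d in dtrajs]
    if any((t < 0).any() for t in trajs):
        raise ValueError("state labels must be >= 0")
    if any(len(t) <= lag for t in trajs):
        raise ValueError("lag must be shorter than every trajectory")
    n = n_states if n_states is not None else max(int(t.max()) for t in trajs) + 1
    c = np.zeros((n, n))
    for t in trajs:
        np.add.at(c, (t[:-lag], t[lag:]), 1.0)
    return c


def largest_connected_set(counts: np.ndarray) -> np.ndarray:
    """States in the largest strongly connected component of the count graph."""
    adj = (counts > 0).astype(int)
    n_comp, labels = scipy.sparse.csgraph.connected_components(
        adj, directed=True, connection="strong")
    sizes = np.array([(counts[labels == i][:, labels == i]).sum()
                      for i in range(n_comp)])
    return np.where(labels == int(np.argmax(sizes)))[0]


@dataclass
class MSM:
    """Discrete-state, discrete-lag Markov state model."""

    transition_matrix: np.ndarray
    stationary: np.ndarray
    lag: int                     # frames
    dt: float                    # seconds per frame
    active_set: np.ndarray       # original state labels retained
    counts: np.ndarray | None = None
    reversible: bool = True

    def __post_init__(self) -> None:
        t = self.transition_matrix
        if np.abs(t.sum(axis=1) - 1.0).max() > 1e-10:
            raise ValueError("transition matrix rows must sum to 1 within 1e-10")
        if np.abs(self.stationary @ t - self.stationary).max() > 1e-8:
            raise ValueError("stationary distribution is not invariant")

    @property
    def lag_time(self) -> float:
        return self.lag * self.dt

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]


def _reversible_mle(counts: np.ndarray, tol: float = 1e-14, max_iter: int = 100000) -> np.ndarray:
    """Reversible maximum-likelihood symmetric-flux fixed point.

    Iterates x_ij <- (c_ij + c_ji) / (c_i/x_i + c_j/x_j); the update keeps x
    symmetric, so the returned transition matrix obeys detailed balance
    exactly (pi_i T_ij = x_ij / X is symmetric by construction).
    """
    c = counts
    csym = c + c.T
    ci = c.sum(axis=1)
    x = csym.copy()
    for _ in range(max_iter):
        xi = x.sum(axis=1)
        denom = ci[:, None] / xi[:, None] + ci[None, :] / xi[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            x_new = np.where(csym > 0, csym / denom, 0.0)
        delta = np.abs(x_new - x).max() / max(x.max(), 1e-300)
        x = x_new
        if delta < tol:
            break
    return x


def estimate_msm(counts_or_dtrajs, lag: int = 1, dt: float = 1.0,
                 reversible: bool = True) -> MSM:
    """Estimate an MSM from a count matrix or from discrete trajectories.

    Reversible mode restricts to the largest strongly connected set and
    solves the detailed-balance maximum-likelihood problem; non-reversible
    mode row-normalizes the counts.  Dropped states are reported through
    ``active_set``.
    """
    if isinstance(counts_or_dtrajs, np.ndarray) and counts_or_dtrajs.ndim == 2 \
            and counts_or_dtrajs.shape[0] == counts_or_dtrajs.shape[1]:
        counts = np.asarray(counts_or_dtrajs, dtype=float)
    else:
        counts = count_matrix(counts_or_dtrajs, lag)

    active = largest_connected_set(counts)
    if len(active) < counts.shape[0]:
        dropped = sorted(set(range(counts.shape[0])) - set(active.tolist()))
        warnings.warn(f"count matrix not connected; dropping states {dropped}")
    c = counts[np.ix_(active, active)]

    if reversible:
        x = _reversible_mle(c)
        xi = x.sum(axis=1)
        t = x / xi[:, None]
        pi = xi / xi.sum()
    else:
        rows = c.sum(axis=1)
        t = c / rows[:, None]
        w, v = np.linalg.eig(t.T)
        i = int(np.argmin(np.abs(w - 1.0)))
        pi = np.real(v[:, i])
        pi = np.abs(pi) / np.abs(pi).sum()
    # repair rounding so rows sum to one at machine precision
    t = t / t.sum(axis=1)[:, None]
    return MSM(t, pi, lag, dt, active, counts=c, reversible=reversible)


def _reversible_spectrum(msm: MSM) -> tuple[np.ndarray, np.ndarray]:
    """Real eigenvalues (descending) and right eigenvectors of a reversible T
    via the symmetrized similarity transform."""
    pi = msm.stationary
    d = np.sqrt(pi)
    s = (msm.transition_matrix * d[:, None]) / d[None, :]
    s = 0.5 * (s + s.T)
    w, v = np.linalg.eigh(s)
    order = np.argsort(w)[::-1]
    w = w[order]
    psi = v[:, order] / d[:, None]          # right eigenvectors of T
    psi /= psi[0, 0] if psi[0, 0] != 0 else 1.0
    return w, psi


def implied_timescales(msm: MSM, k: int | None = None) -> np.ndarray:
    """Implied timescales t_i = -lag_time / ln(lambda_i), sorted descending.

    The stationary eigenvalue is excluded; eigenvalues <= 0 yield NaN
    (undefined at this lag); eigenvalues >= 1 yield +inf.
    """
    if msm.reversible:
        w, _ = _reversible_spectrum(msm)
    else:
        w = np.sort(np.real(np.linalg.eigvals(msm.transition_matrix)))[::-1]
    w = w[1:] if k is None else w[1:k + 1]
    out = np.empty(len(w))
    for i, lam in enumerate(w):
        if lam <= 0:
            out[i] = np.nan
        elif lam >= 1:
            out[i] = np.inf
        else:
            out[i] = -msm.lag_time / math.log(lam)
    return out


@dataclass
class CoarseModel:
    """Metastable coarse-graining of an MSM."""

    memberships: np.ndarray      # micro x macro, rows sum to 1
    assignments: np.ndarray      # crisp argmax macro label per micro state
    populations: np.ndarray      # macro stationary populations
    rate_matrix: np.ndarray      # macro generator, 1/s (rad/s magnitude)
    msm: MSM

    def __post_init__(self) -> None:
        m = self.memberships
        if (m < -1e-10).any() or (m > 1 + 1e-10).any():
            raise ValueError("memberships must lie in [0, 1]")
        if np.abs(m.sum(axis=1) - 1).max() > 1e-8:
            raise ValueError("membership rows must sum to 1")
        if abs(self.populations.sum() - 1.0) > 1e-8:
            raise ValueError("coarse populations must sum to 1")


def _pcca_memberships(psi: np.ndarray, n: int) -> np.ndarray:
    """Inner-simplex PCCA-style memberships from the leading eigenvectors."""
    m = psi.shape[0]
    x = psi[:, :n].copy()
    # vertex hunting: farthest point, then repeated orthogonal deflation
    idx = np.zeros(n, dtype=int)
    idx[0] = int(np.argmax(np.linalg.norm(x, axis=1)))
    ortho = x - x[idx[0]]
    for j in range(1, n):
        norms = np.linalg.norm(ortho, axis=1)
        idx[j] = int(np.argmax(norms))
        d = ortho[idx[j]] / max(norms[idx[j]], 1e-300)
        ortho = ortho - np.outer(ortho @ d, d)
    a = np.linalg.inv(x[idx])
    chi = x @ a
    chi = np.clip(chi, 0.0, None)
    chi /= chi.sum(axis=1)[:, None]
    return chi


def coarse_grain(msm: MSM, n_macrostates: int, gap_tol: float = 1e-3) -> CoarseModel:
    """Coarse-grain a reversible MSM to ``n_macrostates`` metastable states.

    Memberships come from the simplex structure of the n-1 slowest right
    eigenvectors; crisp argmax assignments are used to sum stationary
    populations and to project the microstate generator onto macro rates.
    """
    if n_macrostates < 1 or n_macrostates > msm.n_states:
        raise ValueError("n_macrostates must be in [1, n_states]")
    if n_macrostates == 1:
        memberships = np.ones((msm.n_states, 1))
        return CoarseModel(memberships, np.zeros(msm.n_states, dtype=int),
                           np.array([1.0]), np.zeros((1, 1)), msm)
    w, psi = _reversible_spectrum(msm)
    if len(w) > n_macrostates and abs(w[n_macrostates - 1] - w[n_macrostates]) < gap_tol:
        warnings.warn(
            f"weak spectral gap after {n_macrostates} states "
            f"(lambda_n={w[n_macrostates - 1]:.6f}, lambda_n+1={w[n_macrostates]:.6f})")
    chi = _pcca_memberships(psi, n_macrostates)
    assignments = np.argmax(chi, axis=1)
    # relabel macrostates by first appearance for deterministic output
    order = {}
    for a in assignments:
        if a not in order:
            order[a] = len(order)
    if len(order) < n_macrostates:
        raise ValueError("crisp assignment lost a macrostate; no metastable split")
    relabel = np.array([order[a] for a in range(n_macrostates)])
    chi = chi[:, np.argsort(relabel)]
    assignments = relabel[assignments]

    pi = msm.stationary
    pops = np.array([pi[assignments == a].sum() for a in range(n_macrostates)])
    try:
        gen = generator_from_tmatrix(msm.transition_matrix, msm.lag_time)
        k_coarse = _project_generator(gen.K, pi, assignments, n_macrostates)
    except ValueError:
        # fast intra-macrostate mixing can push microstate eigenvalues below
        # zero at this lag; the coarse-level chain is still embeddable
        t_coarse = _project_tmatrix(msm.transition_matrix, pi, assignments,
                                    n_macrostates)
        warnings.warn("microstate generator undefined at this lag; "
                      "taking the generator of the coarse transition matrix")
        k_coarse = generator_from_tmatrix(t_coarse, msm.lag_time).K
    return CoarseModel(chi, assignments, pops, k_coarse, msm)


def _project_tmatrix(t: np.ndarray, pi: np.ndarray, assignments: np.ndarray,
                     n_macro: int) -> np.ndarray:
    tc = np.zeros((n_macro, n_macro))
    for a in range(n_macro):
        ia = assignments == a
        wa = pi[ia] / pi[ia].sum()
        for b in range(n_macro):
            tc[a, b] = float(wa @ t[np.ix_(ia, assignments == b)].sum(axis=1))
    return tc / tc.sum(axis=1)[:, None]


def _project_generator(k_micro: np.ndarray, pi: np.ndarray,
                       assignments: np.ndarray, n_macro: int) -> np.ndarray:
    """Population-weighted crisp projection of a microstate generator."""
    k = np.zeros((n_macro, n_macro))
    for a in range(n_macro):
        ia = assignments == a
        wa = pi[ia] / pi[ia].sum()
        for b in range(n_macro):
            if a == b:
                continue
            k[a, b] = float(wa @ k_micro[np.ix_(ia, assignments == b)].sum(axis=1))
    np.fill_diagonal(k, -k.sum(axis=1))
    return k


@dataclass
class GeneratorResult:
    K: np.ndarray
    max_clipped: float      # largest negative off-diagonal removed
    imag_norm: float        # size of the discarded imaginary part
    ok: bool


def generator_from_tmatrix(T: np.ndarray, tau: float) -> GeneratorResult:
    """Rate-matrix generator K = log(T)/tau with validity report.

    Negative off-diagonal entries of the matrix logarithm are clipped to
    zero and diagonals repaired to restore zero row sums; the report records
    how much was clipped and how large the discarded imaginary part was.
    """
    t = np.asarray(T, dtype=float)
    if np.abs(t.sum(axis=1) - 1.0).max() > 1e-8:
        raise ValueError("T must be row-stochastic")
    w = np.linalg.eigvals(t)
    if np.any((np.real(w) <= 0) & (np.abs(np.imag(w)) < 1e-10 * np.abs(w))) \
            or np.any(np.abs(w) == 0):
        raise ValueError(
            "matrix logarithm undefined: T has a non-positive real eigenvalue; "
            "increase the lag or check the estimate")
    logt = scipy.linalg.logm(t)
    imag_norm = float(np.abs(np.imag(logt)).max())
    k = np.real(logt) / tau
    offdiag = ~np.eye(k.shape[0], dtype=bool)
    neg = np.minimum(k[offdiag], 0.0)
    max_clipped = float(-neg.min()) if neg.size else 0.0
    k[offdiag] = np.maximum(k[offdiag], 0.0)
    np.fill_diagonal(k, 0.0)
    np.fill_diagonal(k, -k.sum(axis=1))
    ok = imag_norm < 1e-8 and max_clipped < 1e-8 * max(1.0, np.abs(k).max())
    return GeneratorResult(k, max_clipped, imag_norm, ok)


def stationary_from_generator(K: np.ndarray) -> np.ndarray:
    """Stationary distribution pi with pi K = 0, sum(pi) = 1."""
    n = K.shape[0]
    a = np.vstack([K.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    return pi


# ---------------------------------------------------------------------------
# experiment-augmented network

@dataclass
class AugmentedNetwork:
    """Globally consistent kinetic network after experimental augmentation."""

    network: KineticNetwork
    offsets_ppm: dict
    r2_by_field: dict
    chi2: float
    perturbation: float          # sum of squared log deviations of intra rates
    diagnostics: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.chi2 < 0 or self.perturbation < 0:
            raise ValueError("chi2 and perturbation must be >= 0")

    def to_record(self) -> dict:
        net = self.network
        names = net.names or tuple(f"state{i}" for i in range(net.n_states))
        return {
            "states": [{"name": names[i], "population": float(net.populations[i])}
                       for i in range(net.n_states)],
            "rates_rad_s": net.K.tolist(),
            "r2_by_field": {str(k): float(np.mean(v)) for k, v in self.r2_by_field.items()},
            "offsets_ppm": {str(r): list(map(float, np.atleast_1d(o)))
                            for r, o in self.offsets_ppm.items()},
            "chi2": self.chi2,
            "perturbation": self.perturbation,
        }


def _block_coarse(block: MSM, macro: np.ndarray) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Project one simulation block onto its macro labels.

    Returns (K_macro, pi_macro_relative, macro_labels) in the block's own
    macro label order.
    """
    labels = sorted(set(int(m) for m in macro))
    local = {g: i for i, g in enumerate(labels)}
    assign = np.array([local[int(m)] for m in macro])
    gen = generator_from_tmatrix(block.transition_matrix, block.lag_time)
    k = _project_generator(gen.K, block.stationary, assign, len(labels))
    pops = np.array([block.stationary[assign == i].sum() for i in range(len(labels))])
    return k, pops / pops.sum(), labels


def _assemble_K(n_macro: int, edges: list[tuple[int, int]], log_rates: np.ndarray) -> np.ndarray:
    k = np.zeros((n_macro, n_macro))
    for (i, j), lr in zip(edges, log_rates):
        k[i, j] = math.exp(lr)
    np.fill_diagonal(k, -k.sum(axis=1))
    return k


def augment_with_experiment(
    blocks: Sequence[MSM],
    block_macros: Sequence[np.ndarray],
    curves_by_residue: Mapping[int, Sequence[DispersionCurve]],
    offsets_ppm: Mapping[int, np.ndarray] | None = None,
    *,
    lam: float = 1.0,
    inter_edges: Sequence[tuple[int, int]] | None = None,
    trelax: float = DEFAULT_TRELAX,
    nucleus: str = "N15",
    n_starts: int = 8,
    seed: int = DEFAULT_SEED,
    max_nfev: int = 400,
    state_names: Sequence[str] | None = None,
) -> AugmentedNetwork:
    """Reconcile disconnected simulation blocks with dispersion data.

    Parameters
    ----------
    blocks, block_macros
        One MSM per mutually disconnected simulation block, and for each an
        integer array mapping its microstates to global macrostate labels.
    curves_by_residue
        Experimental dispersion curves (both fields) keyed by residue.
    offsets_ppm
        Per-residue chemical-shift offsets of each macrostate (ppm).  When
        omitted they are fitted jointly, bounded to +/- 6 ppm, with each
        residue's first macrostate pinned at 0 (an overall reference shift
        is unobservable).
    lam
        Weight of the log-space penalty tying intra-block rates to their
        simulation estimates.
    inter_edges
        Directed inter-block exchange edges to include as free parameters;
        by default every ordered cross-block pair.

    The free parameters are the inter-block exchange rates (unobserved in
    simulation), deviations of intra-block rates (penalized), and one
    exchange-free R2 per field; populations follow as the stationary
    distribution of the assembled rate matrix, which realizes the global
    population rebalancing across blocks.
    """
    if len(blocks) == 0:
        raise ValueError("need at least one simulation block")
    if len(blocks) != len(block_macros):
        raise ValueError("one macro assignment per block required")
    if not curves_by_residue and len(blocks) > 1:
        raise ValueError(
            "inter-block rates are unidentifiable without experimental data; "
            "supply dispersion curves or a single connected block")

    # project each block; collect macro labels, intra edges and priors
    all_labels: list[int] = []
    block_of: dict[int, int] = {}
    intra_edges: list[tuple[int, int]] = []
    intra_prior: list[float] = []
    rel_pops: dict[int, float] = {}
    for b, (msm_b, macro) in enumerate(zip(blocks, block_macros)):
        k_b, pops_b, labels = _block_coarse(msm_b, np.asarray(macro))
        for g in labels:
            if g in block_of:
                raise ValueError(f"macrostate {g} appears in more than one block")
            block_of[g] = b
        all_labels.extend(labels)
        for i, gi in enumerate(labels):
            rel_pops[gi] = float(pops_b[i])
            for j, gj in enumerate(labels):
                if i != j and k_b[i, j] > 1e-12:
                    intra_edges.append((gi, gj))
                    intra_prior.append(math.log(k_b[i, j]))
    labels_sorted = sorted(all_labels)
    if labels_sorted != list(range(len(labels_sorted))):
        raise ValueError("macro labels must be 0..n_macro-1")
    n_macro = len(labels_sorted)

    if inter_edges is None:
        inter_edges = [(i, j) for i in range(n_macro) for j in range(n_macro)
                       if i != j and block_of[i] != block_of[j]]
    inter_edges = list(inter_edges)
    if len(blocks) > 1 and not inter_edges:
        raise ValueError("disconnected blocks but no inter-block edges allowed")

    edges = intra_edges + inter_edges
    residues = sorted(curves_by_residue)
    fields = sorted({c.field.proton_mhz for r in residues for c in curves_by_residue[r]})
    fit_offsets = offsets_ppm is None
    if not fit_offsets:
        offsets_fixed = {r: np.asarray(offsets_ppm[r], dtype=float) for r in residues}
        for r in residues:
            if len(offsets_fixed[r]) != n_macro:
                raise ValueError(f"offsets for residue {r} must have {n_macro} entries")

    n_intra, n_inter = len(intra_edges), len(inter_edges)
    n_rates = n_intra + n_inter
    n_off = len(residues) * (n_macro - 1) if fit_offsets else 0

    # R2_0 init: fast-pulsing tail of the curves
    r2_init = []
    for mhz in fields:
        tails = [c.r2eff[-2:].mean() for r in residues
                 for c in curves_by_residue[r] if c.field.proton_mhz == mhz]
        r2_init.append(float(np.mean(tails)))

    lo = np.concatenate([np.full(n_rates, math.log(1e-2)),
                         np.full(len(fields), 0.01),
                         np.full(n_off, -6.0)])
    hi = np.concatenate([np.full(n_rates, math.log(3e5)),
                         np.full(len(fields), 300.0),
                         np.full(n_off, 6.0)])

    prior = np.array(intra_prior)
    sqrt_lam = math.sqrt(max(lam, 0.0))

    def unpack(x):
        log_rates = x[:n_rates]
        r2 = {mhz: float(x[n_rates + i]) for i, mhz in enumerate(fields)}
        if fit_offsets:
            off = {}
            base = n_rates + len(fields)
            for ir, r in enumerate(residues):
                o = np.zeros(n_macro)
                o[1:] = x[base + ir * (n_macro - 1): base + (ir + 1) * (n_macro - 1)]
                off[r] = o
        else:
            off = offsets_fixed
        return log_rates, r2, off

    def residual(x):
        log_rates, r2, off = unpack(x)
        k = _assemble_K(n_macro, edges, log_rates)
        pi = stationary_from_generator(k)
        out = []
        if (pi <= 1e-12).any() or not np.all(np.isfinite(pi)):
            n_data = sum(c.n_points for r in residues for c in curves_by_residue[r])
            return np.full(n_data + n_intra, 1e3)
        for r in residues:
            for c in curves_by_residue[r]:
                net_A, m0 = _bm_network_A(k, pi, off[r], r2[c.field.proton_mhz],
                                          c.field, c.nucleus)
                calc = np.array([_bm_decay(net_A, m0, v, c.trelax) for v in c.nu_cpmg])
                sg = np.where(c.sigma > 0, c.sigma, 1.0)
                out.append((c.r2eff - calc) / sg)
        out.append(sqrt_lam * (log_rates[:n_intra] - prior))
        return np.concatenate(out)

    def data_chi2(x):
        r = residual(x)
        n_pen = n_intra
        return float(np.sum(r[:len(r) - n_pen] ** 2))

    rng = np.random.default_rng(seed)
    starts = []
    for s in range(n_starts):
        x0 = np.empty(n_rates + len(fields) + n_off)
        x0[:n_intra] = prior
        if s == 0:
            x0[n_intra:n_rates] = math.log(100.0)
        else:
            x0[n_intra:n_rates] = np.log(10.0 ** rng.uniform(1.0, 4.0, size=n_inter))
        x0[n_rates:n_rates + len(fields)] = r2_init
        if n_off:
            x0[n_rates + len(fields):] = rng.uniform(-1.0, 1.0, size=n_off) if s else 0.0
        starts.append(np.clip(x0, lo, hi))

    best = None
    chi2_init = math.inf
    for x0 in starts:
        chi2_init = min(chi2_init, data_chi2(x0))
        sol = scipy.optimize.least_squares(residual, x0, bounds=(lo, hi),
                                           method="trf", max_nfev=max_nfev)
        if best is None or sol.cost < best.cost:
            best = sol

    log_rates, r2, off = unpack(best.x)
    k = _assemble_K(n_macro, edges, log_rates)
    pi = stationary_from_generator(k)
    chi2 = data_chi2(best.x)
    perturbation = float(np.sum((log_rates[:n_intra] - prior) ** 2))
    network = KineticNetwork(k, pi, np.zeros(n_macro), {m: r2[m] for m in fields},
                             names=tuple(state_names) if state_names else None)
    diagnostics = {
        "success": bool(best.success),
        "converged": bool(best.success),
        "n_starts": n_starts,
        "cost": float(best.cost),
        "chi2_unaugmented": chi2_init,
        "edges": edges,
        "intra_edges": intra_edges,
        "inter_edges": inter_edges,
        "relative_block_populations": rel_pops,
        "message": best.message,
    }
    if not best.success:
        warnings.warn(f"augmentation optimizer did not report convergence: {best.message}")
    return AugmentedNetwork(network, dict(off), r2, chi2, perturbation, diagnostics)


def _bm_network_A(K, pi, offsets_ppm, r2_scalar, field: FieldContext, nucleus: str):
    omega = np.asarray(offsets_ppm, dtype=float) * 1e-6 * abs(field.larmor(nucleus))
    A = K.T.astype(complex) + 1j * np.diag(omega) - np.eye(K.shape[0]) * r2_scalar
    return A, pi.astype(complex)


def predicted_curves(aug: AugmentedNetwork, residue: int,
                     template: DispersionCurve) -> np.ndarray:
    """Model dispersion curve for one residue on a template's nu grid."""
    net = aug.network
    A, m0 = _bm_network_A(net.K, net.populations, aug.offsets_ppm[residue],
                          aug.r2_by_field[template.field.proton_mhz],
                          template.field, template.nucleus)
    return np.array([_bm_decay(A, m0, v, template.trelax) for v in template.nu_cpmg])


# ---------------------------------------------------------------------------
# dtraj I/O

def read_dtraj(path) -> np.ndarray:
    """One integer state label per line."""
    return np.loadtxt(path, dtype=int, ndmin=1)


def write_dtraj(dtraj: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(dtraj, dtype=int), fmt="%d")
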