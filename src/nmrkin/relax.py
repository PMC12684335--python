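"""Backbone amide relaxation analysis.

Model-free (Lipari-Szabo) spectral densities, prediction of longitudinal
(R1), transverse (R2) and heteronuclear-NOE rates for an amide N-H vector
under combined dipolar and chemical-shift-anisotropy relaxation, estimation
of the overall rotational correlation time tau_c from the R2/R1 ratio, and
the simple per-residue screening statistics used to flag fast (ps-ns) and
slow (us-ms) motion: hetNOE below 0.7 and the R1*R2 product above 20 s^-2.

All rates are in s^-1, frequencies in rad/s internally; tau_c is reported
in ns at the user surface because that is the unit practitioners quote.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

# Gyromagnetic ratios, rad s^-1 T^-1 (15N is negative).
GAMMA_H = 2.6752218744e8
GAMMA_N = -2.7126e7
GAMMA_C = 6.728284e7
HBAR = 1.054571817e-34  # J s
MU0_OVER_4PI = 1e-7     # T^2 J^-1 m^3

_NUCLEUS_GAMMA = {"N15": GAMMA_N, "C13": GAMMA_C, "H1": GAMMA_H}

#: default N-H bond length (Angstrom) and 15N CSA (ppm); community defaults
DEFAULT_R_NH = 1.02
DEFAULT_CSA = -172.0

HETNOE_THRESHOLD = 0.7
R1R2_THRESHOLD = 20.0
CSP_NITROGEN_WEIGHT = 0.14


@dataclass(frozen=True)
class FieldContext:
    """Static magnetic field, keyed by the 1H resonance frequency in MHz."""

    proton_mhz: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.proton_mhz) and self.proton_mhz > 0):
            raise ValueError(f"proton frequency must be positive, got {self.proton_mhz}")

    @property
    def omega_h(self) -> float:
        """1H Larmor frequency in rad/s."""
        return 2.0 * math.pi * self.proton_mhz * 1e6

    @property
    def omega_n(self) -> float:
        """15N Larmor frequency in rad/s (signed; negative gamma)."""
        return self.omega_h * GAMMA_N / GAMMA_H

    def larmor(self, nucleus: str = "N15") -> float:
        """Signed Larmor frequency (rad/s) for the given nucleus."""
        return self.omega_h * _NUCLEUS_GAMMA[nucleus] / GAMMA_H


@dataclass(frozen=True)
class MotionParams:
    """Model-free motional parameters of one N-H vector.

    tau_c   overall isotropic tumbling time (seconds)
    s2      generalized order parameter, 0 (isotropic) .. 1 (rigid)
    tau_e   effective internal correlation time (seconds), 0 disables
    r_nh    N-H bond length in Angstrom
    csa_ppm 15N chemical shift anisotropy in ppm
    """

    tau_c: float
    s2: float = 1.0
    tau_e: float = 0.0
    r_nh: float = DEFAULT_R_NH
    csa_ppm: float = DEFAULT_CSA

    def __post_init__(self) -> None:
        if not (self.tau_c > 0 and np.isfinite(self.tau_c)):
            raise ValueError("tau_c must be positive and finite")
        if not (0.0 <= self.s2 <= 1.0):
            raise ValueError("S2 must lie in [0, 1]")
        if self.tau_e < 0:
            raise ValueError("tau_e must be >= 0")

    @property
    def tau_c_ns(self) -> float:
        return self.tau_c * 1e9


def spectral_density(motion: MotionParams, omega) -> np.ndarray | float:
    """Lipari-Szabo spectral density J(omega) in s/rad.

    J(w) = (2/5) [ S2 tc / (1 + (w tc)^2) + (1 - S2) t' / (1 + (w t')^2) ]
    with 1/t' = 1/tc + 1/te.  With S2 = 1 this reduces to the rigid
    isotropic-rotor form (2/5) tc / (1 + (w tc)^2).
    """
    om = np.asarray(omega, dtype=float)
    if not np.all(np.isfinite(om)):
        raise ValueError("non-finite frequency passed to spectral_density")
    tc = motion.tau_c
    j = motion.s2 * tc / (1.0 + (om * tc) ** 2)
    if motion.tau_e > 0.0 and motion.s2 < 1.0:
        tp = 1.0 / (1.0 / tc + 1.0 / motion.tau_e)
        j = j + (1.0 - motion.s2) * tp / (1.0 + (om * tp) ** 2)
    out = 0.4 * j
    return float(out) if np.isscalar(omega) else out


def _dipolar_csa_constants(field: FieldContext, r_nh: float, csa_ppm: float) -> tuple[float, float]:
    r_m = r_nh * 1e-10
    d = MU0_OVER_4PI * HBAR * GAMMA_H * GAMMA_N / r_m**3
    c = field.omega_n * csa_ppm * 1e-6 / math.sqrt(3.0)
    return d, c


def _rates_from_tau(tau_c, field: FieldContext, s2=1.0, tau_e=0.0,
                    r_nh: float = DEFAULT_R_NH, csa_ppm: float = DEFAULT_CSA):
    """Vectorized (R1, R2, hetNOE) for an array of tau_c values (seconds)."""
    tc = np.asarray(tau_c, dtype=float)
    d, c = _dipolar_csa_constants(field, r_nh, csa_ppm)
    wh, wn = field.omega_h, field.omega_n

    def j(om):
        jj = s2 * tc / (1.0 + (om * tc) ** 2)
        if np.any(np.asarray(tau_e) > 0) and np.any(np.asarray(s2) < 1):
            tp = 1.0 / (1.0 / tc + 1.0 / np.maximum(tau_e, 1e-30))
            jj = jj + (1.0 - s2) * tp / (1.0 + (om * tp) ** 2)
        return 0.4 * jj

    j0 = j(0.0)
    jn = j(abs(wn))
    jh = j(abs(wh))
    jhmn = j(abs(wh - wn))
    jhpn = j(abs(wh + wn))

    d2_4 = d * d / 4.0
    c2 = c * c
    r1 = d2_4 * (jhmn + 3.0 * jn + 6.0 * jhpn) + c2 * jn
    r2 = (d2_4 / 2.0) * (4.0 * j0 + jhmn + 3.0 * jn + 6.0 * jh + 6.0 * jhpn) \
        + (c2 / 6.0) * (4.0 * j0 + 3.0 * jn)
    noe = 1.0 + d2_4 * (GAMMA_H / GAMMA_N) * (6.0 * jhpn - jhmn) / r1
    return r1, r2, noe


def predict_rates(motion: MotionParams, field: FieldContext) -> tuple[float, float, float]:
    """Predict (R1, R2, hetNOE) for one N-H vector at the given field.

    Uses the standard dipolar + CSA expressions with spectral densities
    evaluated at {0, wN, wH-wN, wH, wH+wN}.
    """
    r1, r2, noe = _rates_from_tau(motion.tau_c, field, motion.s2, motion.tau_e,
                                  motion.r_nh, motion.csa_ppm)
    return float(r1), float(r2), float(noe)


@dataclass
class RelaxationTable:
    """Per-residue R1/R2/hetNOE table with uncertainties at one field.

    Columns: residue, R1, R1_err, R2, R2_err, hetNOE, hetNOE_err.
    """

    data: pd.DataFrame
    field: FieldContext

    REQUIRED = ("residue", "R1", "R1_err", "R2", "R2_err", "hetNOE", "hetNOE_err")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"relaxation table missing columns {missing}")
        d = self.data
        if (d["R1"] <= 0).any() or (d["R2"] <= 0).any():
            raise ValueError("R1 and R2 must be positive")
        if (d[["R1_err", "R2_err", "hetNOE_err"]] < 0).to_numpy().any():
            raise ValueError("uncertainties must be non-negative")
        if (d["hetNOE"] > 1.2).any():
            raise ValueError("hetNOE above the 1.2 sanity bound")

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        self.data.to_csv(path, sep="\t", index=False)
        Path(str(path) + ".cfg").write_text(
            f"proton_frequency_mhz = {self.field.proton_mhz}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RelaxationTable":
        path = Path(path)
        data = pd.read_csv(path, sep="\t")
        cfg = Path(str(path) + ".cfg")
        if not cfg.exists():
            raise FileNotFoundError(f"sidecar field config not found: {cfg}")
        kv = {}
        for line in cfg.read_text().splitlines():
            if "=" in line:
                k, v = line.split("=", 1)
                kv[k.strip()] = v.strip()
        return cls(data, FieldContext(float(kv["proton_frequency_mhz"])))


@dataclass
class TauCEstimate:
    tau_c_ns: float
    sigma_ns: float
    n_used: int
    n_excluded_noe: int
    n_trimmed: int
    per_residue: pd.DataFrame


def _invert_r2_r1(ratio, field: FieldContext, lo_ns: float = 0.1, hi_ns: float = 100.0,
                  iters: int = 80) -> np.ndarray:
    """Invert the rigid-rotor R2/R1 ratio to tau_c (ns) by bisection.

    The ratio is strictly increasing in tau_c, so bisection on
    [lo_ns, hi_ns] is safe; ratios outside the bracket map to NaN.
    """
    r = np.atleast_1d(np.asarray(ratio, dtype=float))

    def f(tc_ns):
        r1, r2, _ = _rates_from_tau(tc_ns * 1e-9, field)
        return r2 / r1

    lo = np.full_like(r, lo_ns)
    hi = np.full_like(r, hi_ns)
    bad = (r < f(np.array(lo_ns))) | (r > f(np.array(hi_ns))) | ~np.isfinite(r)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        below = f(mid) < r
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    out = 0.5 * (lo + hi)
    out[bad] = np.nan
    return out


def _trimmed_mean_tau(tau_ns: np.ndarray, iqr_factor: float = 1.5) -> tuple[float, np.ndarray]:
    """Mean of tau_c after removing values outside median +/- iqr_factor*IQR."""
    t = tau_ns[np.isfinite(tau_ns)]
    if t.size == 0:
        return np.nan, np.zeros(0, dtype=bool)
    med = np.median(t)
    q1, q3 = np.percentile(t, [25, 75])
    iqr = q3 - q1
    keep_all = np.isfinite(tau_ns) & (np.abs(tau_ns - med) <= iqr_factor * iqr + 1e-12)
    return float(np.mean(tau_ns[keep_all])), keep_all


def estimate_tau_c(table: RelaxationTable, *, noe_threshold: float = HETNOE_THRESHOLD,
                   n_monte_carlo: int = 1000, seed: int = 20250101,
                   iqr_factor: float = 1.5) -> TauCEstimate:
    """Estimate the rotational correlation time from per-residue R2/R1.

    Residues with hetNOE below ``noe_threshold`` (flexible, where the rigid
    approximation fails) are excluded; the remaining per-residue tau_c values
    (rigid inversion of R2/R1) are trimmed to median +/- 1.5 IQR to reject
    residues with residual exchange contributions, then averaged.  The
    uncertainty is a Monte-Carlo estimate obtained by resampling R1 and R2
    within their stated errors.
    """
    d = table.data
    rigid = d["hetNOE"] >= noe_threshold
    n_excluded = int((~rigid).sum())
    sub = d[rigid]
    if len(sub) < 5:
        raise ValueError(
            f"only {len(sub)} residues survive the hetNOE >= {noe_threshold} filter; "
            "need at least 5")
    ratio = (sub["R2"] / sub["R1"]).to_numpy()
    tau = _invert_r2_r1(ratio, table.field)
    mean_tau, keep = _trimmed_mean_tau(tau, iqr_factor)
    n_used = int(keep.sum())
    if n_used == 0:
        raise ValueError("no residues survive the R2/R1 trimming")

    rng = np.random.default_rng(seed)
    r1 = sub["R1"].to_numpy()
    r2 = sub["R2"].to_numpy()
    s1 = sub["R1_err"].to_numpy()
    s2 = sub["R2_err"].to_numpy()
    r1_mc = rng.normal(r1, s1, size=(n_monte_carlo, r1.size))
    r2_mc = rng.normal(r2, s2, size=(n_monte_carlo, r2.size))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio_mc = np.where(r1_mc > 0, r2_mc / r1_mc, np.nan)
    tau_mc = _invert_r2_r1(ratio_mc.ravel(), table.field).reshape(ratio_mc.shape)
    means = np.empty(n_monte_carlo)
    for i in range(n_monte_carlo):
        means[i], _ = _trimmed_mean_tau(tau_mc[i], iqr_factor)
    sigma = float(np.nanstd(means))

    per_res = pd.DataFrame({
        "residue": sub["residue"].to_numpy(),
        "tau_c_ns": tau,
        "used": keep,
    })
    return TauCEstimate(float(mean_tau), sigma, n_used, n_excluded,
                        int((~keep).sum()), per_res)


def r1r2_flags(table: RelaxationTable, threshold: float = R1R2_THRESHOLD) -> pd.DataFrame:
    """R1*R2 product per residue; flagged when strictly above ``threshold``.

    Elevated R1*R2 indicates us-ms chemical exchange without the rotational
    anisotropy sensitivity of R2 alone.
    """
    d = table.data
    prod = d["R1"] * d["R2"]
    return pd.DataFrame({
        "residue": d["residue"],
        "r1r2": prod,
        "flagged": prod > threshold,
    })


def hetnoe_flags(table: RelaxationTable, threshold: float = HETNOE_THRESHOLD) -> pd.DataFrame:
    """Flag residues with hetNOE strictly below ``threshold`` (fast ps-ns motion)."""
    d = table.data
    return pd.DataFrame({
        "residue": d["residue"],
        "hetNOE": d["hetNOE"],
        "flagged": d["hetNOE"] < threshold,
    })


@dataclass(frozen=True)
class ShiftPair:
    """Amide 1H/15N chemical shifts of one residue in two states (ppm)."""

    residue: int
    dh_a: float
    dh_b: float
    dn_a: float
    dn_b: float

    def __post_init__(self) -> None:
        vals = (self.dh_a, self.dh_b, self.dn_a, self.dn_b)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("chemical shifts must be finite")


def csp(pair: ShiftPair, weight: float = CSP_NITROGEN_WEIGHT) -> float:
    """Combined amide chemical shift perturbation in ppm.

    delta = sqrt(dH^2 + (weight * dN)^2), with the conventional nitrogen
    down-weighting (default 0.14).
    """
    if not weight > 0:
        raise ValueError("weight must be positive")
    return math.hypot(pair.dh_a - pair.dh_b, weight * (pair.dn_a - pair.dn_b))


def csp_table(state_a: pd.DataFrame, state_b: pd.DataFrame,
              weight: float = CSP_NITROGEN_WEIGHT) -> pd.DataFrame:
    """Per-residue CSPs from two shift tables with columns residue, dH, dN.

    Residues missing (or non-finite) in either state are skipped with a log
    record, mirroring unassigned resonances in real spectra.
    """
    merged = state_a.merge(state_b, on="residue", suffixes=("_a", "_b"), how="outer")
    rows = []
    for _, row in merged.iterrows():
        vals = row[["dH_a", "dN_a", "dH_b", "dN_b"]]
        if vals.isna().any():
            log.info("csp: residue %s skipped (missing shift)", row["residue"])
            continue
        pair = ShiftPair(int(row["residue"]), row["dH_a"], row["dH_b"],
                         row["dN_a"], row["dN_b"])
        rows.append({"residue": int(row["residue"]), "csp": csp(pair, weight)})
    return pd.DataFrame(rows, columns=["residue", "csp"])
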