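"""CPMG relaxation dispersion: forward models and fitting.

Two forward models for the effective transverse relaxation rate R2,eff as a
function of the refocusing frequency nu_CPMG:

* the Carver-Richards closed form for two-site exchange (``cr_r2eff``), and
* a numerical N-site Bloch-McConnell propagator (``bm_r2eff``) that evolves
  one complex transverse-magnetization component per exchanging state
  through an explicit [tau_cp - 180 - tau_cp] echo train.

Fitting is weighted least squares with seeded multistart, model selection by
AICc against a no-exchange (flat) model, and the exchange contribution Rex is
the model drop from nu_CPMG -> 0 to the fast-pulsing asymptote, flagged when
strictly above 5 s^-1.

Convention: nu_CPMG = 1/(4 tau_cp); one echo element is [tau_cp-180-tau_cp]
(duration 2 tau_cp); N echo elements fill the constant-time relaxation
period Trelax, so valid nu_CPMG values are integer multiples of
1/(2 Trelax).  180-degree pulses are ideal (instantaneous complex
conjugation).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.linalg
import scipy.optimize

from .relax import FieldContext

DEFAULT_TRELAX = 0.040  # s
REX_THRESHOLD = 5.0     # s^-1

_ETA_SAFE = 30.0  # switch to the asymptotic log form of arccosh(cosh) above this


@dataclass
class DispersionCurve:
    """One residue's dispersion profile at one static field."""

    residue: int
    field: FieldContext
    nu_cpmg: np.ndarray
    r2eff: np.ndarray
    sigma: np.ndarray
    nucleus: str = "N15"
    trelax: float = DEFAULT_TRELAX

    def __post_init__(self) -> None:
        self.nu_cpmg = np.asarray(self.nu_cpmg, dtype=float)
        self.r2eff = np.asarray(self.r2eff, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (self.nu_cpmg > 0).all():
            raise ValueError("nu_cpmg values must be positive")
        if not (np.diff(self.nu_cpmg) > 0).all():
            raise ValueError("nu_cpmg values must be strictly increasing")
        if (self.sigma < 0).any():
            raise ValueError("sigma must be non-negative")
        if not (len(self.nu_cpmg) == len(self.r2eff) == len(self.sigma)):
            raise ValueError("nu_cpmg, r2eff, sigma must have equal length")

    @property
    def n_points(self) -> int:
        return len(self.nu_cpmg)


@dataclass(frozen=True)
class TwoStateParams:
    """Two-site exchange parameters under the major-state convention.

    pA >= 0.5 is the major-state population; kex = k_AB + k_BA (reported in
    rad/s following common dispersion-fitting practice, treated numerically
    as an s^-1 magnitude); dw_ppm >= 0 is the shift difference between the
    sites; r2_0 maps proton frequency (MHz) to the exchange-free R2.
    """

    pA: float
    kex: float
    dw_ppm: float
    r2_0: Mapping[float, float]

    def __post_init__(self) -> None:
        if not (0.5 <= self.pA < 1.0):
            raise ValueError("pA must lie in [0.5, 1)")
        if not self.kex > 0:
            raise ValueError("kex must be positive")
        if self.dw_ppm < 0:
            raise ValueError("dw_ppm must be >= 0 under the major-state convention")


@dataclass
class KineticNetwork:
    """N exchanging states: rate matrix, populations, shifts, intrinsic R2.

    K[i, j] is the i -> j rate (rad/s magnitude); rows sum to zero.  The
    stationary populations satisfy pi K = 0.  offsets_ppm holds one chemical
    shift offset per state (an overall reference shift is immaterial for
    dispersion); r2_by_field maps proton MHz to a scalar (shared) or
    per-state array of intrinsic R2 values.
    """

    K: np.ndarray
    populations: np.ndarray
    offsets_ppm: np.ndarray
    r2_by_field: Mapping[float, float | np.ndarray]
    names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        self.populations = np.asarray(self.populations, dtype=float)
        self.offsets_ppm = np.asarray(self.offsets_ppm, dtype=float)
        n = self.K.shape[0]
        if self.K.shape != (n, n):
            raise ValueError("K must be square")
        off = self.K[~np.eye(n, dtype=bool)]
        if (off < -1e-12).any():
            raise ValueError("off-diagonal rates must be >= 0")
        if np.abs(self.K.sum(axis=1)).max() > 1e-8 * max(1.0, np.abs(self.K).max()):
            raise ValueError("rows of K must sum to zero")
        if (self.populations <= 0).any():
            raise ValueError("populations must be strictly positive")
        if abs(self.populations.sum() - 1.0) > 1e-8:
            raise ValueError("populations must sum to one")
        resid = np.abs(self.populations @ self.K).max()
        if resid > 1e-6 * max(1.0, np.abs(self.K).max()):
            raise ValueError("populations are not stationary under K")
        if len(self.offsets_ppm) != n:
            raise ValueError("need one shift offset per state")

    @property
    def n_states(self) -> int:
        return self.K.shape[0]

    def r2_vector(self, proton_mhz: float) -> np.ndarray:
        r2 = self.r2_by_field[proton_mhz]
        return np.broadcast_to(np.asarray(r2, dtype=float), (self.n_states,)).copy()

    @classmethod
    def two_state(cls, pA: float, kex: float, dw_ppm: float,
                  r2_by_field: Mapping[float, float]) -> "KineticNetwork":
        """Build the two-site network equivalent to ``TwoStateParams``."""
        pB = 1.0 - pA
        k_ab, k_ba = pB * kex, pA * kex
        K = np.array([[-k_ab, k_ab], [k_ba, -k_ba]])
        return cls(K, np.array([pA, pB]), np.array([0.0, dw_ppm]), dict(r2_by_field))


def _cr_terms(pA: float, kex: float, dw: float):
    """Shared Carver-Richards intermediates for equal intrinsic R2."""
    pB = 1.0 - pA
    psi = kex * kex - dw * dw
    zeta = -2.0 * dw * kex * (pA - pB)
    s = math.hypot(psi, zeta)
    dplus = 0.5 * ((psi + 2.0 * dw * dw) / s + 1.0) if s > 0 else 1.0
    dminus = dplus - 1.0
    a_plus = math.sqrt(max(s + psi, 0.0)) / (2.0 * math.sqrt(2.0))
    a_minus = math.sqrt(max(s - psi, 0.0)) / (2.0 * math.sqrt(2.0))
    return dplus, dminus, a_plus, a_minus


def cr_r2eff(params: TwoStateParams, field: FieldContext, nu_cpmg,
             nucleus: str = "N15") -> np.ndarray | float:
    """Carver-Richards closed-form R2,eff(nu_CPMG) for two-site exchange.

    dw_ppm is converted to rad/s at the given field; the arccosh(cosh)
    combination is evaluated in a log-stable form at slow pulsing where
    cosh would overflow.
    """
    nu = np.atleast_1d(np.asarray(nu_cpmg, dtype=float))
    if (nu <= 0).any():
        raise ValueError("nu_cpmg must be positive")
    dw = params.dw_ppm * 1e-6 * abs(field.larmor(nucleus))
    r2_0 = params.r2_0[field.proton_mhz]
    if dw == 0.0:
        out = np.full_like(nu, float(r2_0))
        return float(out[0]) if np.isscalar(nu_cpmg) else out

    dplus, dminus, a_plus, a_minus = _cr_terms(params.pA, params.kex, dw)
    eta_p = a_plus / nu
    eta_m = a_minus / nu
    acosh_term = np.empty_like(nu)
    small = eta_p <= _ETA_SAFE
    arg = dplus * np.cosh(eta_p[small]) - dminus * np.cos(eta_m[small])
    acosh_term[small] = np.arccosh(np.maximum(arg, 1.0))
    # slow-pulsing asymptote: arccosh(D+ cosh x) -> x + ln(D+) for large x
    acosh_term[~small] = eta_p[~small] + np.log(max(dplus, 1e-300))
    out = r2_0 + params.kex / 2.0 - nu * acosh_term
    return float(out[0]) if np.isscalar(nu_cpmg) else out


def cr_rex(params: TwoStateParams, field: FieldContext, nucleus: str = "N15") -> float:
    """Closed-form Rex = R2,eff(nu->0) - R2,eff(nu->inf) for the CR model."""
    dw = params.dw_ppm * 1e-6 * abs(field.larmor(nucleus))
    if dw == 0.0:
        return 0.0
    dplus, dminus, a_plus, a_minus = _cr_terms(params.pA, params.kex, dw)
    return math.sqrt(dplus * a_plus**2 + dminus * a_minus**2) - a_plus


def _echo_count(nu: float, trelax: float) -> tuple[int, float]:
    """Nearest integer echo count for nu_CPMG under the fixed Trelax."""
    n_exact = 2.0 * trelax * nu
    n = max(1, int(round(n_exact)))
    if abs(n - n_exact) > 1e-6 * max(1.0, n_exact):
        warnings.warn(
            f"nu_cpmg {nu:.6g} Hz is not commensurate with Trelax={trelax} s; "
            f"using nearest valid grid point {n / (2 * trelax):.6g} Hz",
            stacklevel=3)
    return n, n / (2.0 * trelax)


def _expm_eig(A: np.ndarray, t: float, eig=None) -> np.ndarray:
    """exp(A t) via eigendecomposition, with an expm fallback if A is
    close to defective."""
    if eig is None:
        lam, v = np.linalg.eig(A)
        try:
            vinv = np.linalg.inv(v)
        except np.linalg.LinAlgError:
            return scipy.linalg.expm(A * t)
        if np.linalg.cond(v) > 1e10:
            return scipy.linalg.expm(A * t)
    else:
        lam, v, vinv = eig
    return (v * np.exp(lam * t)) @ vinv


def _bm_decay(A: np.ndarray, m0: np.ndarray, nu: float, trelax: float) -> float:
    """-ln(|sum M(Trelax)| / |sum M0|) / Trelax for one nu_CPMG value."""
    n_echo, nu_used = _echo_count(nu, trelax)
    tau_cp = 1.0 / (4.0 * nu_used)
    u = _expm_eig(A, tau_cp)
    c = u @ np.conj(u)               # one echo: M -> C conj(M)
    p2 = c @ np.conj(c)              # two echoes (linear)
    m = np.linalg.matrix_power(p2, n_echo // 2) @ m0
    if n_echo % 2:
        m = c @ np.conj(m)
    signal = abs(m.sum()) / abs(m0.sum())
    return -math.log(max(signal, 1e-300)) / trelax


def _network_A(network: KineticNetwork, field: FieldContext, nucleus: str) -> tuple[np.ndarray, np.ndarray]:
    omega = network.offsets_ppm * 1e-6 * abs(field.larmor(nucleus))
    r2 = network.r2_vector(field.proton_mhz)
    A = network.K.T.astype(complex) + 1j * np.diag(omega) - np.diag(r2)
    return A, network.populations.astype(complex)


def bm_r2eff(network: KineticNetwork, field: FieldContext, nu_cpmg,
             trelax: float = DEFAULT_TRELAX, nucleus: str = "N15") -> np.ndarray | float:
    """Numerical N-site Bloch-McConnell R2,eff(nu_CPMG).

    The complex transverse magnetization (one component per state,
    initialized to the stationary populations) evolves under
    A = K^T + i Omega - diag(R2_intrinsic); each echo element is free
    evolution for tau_cp, an ideal 180 pulse (complex conjugation), and
    another tau_cp, repeated to fill Trelax.
    """
    A, m0 = _network_A(network, field, nucleus)
    nu = np.atleast_1d(np.asarray(nu_cpmg, dtype=float))
    out = np.array([_bm_decay(A, m0, v, trelax) for v in nu])
    return float(out[0]) if np.isscalar(nu_cpmg) else out


def bm_r2eff_rate(network: KineticNetwork, field: FieldContext, nu_cpmg,
                  nucleus: str = "N15") -> np.ndarray | float:
    """Asymptotic per-echo decay rate of the Bloch-McConnell echo train.

    Returns -ln(max |eigenvalue|) / (4 tau_cp) of the two-echo propagator,
    i.e. the decay rate the signal approaches once initial-condition
    transients have died out.  The Carver-Richards closed form is exactly
    this dominant-mode rate for two sites; ``bm_r2eff`` at finite Trelax
    additionally contains an O(1/Trelax) amplitude transient.
    """
    A, _ = _network_A(network, field, nucleus)
    nu = np.atleast_1d(np.asarray(nu_cpmg, dtype=float))
    out = np.empty_like(nu)
    for i, v in enumerate(nu):
        tau_cp = 1.0 / (4.0 * v)
        u = _expm_eig(A, tau_cp)
        c = u @ np.conj(u)
        p2 = c @ np.conj(c)
        lam = np.max(np.abs(np.linalg.eigvals(p2)))
        out[i] = -math.log(max(lam, 1e-300)) / (4.0 * tau_cp)
    return float(out[0]) if np.isscalar(nu_cpmg) else out


def bm_rex(network: KineticNetwork, field: FieldContext,
           trelax: float = DEFAULT_TRELAX, nucleus: str = "N15") -> float:
    """Rex for an N-site network: lowest supported echo frequency minus the
    fast-pulsing asymptote (evaluated at 10 kHz)."""
    nu_lo = 1.0 / (2.0 * trelax)
    lo = bm_r2eff(network, field, nu_lo, trelax, nucleus)
    hi = bm_r2eff(network, field, 1.0e4, trelax, nucleus)
    return float(lo - hi)


@dataclass
class RexResult:
    value: float
    flagged: bool


def rex(model, field: FieldContext, *, threshold: float = REX_THRESHOLD,
        trelax: float = DEFAULT_TRELAX, nucleus: str = "N15") -> RexResult:
    """Exchange contribution to R2 and its strict > threshold flag.

    ``model`` is either fitted ``TwoStateParams`` (closed form) or a
    ``KineticNetwork`` (numerical Bloch-McConnell difference).
    """
    if isinstance(model, TwoStateParams):
        value = cr_rex(model, field, nucleus)
    elif isinstance(model, KineticNetwork):
        value = bm_rex(model, field, trelax, nucleus)
    else:
        raise TypeError(f"cannot compute Rex for {type(model)!r}")
    return RexResult(float(value), bool(value > threshold))


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitResult:
    model: str                      # "exchange" or "no-exchange"
    params: TwoStateParams | None
    r2_flat: dict[float, float] | None
    chi2: float
    aicc: float
    n_points: int
    n_params: int
    param_sigma: dict[str, float] = dc_field(default_factory=dict)
    param_ci: dict[str, tuple[float, float]] = dc_field(default_factory=dict)
    residuals: np.ndarray | None = None
    success: bool = True
    message: str = ""

    def __post_init__(self) -> None:
        if self.chi2 < 0:
            raise ValueError("chi2 must be >= 0")


def _aicc(chi2: float, k: int, n: int) -> float:
    if n - k - 1 <= 0:
        return math.inf
    return chi2 + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _check_curve_set(curves: Sequence[DispersionCurve]) -> None:
    if not curves:
        raise ValueError("no curves supplied")
    res = {c.residue for c in curves}
    nuc = {c.nucleus for c in curves}
    if len(res) > 1 or len(nuc) > 1:
        raise ValueError("all curves in one fit must share residue and nucleus")
    for c in curves:
        if c.n_points < 4:
            raise ValueError("need at least 4 points per curve to fit")


def _weights(sigma: np.ndarray) -> np.ndarray:
    # zero-sigma (synthetic noiseless) points get unit weight
    w = np.where(sigma > 0, sigma, 1.0)
    return w


def _exchange_residuals(x: np.ndarray, curves: Sequence[DispersionCurve],
                        fields: Sequence[float]) -> np.ndarray:
    pA, log10_kex, dw = x[0], x[1], x[2]
    r2_0 = {mhz: x[3 + i] for i, mhz in enumerate(fields)}
    params = TwoStateParams(pA, 10.0 ** log10_kex, dw, r2_0)
    out = []
    for c in curves:
        calc = cr_r2eff(params, c.field, c.nu_cpmg, c.nucleus)
        out.append((c.r2eff - calc) / _weights(c.sigma))
    return np.concatenate(out)


def fit_flat(curves: Sequence[DispersionCurve]) -> FitResult:
    """No-exchange model: one nu-independent R2_0 per field (weighted mean)."""
    _check_curve_set(curves)
    fields = sorted({c.field.proton_mhz for c in curves})
    r2_flat: dict[float, float] = {}
    chi2 = 0.0
    resid = []
    for mhz in fields:
        ys = np.concatenate([c.r2eff for c in curves if c.field.proton_mhz == mhz])
        ws = np.concatenate([_weights(c.sigma) for c in curves if c.field.proton_mhz == mhz])
        mean = float(np.sum(ys / ws**2) / np.sum(1.0 / ws**2))
        r2_flat[mhz] = mean
        r = (ys - mean) / ws
        chi2 += float(np.sum(r * r))
        resid.append(r)
    n = sum(c.n_points for c in curves)
    k = len(fields)
    return FitResult("no-exchange", None, r2_flat, chi2, _aicc(chi2, k, n),
                     n, k, residuals=np.concatenate(resid))


def _multistart_grid(curves: Sequence[DispersionCurve], fields: Sequence[float],
                     n_starts: int, rng: np.random.Generator) -> list[np.ndarray]:
    r2_init = [min(float(c.r2eff.min()) for c in curves if c.field.proton_mhz == mhz)
               for mhz in fields]
    pas = [0.6, 0.9, 0.97, 0.995]
    kexs = [100.0, 300.0, 1000.0, 3000.0, 10000.0]
    dws = [0.5, 1.5, 3.0]
    grid = [(p, k, d) for p in pas for k in kexs for d in dws]
    idx = rng.permutation(len(grid))[:n_starts]
    starts = []
    for i in idx:
        p, k, d = grid[i]
        starts.append(np.array([p, math.log10(k), d] + r2_init))
    return starts


def fit_dispersion(curves: Sequence[DispersionCurve], *, n_starts: int = 20,
                   seed: int = 20250101, n_bootstrap: int = 200) -> FitResult:
    """Fit the two-site Carver-Richards model to one residue's curves.

    Chi-square-weighted least squares with dw_ppm shared across fields and
    R2_0 free per field; ``n_starts`` seeded starting points over a
    (pA, kex, dw) grid guard against local minima; parameter uncertainties
    come from resampling points with replacement (``n_bootstrap`` refits,
    95% percentile intervals).
    """
    _check_curve_set(curves)
    fields = sorted({c.field.proton_mhz for c in curves})
    rng = np.random.default_rng(seed)
    lower = np.array([0.5, 0.0, 0.0] + [0.01] * len(fields))
    upper = np.array([1.0 - 1e-9, 5.5, 20.0] + [300.0] * len(fields))

    best = None
    n_ok = 0
    for x0 in _multistart_grid(curves, fields, n_starts, rng):
        try:
            sol = scipy.optimize.least_squares(
                _exchange_residuals, np.clip(x0, lower, upper),
                bounds=(lower, upper), args=(curves, fields), method="trf")
        except Exception:  # pragma: no cover - defensive
            continue
        if sol.success:
            n_ok += 1
        if best is None or sol.cost < best.cost:
            best = sol

    n = sum(c.n_points for c in curves)
    k = 3 + len(fields)
    if best is None or n_ok == 0:
        return FitResult("exchange", None, None, math.inf, math.inf, n, k,
                         success=False, message="no start converged")

    x = best.x
    params = TwoStateParams(x[0], 10.0 ** x[1], x[2],
                            {mhz: x[3 + i] for i, mhz in enumerate(fields)})
    chi2 = float(2.0 * best.cost)
    result = FitResult("exchange", params, None, chi2, _aicc(chi2, k, n), n, k,
                       residuals=best.fun, success=True)

    if n_bootstrap > 0:
        samples = _bootstrap(curves, fields, x, lower, upper, n_bootstrap, rng)
        if samples is not None:
            names = ["pA", "kex", "dw_ppm"] + [f"r2_0_{mhz:g}" for mhz in fields]
            vals = samples.copy()
            vals[:, 1] = 10.0 ** vals[:, 1]
            for j, name in enumerate(names):
                result.param_sigma[name] = float(np.std(vals[:, j]))
                lo, hi = np.percentile(vals[:, j], [2.5, 97.5])
                result.param_ci[name] = (float(lo), float(hi))
    return result


def _bootstrap(curves, fields, x_best, lower, upper, n_bootstrap, rng):
    samples = []
    for _ in range(n_bootstrap):
        boot = []
        for c in curves:
            idx = rng.integers(0, c.n_points, size=c.n_points)
            boot.append((c.nu_cpmg[idx], c.r2eff[idx], c.sigma[idx], c.field, c.nucleus))
        def resid(x, boot=boot):
            pA, log10_kex, dw = x[0], x[1], x[2]
            r2_0 = {mhz: x[3 + i] for i, mhz in enumerate(fields)}
            params = TwoStateParams(pA, 10.0 ** log10_kex, dw, r2_0)
            out = []
            for nu, y, sg, fld, nuc in boot:
                order = np.argsort(nu)
                calc = np.empty_like(nu)
                calc[order] = np.asarray(cr_r2eff(params, fld, nu[order], nuc))
                out.append((y - calc) / _weights(sg))
            return np.concatenate(out)
        try:
            sol = scipy.optimize.least_squares(resid, x_best, bounds=(lower, upper),
                                               method="trf", max_nfev=200)
        except Exception:  # pragma: no cover
            continue
        samples.append(sol.x)
    if not samples:
        return None
    return np.array(samples)


def select_model(fit_exchange: FitResult, fit_no_exchange: FitResult) -> str:
    """AICc model selection; ties break to the parsimonious flat model."""
    if fit_exchange.n_points != fit_no_exchange.n_points:
        raise ValueError("model selection requires fits on identical data")
    if fit_exchange.aicc < fit_no_exchange.aicc:
        return "exchange"
    return "no-exchange"


def analyze_residue(curves: Sequence[DispersionCurve], *,
                    rex_threshold: float = REX_THRESHOLD,
                    seed: int = 20250101, n_starts: int = 20,
                    n_bootstrap: int = 200) -> dict:
    """Fit both models, select by AICc, and report per-field Rex.

    Returns a JSON-serializable record mirroring the fitted-output schema:
    residue, model, pA, kex_rad_s, dw_ppm, r2_0_by_field, rex_by_field,
    chi2, aicc.
    """
    fit_ex = fit_dispersion(curves, n_starts=n_starts, seed=seed,
                            n_bootstrap=n_bootstrap)
    fit_no = fit_flat(curves)
    label = select_model(fit_ex, fit_no) if fit_ex.success else "no-exchange"
    fields = sorted({c.field.proton_mhz for c in curves})
    record: dict = {"residue": curves[0].residue, "model": label,
                    "chi2": fit_no.chi2 if label == "no-exchange" else fit_ex.chi2,
                    "aicc": fit_no.aicc if label == "no-exchange" else fit_ex.aicc}
    if label == "exchange" and fit_ex.params is not None:
        p = fit_ex.params
        record.update(pA=p.pA, kex_rad_s=p.kex, dw_ppm=p.dw_ppm,
                      r2_0_by_field={mhz: p.r2_0[mhz] for mhz in fields},
                      rex_by_field={mhz: rex(p, FieldContext(mhz),
                                             threshold=rex_threshold).value
                                    for mhz in fields},
                      param_sigma=fit_ex.param_sigma)
        record["flagged"] = {mhz: record["rex_by_field"][mhz] > rex_threshold
                             for mhz in fields}
    else:
        record.update(pA=None, kex_rad_s=None, dw_ppm=None,
                      r2_0_by_field=fit_no.r2_flat,
                      rex_by_field={mhz: 0.0 for mhz in fields},
                      flagged={mhz: False for mhz in fields})
    return record


# ---------------------------------------------------------------------------
# tabular I/O

def curves_to_frame(curves: Iterable[DispersionCurve]):
    import pandas as pd
    rows = []
    for c in curves:
        for nu, y, sg in zip(c.nu_cpmg, c.r2eff, c.sigma):
            rows.append({"residue": c.residue, "nucleus": c.nucleus,
                         "field_mhz": c.field.proton_mhz, "nu_cpmg_hz": nu,
                         "r2eff": y, "r2eff_err": sg})
    return pd.DataFrame(rows)


def curves_from_frame(frame, trelax: float = DEFAULT_TRELAX) -> list[DispersionCurve]:
    out = []
    for (res, nuc, mhz), grp in frame.groupby(["residue", "nucleus", "field_mhz"]):
        grp = grp.sort_values("nu_cpmg_hz")
        out.append(DispersionCurve(int(res), FieldContext(float(mhz)),
                                   grp["nu_cpmg_hz"].to_numpy(),
                                   grp["r2eff"].to_numpy(),
                                   grp["r2eff_err"].to_numpy(),
                                   nucleus=str(nuc), trelax=trelax))
    return out


def read_dispersion_tsv(path, trelax: float = DEFAULT_TRELAX) -> list[DispersionCurve]:
    import pandas as pd
    return curves_from_frame(pd.read_csv(path, sep="\t"), trelax)


def write_dispersion_tsv(curves: Iterable[DispersionCurve], path) -> None:
    curves_to_frame(curves).to_csv(path, sep="\t", index=False)
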