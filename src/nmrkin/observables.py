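"""Trajectory-derived ensemble observables.

Lipari-Szabo S^2 order parameters from bond-vector series, r^-6-averaged
distances governing NOE visibility, distance histograms, and the
methyl-to-geometric-centre distance used when one partner is a pair of
prochiral methyl groups.  Bond vectors are assumed to be expressed in a
molecule-fixed frame (overall tumbling removed); superposing each frame on
a reference selection with :mod:`nmrkin.structure` is the documented
preprocessing path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

NOE_CUTOFF = 10.0  # Angstrom; methyl-methyl NOEs are typically seen to ~10 A


def s2(vectors: np.ndarray) -> float:
    """Generalized order parameter of a bond-vector series.

    S^2 = (3/2) sum_{a,b in xyz} <e_a e_b>^2 - 1/2 over unit vectors e;
    1 for a static vector, 0 in the isotropic limit.
    """
    v = np.asarray(vectors, dtype=float)
    if v.ndim != 2 or v.shape[1] != 3:
        raise ValueError("vectors must be an (n, 3) array")
    if v.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    norms = np.linalg.norm(v, axis=1)
    if (norms == 0).any():
        raise ValueError("zero-length bond vector")
    e = v / norms[:, None]
    outer = np.einsum("ni,nj->ij", e, e) / e.shape[0]
    return float(1.5 * np.sum(outer**2) - 0.5)


def r6_mean_distance(distances: np.ndarray) -> float:
    """NOE-relevant ensemble average <r^-6>^(-1/6) in the input units."""
    r = np.asarray(distances, dtype=float)
    if r.size == 0:
        raise ValueError("empty distance series")
    if (r <= 0).any():
        raise ValueError("distances must be positive")
    return float(np.mean(r**-6.0) ** (-1.0 / 6.0))


@dataclass
class HistogramResult:
    edges: np.ndarray    # Angstrom
    density: np.ndarray  # per Angstrom; integrates to 1

    def __post_init__(self) -> None:
        if (self.density < 0).any():
            raise ValueError("density must be non-negative")
        area = float(np.sum(self.density * np.diff(self.edges)))
        if abs(area - 1.0) > 1e-8:
            raise ValueError("density must integrate to 1")


def distance_histogram(distances: np.ndarray, edges: np.ndarray) -> HistogramResult:
    """Normalized distance histogram on the given bin edges."""
    density, out_edges = np.histogram(np.asarray(distances, float),
                                      bins=np.asarray(edges, float), density=True)
    return HistogramResult(out_edges, density)


def methyl_center_distance(atom_xyz: np.ndarray, pair_xyz: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    """Per-frame distance from one atom to the midpoint of an atom pair.

    Used for NOEs to prochiral methyl pairs, measured to the geometric
    centre of the two methyl carbons.
    """
    a = np.asarray(atom_xyz, dtype=float)
    p1 = np.asarray(pair_xyz[0], dtype=float)
    p2 = np.asarray(pair_xyz[1], dtype=float)
    if not (a.shape == p1.shape == p2.shape) or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("all inputs must be matching (n, 3) arrays")
    center = 0.5 * (p1 + p2)
    return np.linalg.norm(a - center, axis=1)


def noe_visibility(r6_distance: float, cutoff: float = NOE_CUTOFF) -> bool:
    """An NOE is expected when the r^-6-averaged distance is within the
    cutoff (inclusive; default 10 A for methyl-methyl contacts)."""
    if r6_distance <= 0:
        raise ValueError("distance must be positive")
    return bool(r6_distance <= cutoff)


# ---------------------------------------------------------------------------
# TSV I/O

def read_vector_series(path) -> np.ndarray:
    """TSV with columns frame, x, y, z -> (n, 3) array ordered by frame."""
    df = pd.read_csv(path, sep="\t").sort_values("frame")
    return df[["x", "y", "z"]].to_numpy(dtype=float)


def write_vector_series(vectors: np.ndarray, path) -> None:
    v = np.asarray(vectors, dtype=float)
    pd.DataFrame({"frame": np.arange(len(v)), "x": v[:, 0], "y": v[:, 1],
                  "z": v[:, 2]}).to_csv(path, sep="\t", index=False)


def read_distance_series(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t").sort_values("frame")
    return df["r"].to_numpy(dtype=float)


def write_distance_series(distances: np.ndarray, path) -> None:
    r = np.asarray(distances, dtype=float)
    pd.DataFrame({"frame": np.arange(len(r)), "r": r}).to_csv(path, sep="\t", index=False)


def write_histogram(hist: HistogramResult, path) -> None:
    pd.DataFrame({"edge_lo": hist.edges[:-1], "edge_hi": hist.edges[1:],
                  "density": hist.density}).to_csv(path, sep="\t", index=False)
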