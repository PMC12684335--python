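"""Shared fixtures-adjacent helpers for the test suite."""

import numpy as np


def metastable_counts(n_blocks: int, per_block: int = 3, intra_hop: float = 0.08,
                      inter: float = 0.01, total: float = 2000.0,
                      seed: int = 0, jitter: float = 0.2) -> np.ndarray:
    """Transition counts from a planted block-metastable transition matrix.

    Self-transition probability ~1 - intra_hop - inter; within-block hops
    are fast relative to the small inter-block leakage, giving a clean
    metastable spectrum with ``n_blocks`` eigenvalues near one.
    """
    n = n_blocks * per_block
    t = np.zeros((n, n))
    block = np.repeat(np.arange(n_blocks), per_block)
    rng = np.random.default_rng(seed)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            base = (intra_hop / (per_block - 1) if block[i] == block[j]
                    else inter / (n - per_block))
            t[i, j] = base * (1.0 + jitter * rng.uniform(-1, 1))
    np.fill_diagonal(t, 1.0 - t.sum(axis=1))
    return np.round(t * total)
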