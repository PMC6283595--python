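"""Independent reference implementations used by several test modules."""
import itertools

import numpy as np
from scipy import stats as sps


def enumeration_oracle(diffs: np.ndarray) -> tuple[float, float]:
    """Full 2^n enumeration of the sign-flip null on the observed ranks."""
    diffs = np.asarray(diffs, dtype=float)
    diffs = diffs[diffs != 0]
    n = len(diffs)
    ranks = sps.rankdata(np.abs(diffs))
    w_obs = ranks[diffs > 0].sum()
    w_all = np.array(
        [np.asarray(signs).dot(ranks)
         for signs in itertools.product([0, 1], repeat=n)]
    )
    p_le = np.mean(w_all <= w_obs + 1e-12)
    p_ge = np.mean(w_all >= w_obs - 1e-12)
    return w_obs, min(1.0, 2 * min(p_le, p_ge))


def naive_digest(seq: str, site: str) -> list[tuple[int, int]]:
    """Character-by-character restriction-site scan."""
    seq, site = seq.upper(), site.upper()
    cuts = [i for i in range(len(seq) - len(site) + 1)
            if seq[i: i + len(site)] == site]
    edges = [0] + cuts + [len(seq)]
    return [(a, b) for a, b in zip(edges, edges[1:]) if b > a]


def decayed_block_matrix(
    n: int,
    boundaries: list[int],
    rng: np.random.Generator,
    near_diag: float = 100.0,
    contrast: float = 4.0,
    alpha: float = 0.6,
) -> np.ndarray:
    """Poisson-sampled symmetric matrix with planted domain boundaries.

    Expected counts decay with bin distance (near-diagonal expectation
    ``near_diag``) and are divided by ``contrast`` for cells straddling any
    planted boundary (a boundary at k separates bins < k from bins >= k).
    """
    idx = np.arange(n)
    d = np.abs(idx[:, None] - idx[None, :])
    mu = near_diag / np.maximum(d, 1.0) ** alpha
    domain = np.zeros(n, dtype=int)
    for b in boundaries:
        domain[b:] += 1
    straddle = domain[:, None] != domain[None, :]
    mu = np.where(straddle, mu / contrast, mu)
    upper = rng.poisson(np.triu(mu))
    return (upper + np.triu(upper, 1).T).astype(float)
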