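"""Independent brute-force oracles used to validate the fast implementations.

Each oracle recomputes a quantity from first principles (exhaustive
search, all-pairs scan, full enumeration, exact rational arithmetic) and
deliberately shares no code path with the implementation it checks.
"""

from __future__ import annotations

import itertools
from fractions import Fraction

import numpy as np
from scipy.stats import rankdata


def otsu_exhaustive(values, n_bins: int = 256) -> float:
    """Exhaustively score every histogram split by between-class variance.

    Exact rational arithmetic; ties keep the lowest split. Returns the
    winning interior bin edge.
    """
    vals = np.asarray(values, dtype=float).ravel()
    lo, hi = float(vals.min()), float(vals.max())
    counts, edges = np.histogram(vals, bins=n_bins, range=(lo, hi))
    total = int(counts.sum())
    centers = [Fraction(2 * i + 1) for i in range(n_bins)]  # affine-equivalent
    best_k, best_score = None, None
    for k in range(n_bins - 1):
        w0 = int(counts[: k + 1].sum())
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        m0 = sum(int(c) * ctr for c, ctr in zip(counts[: k + 1], centers[: k + 1])) / Fraction(w0)
        m1 = sum(int(c) * ctr for c, ctr in zip(counts[k + 1 :], centers[k + 1 :])) / Fraction(w1)
        score = Fraction(w0) * Fraction(w1) * (m0 - m1) ** 2
        if best_score is None or score > best_score:
            best_k, best_score = k, score
    return float(edges[1:-1][best_k])


def otsu_exhaustive_exact_bins(values) -> float:
    """Per-value-bin variant: candidate thresholds are the distinct values."""
    vals = np.asarray(values, dtype=float).ravel()
    uniq = np.unique(vals)
    best_t, best_score = None, None
    for t in uniq[:-1]:
        c0, c1 = vals[vals <= t], vals[vals > t]
        w0, w1 = Fraction(len(c0)), Fraction(len(c1))
        m0 = sum(Fraction(v) for v in c0) / w0
        m1 = sum(Fraction(v) for v in c1) / w1
        score = w0 * w1 * (m0 - m1) ** 2
        if best_score is None or score > best_score:
            best_t, best_score = float(t), score
    return best_t


def brute_force_distance_um(mask: np.ndarray, pixel_size_um: float) -> np.ndarray:
    """All-pairs nearest-true-pixel Euclidean distance at every pixel."""
    mask = np.asarray(mask, dtype=bool)
    true_rc = np.argwhere(mask)
    out = np.empty(mask.shape, dtype=float)
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            d2 = (true_rc[:, 0] - r) ** 2 + (true_rc[:, 1] - c) ** 2
            out[r, c] = np.sqrt(d2.min())
    return out * pixel_size_um


def nearest_distance_from_point(mask: np.ndarray, row: float, col: float, pixel_size_um: float) -> float:
    """Distance from an arbitrary (possibly sub-pixel) point to the mask."""
    true_rc = np.argwhere(np.asarray(mask, dtype=bool))
    d = np.hypot(true_rc[:, 0] - row, true_rc[:, 1] - col)
    return float(d.min() * pixel_size_um)


def mann_whitney_enumeration_p(a, b) -> float:
    """Two-sided exact p by enumerating every group-label assignment."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n1, n = a.size, pooled.size
    ranks = rankdata(pooled)
    offset = n1 * (n1 + 1) / 2

    def u_of(idx):
        return ranks[list(idx)].sum() - offset

    u_obs = u_of(range(n1))
    us = np.array([u_of(c) for c in itertools.combinations(range(n), n1)])
    cdf = (us <= u_obs).mean()
    sf = (us >= u_obs).mean()
    return float(min(1.0, 2.0 * min(cdf, sf)))
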