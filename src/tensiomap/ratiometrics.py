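"""Ratiometric tension mapping.

The tension probe (Cy5-FnBPA5) binds untensed fibronectin fibers only,
while a polyclonal antibody (FN channel) stains all fibers. Both channels
are Otsu-thresholded; on the jointly positive mask the per-pixel
probe/antibody intensity ratio maps tensional heterogeneity, and the
*untensed-pixel density* — probe-positive pixels as a percentage of all
antibody-positive pixels — summarises how much of the fiber network is
relaxed.

Conventions (fixed pipeline-wide): "positive" means intensity strictly
greater than the threshold; the Otsu histogram has ``n_bins`` equal-width
bins spanning the observed min–max; threshold ties break toward the lowest
bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._errors import ConstantImageError, EmptyFibronectinMaskError
from .image_io import MultiChannelImage, PixelMask

__all__ = [
    "otsu_threshold",
    "otsu_separability",
    "joint_mask",
    "ratio_map",
    "untensed_density",
    "RatioMap",
    "DensityResult",
]


def _between_class_variance(counts: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """sigma_b^2 for every split 'class0 = bins 0..k', k = 0..n-2."""
    w = counts / counts.sum()
    mu = w * centers
    w0 = np.cumsum(w)[:-1]
    m0 = np.cumsum(mu)[:-1]
    w1 = 1.0 - w0
    m_total = mu.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        mean0 = np.where(w0 > 0, m0 / w0, 0.0)
        mean1 = np.where(w1 > 0, (m_total - m0) / w1, 0.0)
    return w0 * w1 * (mean0 - mean1) ** 2


def otsu_threshold(intensities, n_bins: int | None = 256) -> float:
    """Histogram threshold maximizing between-class intensity variance.

    Returns a bin-edge value; pixels *strictly above* it are positive.
    ``n_bins=None`` uses exact per-value bins (candidate thresholds are the
    distinct values themselves) — useful for small discrete samples.
    Ties in the objective break toward the lowest candidate threshold.

    Raises
    ------
    ConstantImageError
        If all values are equal (no split exists).
    """
    vals = np.asarray(intensities, dtype=np.float64).ravel()
    if vals.size == 0 or not np.all(np.isfinite(vals)):
        raise ValueError("intensities must be non-empty and finite")
    lo, hi = vals.min(), vals.max()
    if lo == hi:
        raise ConstantImageError("all intensities equal; Otsu threshold undefined")
    if n_bins is None:
        centers, counts = np.unique(vals, return_counts=True)
        candidates = centers[:-1]  # split after each distinct value
        sigma_b = _between_class_variance(counts.astype(np.float64), centers)
        k = int(np.argmax(sigma_b))  # argmax returns the first (lowest) maximizer
        return float(candidates[k])
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    counts, edges = np.histogram(vals, bins=n_bins, range=(lo, hi))
    return float(edges[1:-1][_argmax_split(counts)])


def _argmax_split(counts: np.ndarray) -> int:
    """Lowest split index maximizing between-class variance, exactly.

    Ranking of splits is invariant under affine rescaling of the bin
    centers, so centers are taken as the odd integers 2i+1 and the score
    (M0*W1 - M1*W0)^2 / (W0*W1) is evaluated in integer arithmetic for
    the near-tied candidates — float rounding can otherwise flip the
    argmax between splits whose variances agree to 1 ulp.
    """
    c = counts.astype(np.int64)
    centers = 2 * np.arange(c.size, dtype=np.int64) + 1
    w0 = np.cumsum(c)[:-1]
    m0 = np.cumsum(c * centers)[:-1]
    w1 = c.sum() - w0
    m1 = (c * centers).sum() - m0
    a = (m0 * w1 - m1 * w0).astype(np.float64)
    score = a * a / (w0 * w1)  # w0, w1 >= 1: lo/hi are in the end bins
    near = np.flatnonzero(score >= score.max() * (1.0 - 1e-9))
    if near.size == 1:
        return int(near[0])
    best = None
    best_num = best_den = None
    for k in near:
        num = (int(m0[k]) * int(w1[k]) - int(m1[k]) * int(w0[k])) ** 2
        den = int(w0[k]) * int(w1[k])
        if best is None or num * best_den > best_num * den:
            best, best_num, best_den = int(k), num, den
    return best


def otsu_separability(intensities, n_bins: int = 256) -> float:
    """Otsu effectiveness eta = sigma_b^2(t*) / sigma_total^2, in [0, 1].

    Low values mean the histogram is essentially unimodal and the Otsu
    split is meaningless (used as a guard on noise-only channels).
    """
    vals = np.asarray(intensities, dtype=np.float64).ravel()
    lo, hi = vals.min(), vals.max()
    if lo == hi:
        raise ConstantImageError("all intensities equal")
    counts, edges = np.histogram(vals, bins=n_bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    sigma_b = _between_class_variance(counts.astype(np.float64), centers)
    w = counts / counts.sum()
    mean = (w * centers).sum()
    total = (w * (centers - mean) ** 2).sum()
    return float(sigma_b.max() / total) if total > 0 else 0.0


@dataclass
class RatioMap:
    """Per-pixel FNBPA5/FN intensity ratio, defined on the joint mask only.

    ``grid`` holds NaN outside the joint mask; defined values are >= 0.
    """

    grid: np.ndarray
    joint_mask: PixelMask
    fn_threshold: float
    fnbpa5_threshold: float


@dataclass
class DensityResult:
    """Untensed-pixel density: probe-positive share of the fiber mask."""

    fn_positive_px: int
    fnbpa5_positive_px: int
    untensed_density_pct: float


def joint_mask(
    image: MultiChannelImage, n_bins: int = 256
) -> tuple[PixelMask, PixelMask, PixelMask]:
    """Otsu-threshold FN and FNBPA5 and intersect the positive masks.

    Returns ``(fn_mask, fnbpa5_mask, joint)`` where ``joint`` marks pixels
    positive in both channels.
    """
    image.require("FN", "FNBPA5")
    px = image.pixel_size_um
    fn = image["FN"]
    fnbpa5 = image["FNBPA5"]
    fn_mask = PixelMask(fn > otsu_threshold(fn, n_bins), "fn_mask", px)
    fnbpa5_mask = PixelMask(fnbpa5 > otsu_threshold(fnbpa5, n_bins), "fnbpa5_mask", px)
    joint = PixelMask(fn_mask.grid & fnbpa5_mask.grid, "joint_mask", px)
    return fn_mask, fnbpa5_mask, joint


def ratio_map(
    image: MultiChannelImage,
    joint: PixelMask,
    fn_threshold: float,
    fnbpa5_threshold: float,
    background: float = 0.0,
) -> RatioMap:
    """FNBPA5/FN intensity ratio on the joint mask.

    ``background`` (a single scalar, default 0) is subtracted from both
    channels, the numerator floored at 0 and the denominator at a small
    positive epsilon (1e-6 of the FN dynamic range) to keep the map finite.
    """
    fn = image["FN"] - background
    fnbpa5 = image["FNBPA5"] - background
    span = float(np.ptp(image["FN"]))
    eps = max(1e-6 * span, np.finfo(np.float64).tiny)
    num = np.maximum(fnbpa5, 0.0)
    den = np.maximum(fn, eps)
    grid = np.full(fn.shape, np.nan)
    grid[joint.grid] = num[joint.grid] / den[joint.grid]
    return RatioMap(grid, joint, float(fn_threshold), float(fnbpa5_threshold))


def untensed_density(fn_mask: PixelMask, fnbpa5_mask: PixelMask) -> DensityResult:
    """Percentage of FN-positive pixels that are also probe-positive.

    The numerator is restricted to the FN-positive universe, so the result
    is bounded in [0, 100] ("share of all fibronectin fiber pixels").
    """
    if fn_mask.grid.shape != fnbpa5_mask.grid.shape:
        raise ValueError("mask shapes differ")
    denom = fn_mask.count
    if denom == 0:
        raise EmptyFibronectinMaskError("fibronectin mask has no positive pixel")
    numer = int((fnbpa5_mask.grid & fn_mask.grid).sum())
    return DensityResult(denom, numer, 100.0 * numer / denom)


def measure_density(image: MultiChannelImage, n_bins: int = 256) -> DensityResult:
    """Convenience: joint masking + untensed density in one call."""
    fn_mask, fnbpa5_mask, _ = joint_mask(image, n_bins=n_bins)
    return untensed_density(fn_mask, fnbpa5_mask)
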