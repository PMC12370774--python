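"""Platelet-to-fiber proximity statistics.

For every detected platelet the distance from its centroid to the nearest
untensed (probe-positive) and nearest stretched (probe-negative fiber)
pixel is read off exact Euclidean distance transforms of the two masks,
converted to µm. A platelet is "in contact" with a tension class when that
distance satisfies the contact rule; because the two masks are distinct, a
single platelet can be in contact with both classes at once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from ._errors import EmptyGroupError, EmptyMaskError
from .image_io import PixelMask

__all__ = [
    "distance_transform",
    "platelet_distances",
    "summarize_proximity",
    "ContactRule",
]


def distance_transform(mask, pixel_size_um: float | None = None) -> np.ndarray:
    """Exact Euclidean distance (µm) to the nearest mask-positive pixel.

    Distances are measured between pixel centers; pixels inside the mask
    have distance 0. Raises :class:`EmptyMaskError` on an all-false mask.
    """
    if isinstance(mask, PixelMask):
        grid, px = mask.grid, mask.pixel_size_um
    else:
        grid, px = np.asarray(mask, dtype=bool), pixel_size_um
        if px is None or not px > 0:
            raise ValueError("pixel_size_um required for a bare array mask")
    if not grid.any():
        raise EmptyMaskError("distance transform of an empty mask is undefined")
    return ndimage.distance_transform_edt(~grid) * px


@dataclass(frozen=True)
class ContactRule:
    """Decides when a centroid-to-pixel distance counts as contact.

    mode="radius" (default): contact iff distance <= platelet equivalent
    radius + half a pixel — a centroid within its own radius of a target
    pixel means the object overlaps the target. mode="fixed": contact iff
    distance <= ``tolerance_um``.
    """

    mode: str = "radius"
    tolerance_um: float | None = None

    def __post_init__(self):
        if self.mode not in {"radius", "fixed"}:
            raise ValueError(f"unknown contact rule mode {self.mode!r}")
        if self.mode == "fixed" and (self.tolerance_um is None or self.tolerance_um < 0):
            raise ValueError("fixed contact rule needs tolerance_um >= 0")

    def threshold_um(self, equivalent_radius_um, pixel_size_um: float):
        if self.mode == "fixed":
            return np.full_like(np.asarray(equivalent_radius_um, float), self.tolerance_um)
        return np.asarray(equivalent_radius_um, float) + 0.5 * pixel_size_um


def _sample(dt: np.ndarray, rows, cols, interpolation: str) -> np.ndarray:
    order = 1 if interpolation == "bilinear" else 0
    return ndimage.map_coordinates(dt, np.vstack([rows, cols]), order=order, mode="nearest")


def platelet_distances(
    platelets: pd.DataFrame,
    untensed_mask: PixelMask,
    stretched_mask: PixelMask,
    contact_rule: ContactRule = ContactRule(),
    interpolation: str = "bilinear",
) -> pd.DataFrame:
    """Per-platelet distances (µm) to the nearest pixel of each tension class.

    ``platelets`` needs columns ``object_id``, ``centroid_row``,
    ``centroid_col`` and (for the radius contact rule)
    ``equivalent_radius_um``. Sub-pixel centroids sample the distance grid
    by bilinear interpolation (``interpolation="nearest"`` for
    nearest-pixel sampling). An empty target mask yields NaN distances for
    that class, flagged in the ``undefined_*`` QC columns and excluded from
    downstream means.
    """
    px = untensed_mask.pixel_size_um
    n = len(platelets)
    out = platelets[["object_id", "centroid_row", "centroid_col"]].copy()
    rows = platelets["centroid_row"].to_numpy(float)
    cols = platelets["centroid_col"].to_numpy(float)
    for cls, mask in (("untensed", untensed_mask), ("stretched", stretched_mask)):
        try:
            dt = distance_transform(mask)
            d = _sample(dt, rows, cols, interpolation)
            undefined = np.zeros(n, dtype=bool)
        except EmptyMaskError:
            d = np.full(n, np.nan)
            undefined = np.ones(n, dtype=bool)
        out[f"d_{cls}_um"] = d
        out[f"undefined_{cls}"] = undefined
    radii = (
        platelets["equivalent_radius_um"].to_numpy(float)
        if "equivalent_radius_um" in platelets
        else np.zeros(n)
    )
    thr = contact_rule.threshold_um(radii, px)
    for cls in ("untensed", "stretched"):
        d = out[f"d_{cls}_um"].to_numpy()
        out[f"in_contact_{cls}"] = (d <= thr) & ~np.isnan(d)
    return out


def summarize_proximity(
    records: pd.DataFrame, grouping: str | None = None
) -> pd.DataFrame:
    """Per-group contact percentages and mean distances.

    Contact percentages are taken over records with a defined distance for
    that class; the two percentages need not sum to 100 (a platelet can
    touch both classes). Raises :class:`EmptyGroupError` if a group has no
    record with any defined distance.
    """
    if grouping is None:
        groups = [("all", records)]
    else:
        groups = list(records.groupby(grouping, sort=True))
    rows = []
    for key, df in groups:
        if len(df) == 0 or df[["d_untensed_um", "d_stretched_um"]].isna().all().all():
            raise EmptyGroupError(f"group {key!r} has no usable proximity record")
        row = {"group": key, "n_platelets": len(df)}
        for cls in ("stretched", "untensed"):
            d = df[f"d_{cls}_um"]
            defined = d.notna()
            row[f"n_defined_{cls}"] = int(defined.sum())
            row[f"pct_contact_{cls}"] = (
                100.0 * df.loc[defined, f"in_contact_{cls}"].mean() if defined.any() else np.nan
            )
            row[f"mean_d_{cls}_um"] = float(d[defined].mean()) if defined.any() else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
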