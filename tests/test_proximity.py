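"""Distance transforms, per-platelet distances and proximity summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from tensiomap import EmptyGroupError, EmptyMaskError
from tensiomap.image_io import PixelMask
from tensiomap.proximity import (
    ContactRule,
    distance_transform,
    platelet_distances,
    summarize_proximity,
)

from .oracles import brute_force_distance_um, nearest_distance_from_point


def mask(grid, px=0.5):
    return PixelMask(np.asarray(grid, bool), "m", px)


def platelet_df(rows_cols, radius_um=1.0):
    return pd.DataFrame(
        [
            {
                "object_id": i + 1,
                "centroid_row": r,
                "centroid_col": c,
                "equivalent_radius_um": radius_um,
            }
            for i, (r, c) in enumerate(rows_cols)
        ]
    )


class TestDistanceTransform:
    def test_inside_mask_is_zero(self, rng):
        grid = rng.random((16, 16)) > 0.7
        grid[3, 3] = True
        dt = distance_transform(mask(grid))
        assert dt[3, 3] == 0.0
        assert (dt[grid] == 0.0).all()

    def test_three_four_five_triangle(self):
        grid = np.zeros((8, 8), bool)
        grid[0, 0] = True
        dt = distance_transform(mask(grid, px=0.5))
        assert dt[3, 4] == pytest.approx(2.5)

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyMaskError):
            distance_transform(mask(np.zeros((8, 8))))

    @given(grid=hnp.arrays(bool, (16, 16)), px=st.sampled_from([0.25, 0.5, 1.0]))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_matches_brute_force(self, grid, px):
        if not grid.any():
            return
        dt = distance_transform(mask(grid, px=px))
        np.testing.assert_allclose(dt, brute_force_distance_um(grid, px), atol=1e-9)

    def test_lipschitz_bound(self, rng):
        grid = rng.random((32, 32)) > 0.9
        grid[0, 0] = True
        px = 0.5
        dt = distance_transform(mask(grid, px=px))
        assert np.abs(np.diff(dt, axis=0)).max() <= px * np.sqrt(2) + 1e-12
        assert np.abs(np.diff(dt, axis=1)).max() <= px * np.sqrt(2) + 1e-12

    def test_monotone_under_mask_growth(self, rng):
        grid = rng.random((24, 24)) > 0.9
        grid[5, 5] = True
        bigger = grid | (rng.random((24, 24)) > 0.85)
        d1 = distance_transform(mask(grid))
        d2 = distance_transform(mask(bigger))
        assert (d2 <= d1 + 1e-12).all()


class TestPlateletDistances:
    def test_centroid_on_untensed_pixel(self):
        unt = np.zeros((16, 16), bool)
        unt[5, 5] = True
        stre = np.zeros((16, 16), bool)
        stre[10, 10] = True
        rec = platelet_distances(platelet_df([(5, 5)]), mask(unt), mask(stre))
        assert rec.d_untensed_um[0] == 0.0
        assert rec.in_contact_untensed[0]

    def test_integer_centroid_matches_brute_force(self, rng):
        unt = rng.random((20, 20)) > 0.85
        stre = rng.random((20, 20)) > 0.85
        unt[2, 17] = True
        stre[18, 1] = True
        rec = platelet_distances(platelet_df([(7, 11)]), mask(unt), mask(stre))
        assert rec.d_untensed_um[0] == pytest.approx(
            nearest_distance_from_point(unt, 7, 11, 0.5), abs=1e-9
        )
        assert rec.d_stretched_um[0] == pytest.approx(
            nearest_distance_from_point(stre, 7, 11, 0.5), abs=1e-9
        )

    def test_subpixel_centroid_close_to_brute_force(self, rng):
        """Bilinear sampling of the distance grid is within half a pixel
        diagonal of the true point-to-mask distance."""
        grid = rng.random((20, 20)) > 0.9
        grid[4, 4] = True
        px = 0.5
        rec = platelet_distances(
            platelet_df([(7.3, 11.6)]), mask(grid, px), mask(grid, px)
        )
        truth = nearest_distance_from_point(grid, 7.3, 11.6, px)
        assert abs(rec.d_untensed_um[0] - truth) <= px * np.sqrt(2) / 2

    def test_empty_untensed_mask_flagged_not_fatal(self):
        stre = np.zeros((16, 16), bool)
        stre[3, 3] = True
        rec = platelet_distances(
            platelet_df([(8, 8)]), mask(np.zeros((16, 16))), mask(stre)
        )
        assert np.isnan(rec.d_untensed_um[0])
        assert rec.undefined_untensed[0]
        assert np.isfinite(rec.d_stretched_um[0])

    def test_fixed_contact_rule(self):
        unt = np.zeros((16, 16), bool)
        unt[0, 0] = True
        stre = unt.copy()
        rec = platelet_distances(
            platelet_df([(0, 4)]),  # 2 µm away at 0.5 µm px
            mask(unt),
            mask(stre),
            contact_rule=ContactRule("fixed", 2.5),
        )
        assert rec.in_contact_untensed[0]
        rec2 = platelet_distances(
            platelet_df([(0, 4)]), mask(unt), mask(stre), ContactRule("fixed", 1.0)
        )
        assert not rec2.in_contact_untensed[0]


class TestSummary:
    def _records(self, d_untensed, d_stretched, contact_u=None, contact_s=None):
        n = len(d_untensed)
        return pd.DataFrame(
            {
                "object_id": range(n),
                "centroid_row": [0] * n,
                "centroid_col": [0] * n,
                "d_untensed_um": d_untensed,
                "d_stretched_um": d_stretched,
                "undefined_untensed": [v != v for v in d_untensed],
                "undefined_stretched": [v != v for v in d_stretched],
                "in_contact_untensed": contact_u or [d == 0 for d in d_untensed],
                "in_contact_stretched": contact_s or [d == 0 for d in d_stretched],
            }
        )

    def test_all_contact_gives_100_pct(self):
        recs = self._records([0.0, 0.0, 0.0], [0.0, 0.0, 0.0])
        summ = summarize_proximity(recs)
        assert summ.pct_contact_stretched[0] == 100.0

    def test_mean_distance(self):
        recs = self._records([0.0, 2.0, 4.0], [1.0, 1.0, 1.0])
        assert summarize_proximity(recs).mean_d_untensed_um[0] == pytest.approx(2.0)

    def test_contact_with_both_classes_allowed(self):
        recs = self._records(
            [0.0, 0.0], [0.0, 0.0],
            contact_u=[True, True], contact_s=[True, True],
        )
        summ = summarize_proximity(recs)
        assert summ.pct_contact_untensed[0] == 100.0
        assert summ.pct_contact_stretched[0] == 100.0

    def test_undefined_excluded_from_means(self):
        recs = self._records([np.nan, 2.0], [0.0, 0.0])
        summ = summarize_proximity(recs)
        assert summ.mean_d_untensed_um[0] == pytest.approx(2.0)
        assert summ.n_defined_untensed[0] == 1

    def test_empty_group_raises(self):
        recs = self._records([np.nan], [np.nan])
        with pytest.raises(EmptyGroupError):
            summarize_proximity(recs)

    def test_grouping(self):
        recs = pd.concat(
            [
                self._records([0.0], [0.0]).assign(image="a"),
                self._records([2.0], [2.0]).assign(image="b"),
            ]
        )
        summ = summarize_proximity(recs, grouping="image")
        assert list(summ.group) == ["a", "b"]
        assert summ.loc[summ.group == "b", "mean_d_untensed_um"].item() == 2.0
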