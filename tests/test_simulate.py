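"""Generator contracts: label calibration, object coupling, rendering, determinism."""

import numpy as np
import pandas as pd
import pytest

from tensiomap import ConfigError, PlacementError
from tensiomap.proximity import distance_transform
from tensiomap.simulate import (
    SceneParams,
    TensionLabel,
    generate_fiber_network,
    place_objects,
    render_channels,
    simulate_scene,
)

from .oracles import nearest_distance_from_point


def realized_fraction(truth):
    return (truth.tension_label == TensionLabel.UNTENSED).sum() / truth.fiber_mask.sum()


class TestFiberNetwork:
    @pytest.mark.parametrize("f,expect", [(0.0, 0.0), (1.0, 1.0)])
    def test_fraction_boundaries(self, f, expect):
        truth = generate_fiber_network(SceneParams(untensed_fraction=f, seed=1))
        assert realized_fraction(truth) == expect

    def test_quantile_calibration(self):
        """Realized untensed fraction is pinned to f by direct label count."""
        truth = generate_fiber_network(SceneParams(untensed_fraction=0.4, seed=7))
        n_fiber = truth.fiber_mask.sum()
        assert n_fiber >= 10_000
        assert abs(realized_fraction(truth) - 0.4) <= 0.02

    @pytest.mark.parametrize("f", [0.1, 0.25, 0.6, 0.8])
    def test_calibration_across_fractions(self, f):
        truth = generate_fiber_network(SceneParams(untensed_fraction=f, seed=11))
        assert abs(realized_fraction(truth) - f) <= 0.02

    def test_labels_exactly_on_fiber_mask(self):
        truth = generate_fiber_network(SceneParams(seed=3))
        assert np.array_equal(truth.tension_label != TensionLabel.NONE, truth.fiber_mask)

    def test_labels_form_patches(self):
        """Spatially correlated labels: most untensed pixels touch another one."""
        truth = generate_fiber_network(SceneParams(seed=3))
        unt = truth.tension_label == TensionLabel.UNTENSED
        from scipy import ndimage

        neighbor = ndimage.convolve(unt.astype(int), np.ones((3, 3)), mode="constant")
        frac_isolated = (unt & (neighbor == 1)).sum() / unt.sum()
        assert frac_isolated < 0.05

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"untensed_fraction": 1.2},
            {"untensed_fraction": -0.1},
            {"contact_fraction": 2.0},
            {"image_shape": (32, 512)},
            {"pixel_size_um": 0.0},
            {"snr": 0.0},
            {"n_fibers": 0},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            SceneParams(**kwargs)


class TestPlacement:
    def test_no_platelets(self):
        params = SceneParams(n_platelets=0, n_nucleated=4, seed=2)
        truth = place_objects(params, generate_fiber_network(params))
        tab = truth.object_table
        assert (tab["class"] == "platelet").sum() == 0
        assert (tab["class"] == "nucleated").sum() == 4

    def test_full_contact_distances(self):
        """p=1: every platelet centroid within sqrt(2) px of a stretched pixel."""
        params = SceneParams(contact_fraction=1.0, n_platelets=20, seed=4)
        truth = place_objects(params, generate_fiber_network(params))
        stretched = truth.tension_label == TensionLabel.STRETCHED
        plat = truth.object_table[truth.object_table["class"] == "platelet"]
        for _, obj in plat.iterrows():
            d = nearest_distance_from_point(
                stretched, obj.centroid_row, obj.centroid_col, params.pixel_size_um
            )
            assert d <= np.sqrt(2) * params.pixel_size_um

    def test_contact_seeded_count_is_rounded_fraction(self):
        params = SceneParams(contact_fraction=0.8, n_platelets=50, seed=6)
        truth = place_objects(params, generate_fiber_network(params))
        plat = truth.object_table[truth.object_table["class"] == "platelet"]
        assert int(plat["contact_seeded"].sum()) == 40

    def test_offset_mean_recovered(self):
        """Non-contact nearest-stretched distances average to offset_distance_um."""
        dists = []
        for seed in range(4):
            params = SceneParams(contact_fraction=0.0, n_platelets=30, seed=seed)
            truth = place_objects(params, generate_fiber_network(params))
            dt = distance_transform(
                truth.tension_label == TensionLabel.STRETCHED, params.pixel_size_um
            )
            from scipy.ndimage import map_coordinates

            plat = truth.object_table[truth.object_table["class"] == "platelet"]
            dists.append(
                map_coordinates(
                    dt,
                    np.vstack([plat.centroid_row, plat.centroid_col]),
                    order=1,
                )
            )
        d = np.concatenate(dists)
        se = d.std(ddof=1) / np.sqrt(d.size)
        assert abs(d.mean() - params.offset_distance_um) <= 3 * se

    def test_centroid_spacing_invariant(self):
        params = SceneParams(seed=8)
        truth = place_objects(params, generate_fiber_network(params))
        tab = truth.object_table
        rc = tab[["centroid_row", "centroid_col"]].to_numpy()
        from scipy.spatial.distance import pdist

        min_um = pdist(rc).min() * params.pixel_size_um
        assert min_um >= 2 * params.platelet_radius_um

    def test_centroids_inside_image(self):
        params = SceneParams(seed=8)
        truth = place_objects(params, generate_fiber_network(params))
        rows, cols = params.image_shape
        tab = truth.object_table
        assert tab.centroid_row.between(0, rows - 1).all()
        assert tab.centroid_col.between(0, cols - 1).all()

    def test_placement_failure_is_clear(self):
        # far too many platelets for the area -> bounded rejection, clear error
        params = SceneParams(n_platelets=5000, seed=1)
        with pytest.raises(PlacementError, match="spacing"):
            place_objects(params, generate_fiber_network(params))

    def test_all_untensed_blocks_contact_placement(self):
        params = SceneParams(untensed_fraction=1.0, n_platelets=5, seed=1)
        with pytest.raises(PlacementError, match="stretched"):
            place_objects(params, generate_fiber_network(params))


class TestRendering:
    def test_noiseless_probe_support_equals_untensed(self, noiseless_scene):
        truth, image = noiseless_scene
        support = image["FNBPA5"] > truth.params.background_level
        assert np.array_equal(support, truth.tension_label == TensionLabel.UNTENSED)

    def test_no_nucleated_means_flat_dapi(self):
        params = SceneParams(n_nucleated=0, snr=np.inf, psf_sigma_px=0.0, seed=2)
        _, image = simulate_scene(params)
        assert np.all(image["DAPI"] == params.background_level)

    def test_dapi_only_on_nucleated(self, noiseless_scene):
        truth, image = noiseless_scene
        plat = truth.object_table[truth.object_table["class"] == "platelet"]
        dapi = image["DAPI"]
        for _, obj in plat.iterrows():
            r, c = int(round(obj.centroid_row)), int(round(obj.centroid_col))
            assert dapi[r, c] == truth.params.background_level

    def test_byte_identical_reruns(self):
        params = SceneParams(seed=13)
        t1, im1 = simulate_scene(params)
        t2, im2 = simulate_scene(params)
        assert np.array_equal(t1.tension_label, t2.tension_label)
        pd.testing.assert_frame_equal(t1.object_table, t2.object_table)
        for name in im1.channels:
            assert np.array_equal(im1.channels[name], im2.channels[name])

    def test_snr_scales_noise(self):
        params_lo = SceneParams(seed=3, snr=5.0)
        params_hi = SceneParams(seed=3, snr=50.0)
        _, im_lo = simulate_scene(params_lo)
        _, im_hi = simulate_scene(params_hi)
        truth = generate_fiber_network(params_lo)
        bg = ~truth.fiber_mask

        def rel_noise(im):
            fn = im["FN"]
            return fn[bg].std() / fn.max()

        assert rel_noise(im_lo) > rel_noise(im_hi)


def test_params_yaml_round_trip(tmp_path):
    params = SceneParams(untensed_fraction=0.25, seed=99, snr=12.5)
    p = tmp_path / "params.yaml"
    params.to_yaml(p)
    assert SceneParams.from_yaml(p) == params
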