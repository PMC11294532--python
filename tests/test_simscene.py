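import numpy as np
import pytest

from ftcmap import refdata
from ftcmap import simscene as sim
from ftcmap.preprocess import QAFlag


class TestEndmemberCurves:
    def test_tree_plateau(self, tree_spec):
        ndvi, _, _ = sim.endmember_curves(tree_spec)
        assert np.abs(ndvi[17:30] - tree_spec.vmax).max() < 0.02

    def test_herb_single_peak_unimodal(self, herb_spec):
        ndvi, _, _ = sim.endmember_curves(herb_spec)
        peak = int(np.argmax(ndvi))
        assert np.all(np.diff(ndvi[: peak + 1]) > 0)
        assert np.all(np.diff(ndvi[peak:]) < 0)

    def test_degenerate_amplitude_constant(self):
        spec = sim.EndmemberSpec(
            vmin=0.5, vmax=0.5, green_up=12, senescence=34,
            steepness_up=1.0, steepness_down=1.0,
            red_base=0.1, red_min=0.1, swir_base=0.2, swir_min=0.2,
        )
        ndvi, red, swir = sim.endmember_curves(spec)
        np.testing.assert_allclose(ndvi, 0.5)
        assert np.isfinite(red).all() and np.isfinite(swir).all()

    def test_reflectance_decreases_with_greenness(self, tree_spec):
        ndvi, red, swir = sim.endmember_curves(tree_spec)
        # red and swir are affine decreasing in ndvi
        assert red[np.argmax(ndvi)] < red[np.argmin(ndvi)]
        assert swir[np.argmax(ndvi)] < swir[np.argmin(ndvi)]

    def test_inverted_season_rejected(self):
        with pytest.raises(ValueError):
            sim.EndmemberSpec(
                vmin=0.2, vmax=0.8, green_up=34, senescence=12,
                steepness_up=1.0, steepness_down=1.0,
                red_base=0.1, red_min=0.05, swir_base=0.2, swir_min=0.1,
            )


class TestSimulatePixel:
    @pytest.mark.parametrize("fraction,which", [(100.0, "tree"), (0.0, "herb")])
    def test_pure_endmember(self, fraction, which, tree_spec, herb_spec, zero_cfg):
        s = sim.simulate_pixel(fraction, 0, tree_spec, herb_spec, zero_cfg)
        spec = tree_spec if which == "tree" else herb_spec
        ndvi, red, swir = sim.endmember_curves(spec)
        np.testing.assert_allclose(s.ndvi, ndvi, atol=1e-12)
        np.testing.assert_allclose(s.red, red, atol=1e-12)
        np.testing.assert_allclose(s.swir, swir, atol=1e-12)

    def test_half_mix_is_arithmetic_mean_of_red(self, tree_spec, herb_spec, zero_cfg):
        s = sim.simulate_pixel(50.0, 0, tree_spec, herb_spec, zero_cfg)
        _, t_red, _ = sim.endmember_curves(tree_spec)
        _, h_red, _ = sim.endmember_curves(herb_spec)
        np.testing.assert_allclose(s.red, (t_red + h_red) / 2, atol=1e-12)

    def test_fraction_out_of_range_rejected(self, zero_cfg):
        with pytest.raises(ValueError):
            sim.simulate_pixel(101.0, 0, cfg=zero_cfg)

    def test_seeded_determinism(self):
        cfg = sim.SimConfig(noise_sd=0.02, cloud_prob=0.3, seed=9)
        a = sim.simulate_pixel(40.0, 3, cfg=cfg)
        b = sim.simulate_pixel(40.0, 3, cfg=cfg)
        np.testing.assert_array_equal(a.ndvi, b.ndvi)
        np.testing.assert_array_equal(a.qa, b.qa)


class TestSimulateScene:
    def test_corner_pixels_are_pure_endmembers(self, tree_spec, herb_spec, zero_cfg):
        truth = sim.SceneTruth(
            fraction=np.array([[0.0, 100.0], [50.0, 50.0]]),
            pheno_shift=np.zeros((2, 2), dtype=int),
        )
        scene = sim.simulate_scene(truth, tree_spec, herb_spec, zero_cfg)
        t_ndvi, _, _ = sim.endmember_curves(tree_spec)
        h_ndvi, _, _ = sim.endmember_curves(herb_spec)
        np.testing.assert_allclose(scene.ndvi[:, 0, 0], h_ndvi, atol=1e-12)
        np.testing.assert_allclose(scene.ndvi[:, 0, 1], t_ndvi, atol=1e-12)

    def test_same_seed_bit_identical(self):
        truth = sim.random_scene_truth(8, 8, seed=3)
        cfg = sim.SimConfig(seed=11)
        a = sim.simulate_scene(truth, cfg=cfg)
        b = sim.simulate_scene(truth, cfg=cfg)
        for name in ("ndvi", "red", "swir", "qa"):
            np.testing.assert_array_equal(getattr(a, name), getattr(b, name))

    def test_cloud_rate_matches_probability(self):
        truth = sim.random_scene_truth(16, 16, seed=5)
        scene = sim.simulate_scene(truth, cfg=sim.SimConfig(cloud_prob=0.2, seed=5))
        rate = np.mean(scene.qa == QAFlag.CLOUD)
        assert abs(rate - 0.2) < 0.05  # binomial expectation over 46*256 draws

    def test_shift_rotates_series(self, zero_cfg):
        truth = sim.SceneTruth(
            fraction=np.full((1, 2), 80.0), pheno_shift=np.array([[0, 7]])
        )
        scene = sim.simulate_scene(truth, cfg=zero_cfg)
        np.testing.assert_allclose(
            scene.ndvi[:, 0, 1], np.roll(scene.ndvi[:, 0, 0], 7), atol=1e-12
        )

    def test_mixing_monotonic_in_fraction(self, tree_spec, herb_spec, zero_cfg):
        fracs = np.linspace(0, 100, 11)
        truth = sim.SceneTruth(
            fraction=fracs.reshape(1, -1), pheno_shift=np.zeros((1, 11), dtype=int)
        )
        scene = sim.simulate_scene(truth, tree_spec, herb_spec, zero_cfg)
        t_ndvi, _, _ = sim.endmember_curves(tree_spec)
        h_ndvi, _, _ = sim.endmember_curves(herb_spec)
        season = slice(14, 32)
        assert np.all(t_ndvi[season] > h_ndvi[season])
        ndvi = scene.ndvi[season, 0, :]
        assert np.all(np.diff(ndvi, axis=1) >= -1e-12)


class TestSimulateProducts:
    def test_full_cover_all_tree(self):
        truth = sim.SceneTruth(
            fraction=np.full((2, 2), 100.0), pheno_shift=np.zeros((2, 2), int)
        )
        for p in sim.simulate_products(truth, sim.SimConfig.zero_error(subgrid_factor=5)):
            assert (p == 1).all()

    def test_zero_cover_no_tree(self):
        truth = sim.SceneTruth(
            fraction=np.zeros((2, 2)), pheno_shift=np.zeros((2, 2), int)
        )
        for p in sim.simulate_products(truth, sim.SimConfig.zero_error(subgrid_factor=5)):
            assert (p == 0).all()

    def test_exact_quota_per_cell(self):
        truth = sim.SceneTruth(
            fraction=np.full((3, 3), 40.0), pheno_shift=np.zeros((3, 3), int)
        )
        cfg = sim.SimConfig.zero_error(subgrid_factor=10)
        for p in sim.simulate_products(truth, cfg):
            per_cell = p.reshape(3, 10, 3, 10).sum(axis=(1, 3))
            np.testing.assert_array_equal(per_cell, 40)

    def test_zero_error_aggregation_recovers_truth(self):
        truth = sim.random_scene_truth(6, 6, seed=2)
        cfg = sim.SimConfig.zero_error(seed=2, subgrid_factor=10)
        for p in sim.simulate_products(truth, cfg):
            frac = refdata.aggregate_categorical(p.astype(float), 10)
            quota = np.floor(truth.fraction * 100 / 100.0 + 0.5)
            np.testing.assert_allclose(frac, quota, atol=1e-9)

    def test_tall_dense_suppression_only_last_product(self):
        truth = sim.SceneTruth(
            fraction=np.full((2, 2), 20.0), pheno_shift=np.zeros((2, 2), int)
        )
        cfg = sim.SimConfig(
            noise_sd=0.0, cloud_prob=0.0, seed=0, subgrid_factor=5,
            product_error=((0.0, 0.0),) * 4, tall_dense_threshold=30.0,
        )
        products = sim.simulate_products(truth, cfg)
        assert all((p.sum() > 0) for p in products[:3])
        assert products[3].sum() == 0
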