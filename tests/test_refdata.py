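import numpy as np
import pytest

from ftcmap import refdata
from ftcmap import simscene as sim


class TestAggregateCategorical:
    def test_three_of_four(self):
        binary = np.array([[1, 1], [1, 0]], dtype=float)
        np.testing.assert_allclose(refdata.aggregate_categorical(binary, 2), [[75.0]])

    def test_all_non_tree(self):
        np.testing.assert_allclose(
            refdata.aggregate_categorical(np.zeros((4, 4)), 2), np.zeros((2, 2))
        )

    def test_forty_percent(self):
        binary = np.zeros((10, 10))
        binary.ravel()[:40] = 1
        np.testing.assert_allclose(refdata.aggregate_categorical(binary, 10), [[40.0]])

    def test_invalid_subcells_excluded_from_denominator(self):
        binary = np.array([[1.0, np.nan], [1.0, 0.0]])
        np.testing.assert_allclose(refdata.aggregate_categorical(binary, 2), [[2 / 3 * 100]])

    def test_mostly_invalid_cell_is_fill(self):
        binary = np.full((2, 2), np.nan)
        binary[0, 0] = 1.0  # 25% valid < 50%
        assert np.isnan(refdata.aggregate_categorical(binary, 2)[0, 0])

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            refdata.aggregate_categorical(np.zeros((5, 4)), 2)


class TestCombineProducts:
    def test_hand_example(self):
        grids = [np.full((1, 1), v) for v in (80.0, 90.0, 100.0, 70.0)]
        ref = refdata.combine_products(grids)
        assert ref.tc_ref_mean[0, 0] == pytest.approx(85.0)
        assert ref.mae_ref[0, 0] == pytest.approx(10.0)  # (5+5+15+15)/4

    def test_identical_products_zero_spread(self):
        ref = refdata.combine_products([np.full((2, 2), 60.0)] * 4)
        np.testing.assert_allclose(ref.mae_ref, 0.0)

    def test_two_extreme_products(self):
        ref = refdata.combine_products([np.zeros((1, 1)), np.full((1, 1), 100.0)])
        assert ref.tc_ref_mean[0, 0] == pytest.approx(50.0)
        assert ref.mae_ref[0, 0] == pytest.approx(50.0)

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            refdata.combine_products([np.zeros((1, 1))])

    def test_permutation_invariance(self, rng):
        grids = [rng.uniform(0, 100, (4, 4)) for _ in range(4)]
        a = refdata.combine_products(grids)
        b = refdata.combine_products(grids[::-1])
        np.testing.assert_allclose(a.tc_ref_mean, b.tc_ref_mean)
        np.testing.assert_allclose(a.mae_ref, b.mae_ref)

    def test_mean_within_product_range(self, rng):
        grids = [rng.uniform(0, 100, (4, 4)) for _ in range(4)]
        ref = refdata.combine_products(grids)
        stack = np.stack(grids)
        assert np.all(ref.tc_ref_mean >= stack.min(axis=0) - 1e-12)
        assert np.all(ref.tc_ref_mean <= stack.max(axis=0) + 1e-12)


def make_ref(mae):
    grid = np.asarray(mae, dtype=float)
    return refdata.ReferenceCoverSet(
        product_fractions=[np.full_like(grid, 50.0)] * 4,
        tc_ref_mean=np.full_like(grid, 50.0),
        mae_ref=grid,
        valid_mask=np.isfinite(grid),
    )


class TestApplyExclusions:
    def base_inputs(self, shape=(1, 1)):
        return dict(
            clear_counts=np.full(shape, 40),
            run_length=np.full(shape, 20),
            evergreen=np.zeros(shape, dtype=bool),
        )

    def test_mae_boundary_strict(self):
        ref = make_ref([[10.0, 10.0001]])
        mask = refdata.apply_exclusions(ref, **self.base_inputs((1, 2)))
        assert mask[0, 0] and not mask[0, 1]

    @pytest.mark.parametrize("clear,kept", [(24, False), (25, True)])
    def test_clear_count_boundary(self, clear, kept):
        inputs = self.base_inputs()
        inputs["clear_counts"] = np.array([[clear]])
        assert refdata.apply_exclusions(make_ref([[5.0]]), **inputs)[0, 0] == kept

    @pytest.mark.parametrize("length,kept", [(11, False), (12, True)])
    def test_season_length_boundary(self, length, kept):
        inputs = self.base_inputs()
        inputs["run_length"] = np.array([[length]])
        assert refdata.apply_exclusions(make_ref([[5.0]]), **inputs)[0, 0] == kept

    def test_evergreen_exempt_from_season_rule(self):
        inputs = self.base_inputs()
        inputs["run_length"] = np.array([[0]])
        inputs["evergreen"] = np.array([[True]])
        assert refdata.apply_exclusions(make_ref([[5.0]]), **inputs)[0, 0]

    def test_landcover_exclusion(self):
        inputs = self.base_inputs((1, 4))
        lc = np.array([[refdata.LC_VEGETATED, refdata.LC_WATER,
                        refdata.LC_SNOW_ICE, refdata.LC_BARREN]])
        mask = refdata.apply_exclusions(make_ref([[5.0] * 4]), landcover=lc, **inputs)
        np.testing.assert_array_equal(mask, [[True, False, False, False]])


class TestBalanceSamples:
    def make_rows(self, bins):
        targets = np.concatenate([np.full(n, b, dtype=float) for b, n in bins])
        features = np.tile(np.arange(12, dtype=float), (targets.size, 1))
        features[:, 0] = np.arange(targets.size)  # distinguish rows
        return features, targets

    def test_caps_applied(self):
        X, y = self.make_rows([(0, 1000), (50, 30), (100, 800)])
        ts = refdata.balance_samples(X, y, cap0=100, cap100=100, seed=1)
        assert ts.bin_counts[0] == 100
        assert ts.bin_counts[50] == 30
        assert ts.bin_counts[100] == 100
        assert ts.bin_counts.sum() == len(ts)

    def test_large_caps_identity(self):
        X, y = self.make_rows([(0, 10), (100, 10)])
        ts = refdata.balance_samples(X, y, cap0=1000, cap100=1000, seed=1)
        assert len(ts) == 20

    def test_seeded_determinism(self):
        X, y = self.make_rows([(0, 500), (100, 500)])
        a = refdata.balance_samples(X, y, cap0=50, cap100=50, seed=7)
        b = refdata.balance_samples(X, y, cap0=50, cap100=50, seed=7)
        np.testing.assert_array_equal(a.table["pixel_id"], b.table["pixel_id"])

    def test_rows_unaltered(self):
        X, y = self.make_rows([(0, 200), (37, 5), (100, 200)])
        ts = refdata.balance_samples(X, y, cap0=20, cap100=20, seed=3)
        kept_ids = ts.table["pixel_id"].to_numpy()
        np.testing.assert_array_equal(
            ts.table[list(ts.table.columns[:12])].to_numpy(), X[kept_ids]
        )
        np.testing.assert_array_equal(ts.table["target"].to_numpy(), y[kept_ids])

    def test_rounding_half_up_binning(self):
        X = np.zeros((2, 12))
        ts = refdata.balance_samples(X, np.array([49.5, 49.4]), cap0=10, cap100=10, seed=0)
        assert ts.bin_counts[50] == 1 and ts.bin_counts[49] == 1


class TestAggregationClosure:
    def test_zero_error_products_reconstruct_truth(self):
        truth = sim.SceneTruth(
            fraction=np.arange(16, dtype=float).reshape(4, 4) * 6.0,
            pheno_shift=np.zeros((4, 4), int),
        )
        cfg = sim.SimConfig.zero_error(seed=4, subgrid_factor=10)
        grids = [
            refdata.aggregate_categorical(p.astype(float), 10)
            for p in sim.simulate_products(truth, cfg)
        ]
        ref = refdata.combine_products(grids)
        np.testing.assert_allclose(ref.tc_ref_mean, truth.fraction, atol=1e-9)
        np.testing.assert_allclose(ref.mae_ref, 0.0, atol=1e-9)
        assert refdata.apply_exclusions(
            ref,
            clear_counts=np.full((4, 4), 46),
            run_length=np.full((4, 4), 20),
            evergreen=np.zeros((4, 4), bool),
        ).all()
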