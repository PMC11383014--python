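"""MNAR partitioning, calibration, validation split and biased batches."""

import numpy as np
import pytest
from scipy import stats

import lupine as lp
from conftest import make_qm


def closed_form_test_fraction(values, params):
    """Analytic expected test share: mean per-entry P(x < T) times p."""
    center = np.quantile(values, params.center_quantile)
    sd = params.sd_multiplier * values.std()
    return params.bernoulli_p * stats.norm.cdf((center - values) / sd).mean()


class TestMnarPartition:
    def test_p_zero_sends_everything_to_train(self, tiny_qm):
        params = lp.PartitionParams(bernoulli_p=0.0, seed=3)
        masks = lp.mnar_partition(tiny_qm, params)
        assert not masks.test_mask.any()
        assert (masks.train_mask == tiny_qm.present_mask()).all()

    def test_fraction_matches_normal_cdf_oracle(self, normal_qm):
        params = lp.PartitionParams(seed=17)
        masks = lp.mnar_partition(normal_qm, params)
        n = normal_qm.values.size
        realized = masks.test_mask.sum() / n
        expected = closed_form_test_fraction(normal_qm.values, params)
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(realized - expected) < 4 * se

    def test_test_set_is_left_skewed(self, normal_qm):
        masks = lp.mnar_partition(normal_qm, lp.PartitionParams(seed=17))
        assert (
            normal_qm.values[masks.test_mask].mean()
            < normal_qm.values[masks.train_mask].mean()
        )

    def test_masks_disjoint_and_exhaustive(self, default_sim):
        observed, _ = default_sim
        masks = lp.mnar_partition(observed, lp.PartitionParams(seed=2))
        masks = lp.mcar_validation_split(masks, 0.1, seed=3)
        assert not (masks.train_mask & masks.test_mask).any()
        assert not (masks.train_mask & masks.val_mask).any()
        assert not (masks.val_mask & masks.test_mask).any()
        assert (masks.union() == observed.present_mask()).all()

    def test_p_one_matches_pure_censoring_oracle(self, normal_qm):
        params = lp.PartitionParams(bernoulli_p=1.0, seed=23)
        masks = lp.mnar_partition(normal_qm, params)
        n = normal_qm.values.size
        expected = closed_form_test_fraction(normal_qm.values, params)
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(masks.test_mask.sum() / n - expected) < 3 * se

    def test_seed_determinism(self, tiny_qm):
        params = lp.PartitionParams(seed=9)
        a = lp.mnar_partition(tiny_qm, params)
        b = lp.mnar_partition(tiny_qm, params)
        assert (a.test_mask == b.test_mask).all()
        assert (a.train_mask == b.train_mask).all()

    def test_all_missing_rejected(self):
        qm = make_qm(np.full((2, 2), np.nan))
        with pytest.raises(ValueError):
            lp.mnar_partition(qm, lp.PartitionParams())


class TestCalibrateBernoulliP:
    def test_target_zero_gives_zero(self, normal_qm):
        assert lp.calibrate_bernoulli_p(normal_qm, lp.PartitionParams(), 0.0) == 0.0

    def test_realized_fraction_near_target(self, normal_qm):
        params = lp.PartitionParams(seed=0)
        p = lp.calibrate_bernoulli_p(normal_qm, params, 0.20)
        fresh = lp.PartitionParams(bernoulli_p=p, seed=999)
        masks = lp.mnar_partition(normal_qm, fresh)
        realized = masks.test_mask.sum() / normal_qm.values.size
        assert abs(realized - 0.20) < 0.01

    def test_monotone_in_target(self, normal_qm):
        params = lp.PartitionParams()
        p_lo = lp.calibrate_bernoulli_p(normal_qm, params, 0.10)
        p_hi = lp.calibrate_bernoulli_p(normal_qm, params, 0.30)
        assert p_hi > p_lo

    def test_unreachable_target_reports_maximum(self, normal_qm):
        with pytest.raises(ValueError, match="maximum"):
            lp.calibrate_bernoulli_p(normal_qm, lp.PartitionParams(), 0.9)


class TestMcarValidationSplit:
    def test_exact_counts(self):
        rng = np.random.default_rng(4)
        qm = make_qm(rng.normal(size=(50, 20)))
        masks = lp.mnar_partition(qm, lp.PartitionParams(bernoulli_p=0.0))
        assert masks.train_mask.sum() == 1000
        out = lp.mcar_validation_split(masks, 0.10, seed=5)
        assert out.val_mask.sum() == 100
        assert out.train_mask.sum() == 900
        assert (out.test_mask == masks.test_mask).all()

    def test_fraction_zero_is_identity(self, sim_masks):
        out = lp.mcar_validation_split(sim_masks, 0.0, seed=1)
        assert out.val_mask.sum() == 0
        assert (out.train_mask == sim_masks.train_mask).all()

    def test_validation_intensities_unbiased(self, normal_qm):
        # MCAR: across seeds, val means scatter symmetrically about the
        # train mean (unlike the left-skewed MNAR test set)
        masks = lp.mnar_partition(normal_qm, lp.PartitionParams(seed=0))
        diffs = []
        for seed in range(100):
            out = lp.mcar_validation_split(masks, 0.10, seed=seed)
            diffs.append(
                normal_qm.values[out.val_mask].mean()
                - normal_qm.values[out.train_mask].mean()
            )
        t = stats.ttest_1samp(diffs, 0.0)
        assert t.pvalue > 0.01

    def test_bad_fraction_rejected(self, sim_masks):
        with pytest.raises(ValueError):
            lp.mcar_validation_split(sim_masks, 1.0)


class TestBiasedBatches:
    def test_batches_have_exact_size(self, normal_qm):
        masks = lp.mnar_partition(normal_qm, lp.PartitionParams(seed=1))
        for batch in lp.biased_batches(normal_qm, masks, n_batches=5, seed=2):
            assert batch.shape == (128, 2)
            assert masks.train_mask[batch[:, 0], batch[:, 1]].all()

    def test_pooled_batches_left_shifted(self, normal_qm):
        masks = lp.mnar_partition(normal_qm, lp.PartitionParams(seed=1))
        pooled = np.concatenate(
            [
                normal_qm.values[b[:, 0], b[:, 1]]
                for b in lp.biased_batches(normal_qm, masks, n_batches=200, seed=3)
            ]
        )
        train_mean = normal_qm.values[masks.train_mask].mean()
        se = pooled.std() / np.sqrt(pooled.size)
        assert pooled.mean() < train_mean - 3 * se

    def test_uniform_override_matches_training_distribution(self, normal_qm):
        masks = lp.mnar_partition(normal_qm, lp.PartitionParams(seed=1))
        pooled = np.concatenate(
            [
                normal_qm.values[b[:, 0], b[:, 1]]
                for b in lp.biased_batches(
                    normal_qm, masks, n_batches=79, seed=4, uniform=True
                )
            ]
        )[:10_000]
        ks = stats.ks_2samp(pooled, normal_qm.values[masks.train_mask])
        assert ks.pvalue > 0.01

    def test_batches_avoid_val_and_test_entries(self, default_sim):
        observed, _ = default_sim
        masks = lp.mcar_validation_split(
            lp.mnar_partition(observed, lp.PartitionParams(seed=2)), 0.1, seed=3
        )
        blocked = masks.val_mask | masks.test_mask
        for batch in lp.biased_batches(observed, masks, n_batches=20, seed=5):
            assert not blocked[batch[:, 0], batch[:, 1]].any()

    def test_stream_is_seed_deterministic(self, normal_qm):
        masks = lp.mnar_partition(normal_qm, lp.PartitionParams(seed=1))
        a = list(lp.biased_batches(normal_qm, masks, n_batches=3, seed=8))
        b = list(lp.biased_batches(normal_qm, masks, n_batches=3, seed=8))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)


def test_mask_round_trip(tmp_path, tiny_qm):
    masks = lp.mcar_validation_split(
        lp.mnar_partition(tiny_qm, lp.PartitionParams(seed=1)), 0.2, seed=2
    )
    path = tmp_path / "masks.tsv"
    lp.write_masks(masks, tiny_qm, path, header_lines=["run info"])
    back = lp.read_masks(path, tiny_qm)
    for name in ("train_mask", "val_mask", "test_mask"):
        np.testing.assert_array_equal(getattr(back, name), getattr(masks, name))
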