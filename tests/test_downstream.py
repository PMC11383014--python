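"""BH adjustment, Spearman, differential expression, complex correlations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lupine as lp
from conftest import make_qm


def brute_force_bh(p):
    """Independent step-up implementation: argsort, scale, running minimum."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    out = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        out[order[rank - 1]] = min(running, 1.0)
    return out


def brute_force_spearman(x, y):
    """Rank (mid-ranks for ties) then Pearson."""

    def midrank(v):
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks

    rx, ry = midrank(np.asarray(x)), midrank(np.asarray(y))
    return np.corrcoef(rx, ry)[0, 1]


class TestBhAdjust:
    def test_hand_worked_example(self):
        np.testing.assert_allclose(
            lp.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_p_unchanged(self):
        assert lp.bh_adjust([0.37])[0] == 0.37

    def test_matches_brute_force_oracle_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 30))
            np.testing.assert_allclose(lp.bh_adjust(p), brute_force_bh(p))

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        p = rng.uniform(size=200)
        np.testing.assert_allclose(
            lp.bh_adjust(p), multipletests(p, method="fdr_bh")[1]
        )

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=20),
        st.randoms(use_true_random=False),
    )
    def test_permutation_equivariance(self, p, rnd):
        p = np.array(p)
        perm = np.array(rnd.sample(range(len(p)), len(p)))
        adjusted = lp.bh_adjust(p)
        np.testing.assert_allclose(lp.bh_adjust(p[perm]), adjusted[perm])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            lp.bh_adjust([0.5, 1.5])


class TestSpearman:
    def test_monotone_sequences(self):
        x = np.arange(10.0)
        assert lp.spearman(x, np.exp(x)) == pytest.approx(1.0)
        assert lp.spearman(x, -(x**3)) == pytest.approx(-1.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(1000):
            x = rng.integers(0, 8, size=20).astype(float)  # ties likely
            y = rng.normal(size=20)
            if np.all(x == x[0]):
                continue
            assert lp.spearman(x, y) == pytest.approx(brute_force_spearman(x, y))

    def test_constant_sequence_undefined(self):
        assert np.isnan(lp.spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))

    def test_missing_pairs_dropped(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [2.0, 4.0, 0.0, 8.0, 10.0]
        assert lp.spearman(x, y) == pytest.approx(1.0)


def _paired_cohort(n_pairs=10, n_proteins=6, shift_protein=0, shift=2.0, seed=0):
    """Small tumor/non-tumor cohort with one optionally shifted protein."""
    rng = np.random.default_rng(seed)
    base = rng.normal(size=(n_proteins, n_pairs))
    tumor = base + rng.normal(0, 0.1, size=base.shape)
    normal = base + rng.normal(0, 0.1, size=base.shape)
    if shift_protein is not None:
        tumor[shift_protein] += shift
    values = np.concatenate([tumor, normal], axis=1)
    sample_ids = [f"T{k}" for k in range(n_pairs)] + [f"N{k}" for k in range(n_pairs)]
    return make_qm(
        values,
        sample_ids=sample_ids,
        sample_type={s: ("tumor" if s.startswith("T") else "non_tumor")
                     for s in sample_ids},
        patient_of_sample={s: f"pt{s[1:]}" for s in sample_ids},
    )


class TestRunDe:
    def test_identical_groups_yield_no_calls(self):
        qm = _paired_cohort(shift_protein=None)
        qm.values[:, 10:] = qm.values[:, :10]  # non-tumor == tumor
        table = lp.run_de(qm, qm)
        assert (table["direction"] == "none").all()

    def test_shifted_protein_called_up(self):
        qm = _paired_cohort(shift_protein=0, shift=2.0)
        table = lp.run_de(qm, qm, alpha=0.05)
        assert table.loc["P0", "direction"] == "up"
        assert table.loc["P0", "log2_fold_change"] > 0.5

    def test_high_missingness_protein_excluded(self):
        qm = _paired_cohort(shift_protein=0)
        pre = qm.copy()
        pre.values[1, :12] = np.nan  # 60% missing before imputation
        table = lp.run_de(qm, pre)
        assert "P1" not in table.index
        assert "P0" in table.index

    def test_alpha_zero_and_infinite_lfc_yield_no_calls(self):
        qm = _paired_cohort(shift_protein=0, shift=3.0)
        assert (lp.run_de(qm, qm, alpha=0.0)["direction"] == "none").all()
        assert (
            lp.run_de(qm, qm, lfc_cut=np.inf)["direction"] == "none"
        ).all()

    def test_no_imputation_mode_drops_incomplete_pairs(self):
        qm = _paired_cohort(shift_protein=None)
        holey = qm.copy()
        holey.values[0, 0] = np.nan  # tumor member of pair 0 missing
        table = lp.run_de(holey, holey)
        assert table.loc["P0", "n_pairs"] == 9
        assert table.loc["P1", "n_pairs"] == 10

    def test_annotations_required(self, tiny_qm):
        with pytest.raises(ValueError):
            lp.run_de(tiny_qm, tiny_qm)

    def test_planted_de_recovery(self):
        spec = lp.SimSpec(
            n_cohorts=1,
            proteins_per_cohort=200,
            samples_per_cohort=80,
            paired_patients_per_cohort=40,
            noise_sd=0.3,
            n_de_proteins=20,
            de_log2_shift=1.0,
            n_complexes=5,
            target_missing_fraction=0.25,
            seed=5,
        )
        observed, truth = lp.simulate_cohorts(spec)
        table = lp.run_de(observed, observed)
        called = set(table.index[table["direction"] == "up"])
        planted = set(truth.de_proteins)
        recall = len(called & planted) / len(planted)
        assert recall >= 0.9
        if called:
            assert len(called - planted) / len(called) <= 0.1


class TestComplexCorrelations:
    def _block_matrix(self, seed=0):
        rng = np.random.default_rng(seed)
        n_samples = 30
        shared = rng.normal(size=n_samples)
        values = rng.normal(size=(12, n_samples))
        values[0] += 2.0 * shared
        values[1] += 2.0 * shared
        values[2] += 2.0 * shared
        return make_qm(values)

    def test_identical_rows_correlate_perfectly(self):
        qm = self._block_matrix()
        qm.values[1] = qm.values[0]
        report = lp.complex_correlations(
            qm, {"c1": {"P0", "P1"}}, tumor_only=False, seed=1
        )
        assert report.within_correlations[0] == pytest.approx(1.0)

    def test_within_exceeds_background_on_planted_block(self):
        qm = self._block_matrix()
        report = lp.complex_correlations(
            qm, {"c1": {"P0", "P1", "P2"}}, tumor_only=False, seed=2
        )
        assert report.mean_within > report.mean_background
        assert report.n_pairs == 3
        assert len(report.background_correlations) == report.n_pairs

    def test_background_avoids_complex_internal_pairs(self):
        qm = self._block_matrix()
        complexes = {"c1": {"P0", "P1", "P2"}, "c2": {"P3", "P4"}}
        # with few proteins, exhaust many seeds; backgrounds must never
        # include a within-complex pair, so correlations stay low on average
        reports = [
            lp.complex_correlations(qm, complexes, tumor_only=False, seed=s)
            for s in range(10)
        ]
        for r in reports:
            assert len(r.background_correlations) == r.n_pairs

    def test_high_missingness_members_excluded(self):
        qm = self._block_matrix()
        pre = qm.copy()
        pre.values[0, :20] = np.nan  # 67% initially missing
        report = lp.complex_correlations(
            qm, {"c1": {"P0", "P1", "P2"}}, tumor_only=False,
            pre_imputation=pre, seed=3,
        )
        assert report.n_pairs == 1  # only the P1-P2 pair survives

    def test_insufficient_background_pool_rejected(self):
        qm = make_qm(np.random.default_rng(0).normal(size=(3, 10)))
        with pytest.raises(ValueError):
            lp.complex_correlations(
                qm, {"c1": {"P0", "P1", "P2"}}, tumor_only=False, seed=4
            )
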