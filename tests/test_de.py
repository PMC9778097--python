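"""Size factors, NB Wald test, BH adjustment, volcano and recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from countsimbench import (
    CountMatrix,
    SampleAnnotation,
    bh_adjust,
    count_degs,
    deg_recovery,
    make_fixture,
    nb_wald_test,
    sign_balance,
    size_factors,
    volcano_table,
)
from countsimbench.de import DEResult


def mk(counts):
    counts = np.asarray(counts)
    return CountMatrix(
        counts,
        [f"g{i}" for i in range(counts.shape[0])],
        [f"s{j}" for j in range(counts.shape[1])],
    )


def two_class_ann(n1, n2):
    return SampleAnnotation(
        {f"s{j}": (1 if j < n1 else 2) for j in range(n1 + n2)}
    )


def make_result(pvalues, lfc=None, qvalues=None):
    p = np.asarray(pvalues, float)
    lfc = np.zeros_like(p) if lfc is None else np.asarray(lfc, float)
    q = bh_adjust(p) if qvalues is None else np.asarray(qvalues, float)
    se = np.ones_like(p)
    return DEResult(
        feature_ids=[f"g{i}" for i in range(p.size)],
        base_mean=np.full(p.size, 100.0),
        lfc=lfc, se=se, wald=lfc / se, pvalue=p, qvalue=q,
    )


class TestSizeFactors:
    def test_identical_columns_unit_factors(self, rng):
        col = rng.integers(1, 100, size=10)
        cm = mk(np.column_stack([col, col, col]))
        np.testing.assert_allclose(size_factors(cm), 1.0)

    def test_doubled_column_analytic(self, rng):
        col = rng.integers(1, 100, size=20)
        cm = mk(np.column_stack([col, 2 * col]))
        np.testing.assert_allclose(
            size_factors(cm), [1 / np.sqrt(2), np.sqrt(2)]
        )

    def test_matches_median_of_ratios_oracle(self, rng):
        counts = rng.integers(1, 500, size=(50, 6))
        cm = mk(counts)
        geo = np.array([np.exp(np.mean(np.log(row))) for row in counts])
        oracle = [np.median(counts[:, j] / geo) for j in range(6)]
        np.testing.assert_allclose(size_factors(cm), oracle)

    def test_fallback_without_all_positive_feature_warns(self, rng):
        counts = rng.integers(1, 50, size=(20, 4))
        for i in range(20):
            counts[i, i % 4] = 0  # every feature has a zero somewhere
        with pytest.warns(UserWarning, match="positive"):
            sf = size_factors(mk(counts))
        assert np.all(sf > 0)


class TestBHAdjust:
    def test_step_up_arithmetic(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        pvals=st.lists(st.floats(0, 1), min_size=1, max_size=60),
        alpha=st.sampled_from([0.01, 0.05, 0.1, 0.25]),
    )
    def test_rejection_set_matches_step_up_oracle(self, pvals, alpha):
        p = np.array(pvals)
        m = p.size
        order = np.argsort(p, kind="stable")
        sorted_p = p[order]
        # brute force: largest k with p_(k) <= k * alpha / m
        k_star = 0
        for k in range(1, m + 1):
            if sorted_p[k - 1] <= k * alpha / m:
                k_star = k
        oracle_reject = np.zeros(m, bool)
        oracle_reject[order[:k_star]] = True
        got_reject = bh_adjust(p) <= alpha
        np.testing.assert_array_equal(got_reject, oracle_reject)

    def test_monotone_in_p_rank(self, rng):
        p = rng.uniform(size=100)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q >= p)  # BH never decreases a p-value
        assert np.all(q <= 1.0)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestNBWaldTest:
    def test_equal_class_means_null_statistics(self):
        block = np.array([[30, 40, 30, 40], [10, 20, 10, 20],
                          [5, 5, 5, 5], [100, 90, 100, 90]])
        cm = mk(block)
        res = nb_wald_test(cm, two_class_ann(2, 2))
        np.testing.assert_allclose(res.lfc, 0.0, atol=1e-12)
        np.testing.assert_allclose(res.wald, 0.0, atol=1e-12)
        np.testing.assert_allclose(res.pvalue, 1.0)

    def test_type_i_error_near_nominal(self, null_nb):
        cm, ann = null_nb
        res = nb_wald_test(cm, ann)
        rate = np.mean(res.pvalue < 0.05)
        assert 0.035 <= rate <= 0.065

    def test_huge_effect_tiny_dispersion(self, rng):
        n = 50
        c1 = rng.poisson(100, size=(1, n))
        c2 = rng.poisson(800, size=(1, n))
        filler = rng.poisson(300, size=(30, 2 * n))
        counts = np.vstack([np.hstack([c1, c2]), filler])
        res = nb_wald_test(mk(counts), two_class_ann(n, n))
        assert res.qvalue[0] < 1e-6
        assert res.lfc[0] == pytest.approx(3.0, abs=0.2)

    def test_label_swap_negates_lfc_keeps_pvalues(self, ngsspg1_small):
        cm, ann, _ = ngsspg1_small
        swapped = SampleAnnotation(
            {s: (3 - c) for s, c in ann.class_of.items()}
        )
        a = nb_wald_test(cm, ann)
        b = nb_wald_test(cm, swapped)
        np.testing.assert_allclose(b.lfc, -a.lfc, atol=1e-9)
        np.testing.assert_allclose(b.pvalue, a.pvalue, atol=1e-12)

    def test_normalization_consistency_under_sample_scaling(self, ngsspg1_small):
        # scaling one sample's counts by c and its size factor by c leaves
        # all statistics unchanged
        cm, ann, _ = ngsspg1_small
        sf = size_factors(cm)
        base = nb_wald_test(cm, ann, size_factors_=sf)
        scaled_counts = cm.counts.copy()
        scaled_counts[:, 0] *= 3
        cm_scaled = CountMatrix(scaled_counts, cm.feature_ids, cm.sample_ids)
        sf_scaled = sf.copy()
        sf_scaled[0] *= 3
        scaled = nb_wald_test(cm_scaled, ann, size_factors_=sf_scaled)
        np.testing.assert_allclose(scaled.lfc, base.lfc, atol=1e-12)
        np.testing.assert_allclose(scaled.pvalue, base.pvalue, atol=1e-12)

    def test_degenerate_class_sizes_rejected(self):
        cm = mk(np.arange(12).reshape(3, 4) + 1)
        ann = SampleAnnotation({"s0": 1, "s1": 2, "s2": 2, "s3": 2})
        with pytest.raises(ValueError, match="class 1"):
            nb_wald_test(cm, ann)


class TestCountAndClassify:
    def test_count_degs_boundaries(self):
        res = make_result([0.5, 0.5], qvalues=[0.04, 0.04])
        assert count_degs(res, alpha=0.0) == 0
        assert count_degs(res, alpha=0.05) == 2

    @pytest.mark.parametrize(
        "p,lfc,expected",
        [
            (0.01, 2.0, "sig_up"),
            (0.5, 3.0, "nonsig"),
            (0.01, 0.3, "sig_small_fc"),
            (0.01, -2.0, "sig_down"),
            (0.05, 2.0, "nonsig"),  # boundary: significance is strict
        ],
    )
    def test_volcano_classification(self, p, lfc, expected):
        res = make_result([p], lfc=[lfc])
        assert volcano_table(res).volcano_class[0] == expected

    def test_volcano_p_zero_capped(self):
        res = make_result([0.0], lfc=[5.0])
        vt = volcano_table(res)
        assert np.isfinite(vt.neg_log10_p[0])

    def test_sign_balance_limits(self):
        up = make_result([1e-4] * 4, lfc=[1, 2, 3, 4])
        assert sign_balance(up) == 1.0
        one_down = make_result([1e-4], lfc=[-2.0])
        assert sign_balance(one_down) == 0.0
        nothing = make_result([0.9, 0.8])
        assert np.isnan(sign_balance(nothing))

    def test_sign_balance_symmetric_effects(self, rng):
        # strong symmetric signal: half up, half down
        n, m = 30, 200
        mu = np.full((m, 2 * n), 300.0)
        lfc = np.concatenate([np.ones(m // 2), -np.ones(m // 2)])
        mu[:, n:] *= 2.0 ** lfc[:, None]
        counts = rng.poisson(mu)
        res = nb_wald_test(mk(counts), two_class_ann(n, n))
        assert sign_balance(res) == pytest.approx(0.5, abs=0.05)


class TestDegRecovery:
    def test_perfect_and_empty_callers(self, ngsspg1_small):
        _, _, truth = ngsspg1_small
        m = truth.de_flags.size
        perfect = make_result(
            np.where(truth.de_flags, 1e-12, 0.99),
            qvalues=np.where(truth.de_flags, 1e-12, 0.99),
        )
        rec = deg_recovery(perfect, truth)
        assert rec["sensitivity"] == 1.0 and rec["observed_fdr"] == 0.0
        silent = make_result(np.ones(m), qvalues=np.ones(m))
        rec0 = deg_recovery(silent, truth)
        assert rec0["sensitivity"] == 0.0 and rec0["observed_fdr"] == 0.0

    def test_small_preset_controls_fdr(self, ngsspg1_small):
        cm, ann, truth = ngsspg1_small
        res = nb_wald_test(cm, ann)
        rec = deg_recovery(res, truth)
        assert rec["observed_fdr"] <= 0.1
        assert rec["sensitivity"] > 0.0
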