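"""Identifiability matrix, fingerprint metrics and permutation inference."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from connfp import (
    build_identifiability_matrix,
    generate_edge_panel,
    identifiability_metrics,
    paired_self_other_test,
    permutation_group_anova,
    permutation_null,
)
from connfp.synthgen import SyntheticModelSpec

HAND_M = np.array([[0.9, 0.1, 0.2], [0.3, 0.8, 0.1], [0.2, 0.4, 0.7]])


def naive_matrix(test, retest):
    n = test.shape[0]
    out = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = stats.pearsonr(test[i], retest[j]).statistic
    return out


class TestMatrix:
    def test_two_subject_structure(self, rng):
        u, v = rng.normal(size=(2, 40))
        c = stats.pearsonr(u, v).statistic
        m = build_identifiability_matrix(np.vstack([u, v]), np.vstack([u, v]))
        np.testing.assert_allclose(m, [[1, c], [c, 1]], atol=1e-12)

    def test_matches_double_loop_oracle(self, rng):
        test = rng.normal(size=(5, 30))
        retest = rng.normal(size=(5, 30))
        np.testing.assert_allclose(
            build_identifiability_matrix(test, retest),
            naive_matrix(test, retest),
            atol=1e-12,
        )

    def test_constant_vector_rejected(self, rng):
        test = rng.normal(size=(3, 10))
        test[1] = 0.7
        with pytest.raises(ValueError, match="constant"):
            build_identifiability_matrix(test, rng.normal(size=(3, 10)))

    def test_nan_edges_dropped_for_all_subjects(self, rng):
        test = rng.normal(size=(4, 20))
        retest = rng.normal(size=(4, 20))
        test_nan, retest_nan = test.copy(), retest.copy()
        test_nan[2, 5] = np.nan
        keep = np.ones(20, dtype=bool)
        keep[5] = False
        np.testing.assert_allclose(
            build_identifiability_matrix(test_nan, retest_nan),
            build_identifiability_matrix(test[:, keep], retest[:, keep]),
            atol=1e-12,
        )


class TestMetrics:
    def test_identity_matrix(self):
        m = identifiability_metrics(np.eye(2))
        assert m.iself.tolist() == [1.0, 1.0]
        assert m.iothers.tolist() == [0.0, 0.0]
        assert m.idiff == 1.0 and m.success_rate == 100.0

    def test_hand_iothers_two_n_minus_two(self):
        m = identifiability_metrics(HAND_M)
        assert m.iothers[0] == pytest.approx((0.1 + 0.2 + 0.3 + 0.2) / 4)
        assert m.iothers[0] == pytest.approx(0.2)

    def test_ties_count_as_failures(self):
        m = identifiability_metrics(np.full((4, 4), 0.5))
        assert m.idiff == 0.0 and m.success_rate == 0.0
        assert identifiability_metrics(np.full((4, 4), 0.5), "mean").success_rate == 0.0

    @given(st.integers(2, 12), st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_idiff_identity_property(self, n, seed):
        m = np.random.default_rng(seed).normal(size=(n, n))
        res = identifiability_metrics(m)
        expected = np.mean(np.diag(m)) - np.mean(
            [
                (m[s].sum() - m[s, s] + m[:, s].sum() - m[s, s]) / (2 * n - 2)
                for s in range(n)
            ]
        )
        assert abs(res.idiff - expected) < 1e-12

    def test_success_rate_invariant_under_monotone_transform(self, rng):
        m = rng.normal(size=(8, 8))
        for rule in ("max", "mean"):
            base = identifiability_metrics(m, rule).success_rate
            warped = identifiability_metrics(np.exp(3 * m) - 1, rule).success_rate
            assert base == warped


class TestPermutationNull:
    def test_identity_matrix_extreme_statistic(self):
        null = permutation_null(np.eye(10), n_permutations=1000, seed=0)
        assert null.p_idiff == pytest.approx(1 / 1001)
        assert null.p_idiff <= 0.001

    def test_invariant_to_subject_relabeling(self, rng):
        m = rng.normal(size=(6, 6))
        perm = rng.permutation(6)
        a = permutation_null(m, 500, seed=1)
        b = permutation_null(m[np.ix_(perm, perm)], 500, seed=1)
        assert a.p_idiff == b.p_idiff


class TestPairedTest:
    def test_clear_positive_difference(self, rng):
        iself = rng.normal(0.7, 0.05, 20)
        res = paired_self_other_test(iself, iself - rng.uniform(0.3, 0.5, 20))
        assert res.p_value < 0.05 and res.statistic > 0

    def test_non_normal_differences_select_wilcoxon(self, rng):
        iothers = rng.normal(0, 0.01, 40)
        diffs = rng.exponential(0.3, 40) ** 3  # heavily skewed
        res = paired_self_other_test(iothers + diffs, iothers)
        assert res.shapiro_p < 0.05 and res.chosen == "wilcoxon"

    def test_degenerate_all_zero(self):
        with pytest.warns(UserWarning, match="zero"):
            res = paired_self_other_test(np.ones(5), np.ones(5))
        assert res.p_value == 1.0

    def test_type_one_error_near_nominal(self):
        rng = np.random.default_rng(99)
        rejections = 0
        n_sim = 400
        for _ in range(n_sim):
            d = rng.normal(0, 1, 15)  # symmetric about zero
            res = paired_self_other_test(d, np.zeros(15))
            rejections += res.p_value < 0.05
        assert 0.02 <= rejections / n_sim <= 0.08


class TestPermutationANOVA:
    def test_strong_group_effect_detected(self, rng):
        groups = np.repeat(["a", "b"], 20)
        y = rng.normal(0, 1, 40)
        y[20:] += 2.0  # two pooled SDs
        res = permutation_group_anova(y, groups, n_permutations=1000, seed=3)
        assert res.p_value <= 0.001

    def test_covariate_effect_alone_not_flagged(self, rng):
        n = 60
        groups = rng.choice(["a", "b", "c"], n)
        age = rng.normal(70, 5, n)
        y = 0.05 * age + rng.normal(0, 1, n)
        res = permutation_group_anova(y, groups, covariates=age, n_permutations=500,
                                      seed=4)
        assert res.p_value > 0.05

    def test_rank_deficient_design_rejected(self, rng):
        groups = np.repeat(["a", "b"], 10)
        dup = np.repeat([0.0, 1.0], 10)  # collinear with the group factor
        with pytest.raises(ValueError, match="rank"):
            permutation_group_anova(rng.normal(size=20), groups, covariates=dup)


def test_high_snr_cohort_perfect_identification():
    spec = SyntheticModelSpec(
        n_subjects_per_group={"CU": 30}, n_regions=25, sigma_b=0.2, sigma_w=0.05,
        seed=21,
    )
    panel = generate_edge_panel(spec)
    m = build_identifiability_matrix(panel.test, panel.retest)
    metrics = identifiability_metrics(m)
    assert metrics.success_rate == 100.0
    assert metrics.idiff > 0.5
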