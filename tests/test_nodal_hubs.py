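"""Surrogate-null edge significance, nodal strength and hub masks."""

import numpy as np
import pytest

from connfp import (
    SyntheticModelSpec,
    edge_significance,
    generate_edge_panel,
    hub_mask,
    hub_mask_and_overlap,
    icc_one_way,
    nodal_strength,
    surrogate_icc_null,
)
from connfp.nodal_hubs import SurrogateNull


def make_groups(spec):
    panel = generate_edge_panel(spec)
    return {g: panel.group_panel(g) for g in spec.group_labels}


class TestSurrogateNull:
    def test_identical_groups_surrogate_matches_pooled_icc(self):
        spec = SyntheticModelSpec(
            n_subjects_per_group={"CU": 8, "MCI": 8, "AD": 8}, n_regions=15,
            sigma_b=0.15, sigma_w=0.1, seed=13,
        )
        panel = generate_edge_panel(spec)
        groups = {g: panel.group_panel(g) for g in spec.group_labels}
        pooled = icc_one_way(panel.test, panel.retest)
        null = surrogate_icc_null(
            groups, real={g: pooled for g in groups}, draw_per_group=5,
            n_runs=1000, seed=0,
        )
        assert np.abs(null.mean - pooled.values).mean() <= 0.05

    def test_seeded_determinism(self):
        spec = SyntheticModelSpec(n_subjects_per_group={"CU": 6, "AD": 6},
                                  n_regions=8, seed=2)
        groups = make_groups(spec)
        real = {g: icc_one_way(*groups[g]) for g in groups}
        a = surrogate_icc_null(groups, real, 5, 40, seed=5)
        b = surrogate_icc_null(groups, real, 5, 40, seed=5)
        np.testing.assert_array_equal(a.mean, b.mean)
        for g in real:
            np.testing.assert_array_equal(a.exceed_counts[g], b.exceed_counts[g])

    def test_group_smaller_than_draw_rejected(self):
        spec = SyntheticModelSpec(n_subjects_per_group={"CU": 6, "AD": 3},
                                  n_regions=8, seed=2)
        groups = make_groups(spec)
        real = {g: icc_one_way(*groups[g]) for g in groups}
        with pytest.raises(ValueError, match="fewer"):
            surrogate_icc_null(groups, real, draw_per_group=5, n_runs=5, seed=0)

    def test_streaming_matches_retained_runs(self):
        spec = SyntheticModelSpec(n_subjects_per_group={"CU": 7, "AD": 7},
                                  n_regions=10, seed=4)
        groups = make_groups(spec)
        real = {g: icc_one_way(*groups[g]) for g in groups}
        null = surrogate_icc_null(groups, real, 5, 60, seed=9, keep_runs=True)
        runs = np.vstack(null.runs)
        np.testing.assert_allclose(null.mean, runs.mean(axis=0), atol=1e-12)
        for g, icc in real.items():
            np.testing.assert_array_equal(
                null.exceed_counts[g], (runs > icc.values).sum(axis=0)
            )

    def test_null_p_values_roughly_uniform_under_exchangeability(self):
        # same generating distribution in every group: ~5% of edges significant
        # (group size chosen to match the pooled surrogate sample, 2 x 5, so
        # real and surrogate ICC estimates share a sampling distribution)
        fractions = []
        for seed in range(20):
            spec = SyntheticModelSpec(
                n_subjects_per_group={"CU": 10, "AD": 10}, n_regions=25,
                sigma_b=0.12, sigma_w=0.1, seed=seed,
            )
            groups = make_groups(spec)
            real = {g: icc_one_way(*groups[g]) for g in groups}
            null = surrogate_icc_null(groups, real, 5, 200, seed=seed)
            p, sig = edge_significance(real["CU"], null, "CU")
            fractions.append(sig.mean())
        assert 0.03 <= np.mean(fractions) <= 0.08

    def test_planted_group_edges_have_small_p(self):
        spec = SyntheticModelSpec(
            n_subjects_per_group={"CU": 10, "AD": 10}, n_regions=15,
            sigma_b=0.05, sigma_w=0.1, seed=6,
            effect_map={"AD": [{"edges": list(range(20)), "sigma_b": 0.4}]},
        )
        groups = make_groups(spec)
        real = {g: icc_one_way(*groups[g]) for g in groups}
        null = surrogate_icc_null(groups, real, 5, 300, seed=1)
        p, _ = edge_significance(real["AD"], null, "AD")
        assert np.median(p[:20]) < np.median(p[20:])


class TestEdgeSignificance:
    def null_with_counts(self, counts, runs=1000):
        counts = np.asarray(counts)
        return SurrogateNull(
            mean=np.zeros_like(counts, dtype=float),
            n_runs=runs,
            draw_per_group=5,
            exceed_counts={"g": counts},
        )

    def test_literal_proportion_rule(self):
        null = self.null_with_counts([20, 1000, 0])
        p, sig = edge_significance(np.zeros(3), null, "g")
        np.testing.assert_allclose(p, [0.02, 1.0, 0.0])
        assert sig.tolist() == [True, False, True]

    def test_add_one_variant_never_zero(self):
        null = self.null_with_counts([0, 1000])
        p, _ = edge_significance(np.zeros(2), null, "g", add_one=True)
        assert p[0] == pytest.approx(1 / 1001)
        assert p[1] == pytest.approx(1.0)


class TestNodalStrength:
    def test_hand_row_mean_including_zeros(self):
        # R=4: node 0 has masked row values (0.8, 0, 0.4)
        icc = np.array([0.8, 0.5, 0.4, 0.1, 0.2, 0.3])  # edges of a 4-node graph
        sig = np.array([True, False, True, False, False, False])
        strength = nodal_strength(icc, sig)
        assert strength[0] == pytest.approx((0.8 + 0.0 + 0.4) / 3)

    def test_no_significant_edges_zero_everywhere(self, rng):
        strength = nodal_strength(rng.uniform(0, 1, 10), np.zeros(10, dtype=bool))
        np.testing.assert_array_equal(strength, 0.0)

    def test_fully_significant_equals_row_mean(self, rng):
        icc = rng.uniform(-0.2, 1.0, 15)
        from connfp import devectorize_edges

        strength = nodal_strength(icc, np.ones(15, dtype=bool))
        matrix = devectorize_edges(icc, 6, diag=0.0)
        np.testing.assert_allclose(strength, matrix.sum(axis=1) / 5)

    def test_linearity(self, rng):
        icc = rng.uniform(0, 0.5, 10)
        sig = rng.random(10) < 0.5
        np.testing.assert_allclose(
            nodal_strength(2 * icc, sig), 2 * nodal_strength(icc, sig)
        )


class TestHubMasks:
    def test_top_quartile_of_1_to_100(self):
        strength = np.arange(1.0, 101.0)
        mask = hub_mask(strength)
        assert mask.sum() == 25
        assert mask[-25:].all() and not mask[:-25].any()

    def test_identical_cohorts_overlap_is_single_mask(self, rng):
        s = rng.uniform(size=30)
        a, b, overlap = hub_mask_and_overlap(s, s)
        np.testing.assert_array_equal(overlap, a)

    def test_disjoint_quartiles_empty_overlap(self):
        a = np.concatenate([np.ones(5), np.zeros(15)])
        b = np.concatenate([np.zeros(15), np.ones(5)])
        _, _, overlap = hub_mask_and_overlap(a, b)
        assert overlap.sum() == 0

    def test_all_equal_strengths_empty_with_warning(self):
        with pytest.warns(UserWarning, match="equal"):
            assert hub_mask(np.full(10, 0.3)).sum() == 0
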