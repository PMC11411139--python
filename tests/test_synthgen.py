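"""Generator contracts: analytic ground truth, determinism, planted effects."""

import numpy as np
import pytest

from connfp import (
    FD_ONLY_RULES,
    CONJUNCTIVE_RULES,
    QCRules,
    SyntheticModelSpec,
    fingerprint_cohort_spec,
    generate_cohort_timeseries,
    generate_edge_panel,
    generate_qc_traces,
    icc_one_way,
    nearest_positive_definite_correlation,
    plant_topology_shift,
    qc_tag_and_exclude,
)
from connfp.synthgen import edge_block_mask, template_correlation


class TestEdgePanel:
    def test_zero_session_noise_makes_test_equal_retest(self):
        spec = SyntheticModelSpec(
            n_subjects_per_group={"CU": 10}, n_regions=11, sigma_b=1.0, sigma_w=0.0,
            seed=7,
        )
        panel = generate_edge_panel(spec)
        np.testing.assert_array_equal(panel.test, panel.retest)

    def test_true_icc_is_variance_ratio(self):
        spec = SyntheticModelSpec(
            n_subjects_per_group={"CU": 4},
            n_regions=10,
            sigma_b=np.sqrt(0.6),
            sigma_w=np.sqrt(0.4),
        )
        np.testing.assert_allclose(spec.true_icc("CU"), 0.6, atol=1e-15)
        panel = generate_edge_panel(spec)
        np.testing.assert_allclose(panel.true_icc["CU"], 0.6, atol=1e-15)

    def test_determinism_bit_identical(self, flat_spec):
        a, b = generate_edge_panel(flat_spec), generate_edge_panel(flat_spec)
        np.testing.assert_array_equal(a.test, b.test)
        np.testing.assert_array_equal(a.retest, b.retest)

    def test_subsetting_groups_preserves_other_subjects(self):
        big = SyntheticModelSpec(
            n_subjects_per_group={"CU": 6, "AD": 5}, n_regions=8, seed=3
        )
        small = SyntheticModelSpec(
            n_subjects_per_group={"CU": 4, "AD": 5}, n_regions=8, seed=3
        )
        pa, pb = generate_edge_panel(big), generate_edge_panel(small)
        np.testing.assert_array_equal(
            pa.test[pa.groups == "AD"], pb.test[pb.groups == "AD"]
        )
        np.testing.assert_array_equal(pa.test[:4], pb.test[:4])

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_subjects_per_group": {"CU": 0}},
            {"n_regions": 1},
            {"sigma_b": 0.0, "sigma_w": 0.0},
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SyntheticModelSpec(**kwargs)

    def test_null_cohort_icc_estimates_center_on_zero(self):
        # sigma_b = 0: any apparent reliability is sampling noise
        means = []
        for seed in range(30):
            spec = SyntheticModelSpec(
                n_subjects_per_group={"CU": 50}, n_regions=23, sigma_b=0.0,
                sigma_w=1.0, seed=seed,
            )
            panel = generate_edge_panel(spec)
            means.append(np.mean(icc_one_way(panel.test, panel.retest).values))
        assert -0.05 < np.mean(means) < 0.05


class TestTimeseries:
    def test_large_t_fc_recovers_template(self):
        spec = SyntheticModelSpec(
            n_subjects_per_group={"CU": 1}, n_regions=20, T=20000, seed=2
        )
        series = generate_cohort_timeseries(spec, tau=0.0)[0]
        emp = np.corrcoef(series.data.T)
        assert np.abs(emp - template_correlation(spec)).max() <= 0.03

    def test_determinism(self):
        spec = SyntheticModelSpec(n_subjects_per_group={"CU": 2}, n_regions=8, T=50)
        a = generate_cohort_timeseries(spec, tau=0.5)
        b = generate_cohort_timeseries(spec, tau=0.5)
        for ts_a, ts_b in zip(a, b):
            np.testing.assert_array_equal(ts_a.data, ts_b.data)

    def test_nearest_pd_projection_fixes_invalid_template(self):
        bad = np.eye(3)
        bad[0, 1] = bad[1, 0] = 1.02
        fixed = nearest_positive_definite_correlation(bad)
        assert np.linalg.eigvalsh(fixed).min() > 0
        np.testing.assert_allclose(np.diag(fixed), 1.0)

    def test_asymmetric_template_fatal(self):
        bad = np.eye(3)
        bad[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetriz"):
            nearest_positive_definite_correlation(bad)


class TestTopologyShift:
    def test_shift_moves_supra_icc_to_between_block(self):
        spec = fingerprint_cohort_spec(
            {"CU": 6, "AD": 6}, n_regions=24, between_reliable_fraction=0.0
        )
        shifted = plant_topology_shift(spec, "within:FPN", "between:FPN", "AD")
        icc_ad = shifted.true_icc("AD")
        within = edge_block_mask(spec.partition, "within:FPN")
        between = edge_block_mask(spec.partition, "between:FPN")
        assert not (icc_ad[within] > 0.6).any()
        assert (icc_ad[between] > 0.6).sum() == within.sum()
        # other group untouched
        np.testing.assert_array_equal(shifted.true_icc("CU"), spec.true_icc("CU"))

    def test_healthy_supra_edges_lie_within_blocks(self):
        spec = fingerprint_cohort_spec(
            {"CU": 6}, n_regions=24, between_reliable_fraction=0.0
        )
        icc = spec.true_icc("CU")
        nets = np.asarray(spec.partition, dtype=object)
        iu = np.triu_indices(spec.n_regions, 1)
        within_any = nets[iu[0]] == nets[iu[1]]
        assert (icc[~within_any] <= 0.6).all()
        assert (icc[within_any] > 0.6).all()

    def test_unknown_block_or_group_rejected(self, small_cohort):
        spec = small_cohort.spec
        with pytest.raises(ValueError):
            plant_topology_shift(spec, "within:FPN", "between:FPN", "nope")
        with pytest.raises(ValueError):
            plant_topology_shift(spec, "inside:FPN", "between:FPN", "AD")


class TestQCTraces:
    def test_zero_outlier_rate_never_tagged(self):
        trace = generate_qc_traces(T=300, outlier_rate=0.0, seed=4)
        for rules in (CONJUNCTIVE_RULES, FD_ONLY_RULES):
            assert qc_tag_and_exclude(trace, rules).tagged.sum() == 0

    def test_forty_percent_outliers_trigger_exclusion_fd_rules(self):
        trace = generate_qc_traces(T=200, outlier_rate=0.4, seed=4)
        for rules in (FD_ONLY_RULES, QCRules(fd_threshold=0.3, combine="any", name="g")):
            report = qc_tag_and_exclude(trace, rules)
            assert report.tagged_fraction == pytest.approx(0.4)
            assert report.exclude_subject

    def test_conjunctive_sd_rule_caps_tagging_below_subject_threshold(self):
        # the SD fence is relative to the trace's own quartiles, so the
        # conjunction can never tag more than ~25% of volumes
        trace = generate_qc_traces(T=400, outlier_rate=0.4, seed=4)
        report = qc_tag_and_exclude(trace, CONJUNCTIVE_RULES)
        assert report.tagged_fraction <= 0.26

    def test_seed_reproducibility_and_validation(self):
        a = generate_qc_traces(100, 0.2, seed=9)
        b = generate_qc_traces(100, 0.2, seed=9)
        np.testing.assert_array_equal(a.fd, b.fd)
        np.testing.assert_array_equal(a.sd, b.sd)
        with pytest.raises(ValueError):
            generate_qc_traces(0, 0.1, seed=1)
        with pytest.raises(ValueError):
            generate_qc_traces(10, 1.5, seed=1)
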