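"""Statistical workflow: MWU, normality, variance routing, post-hoc."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

import vestigait as vg
from vestigait.errors import InputError
from vestigait.simulate import TABLE_MEANS


def brute_force_mwu_p(x, y, alternative="two-sided"):
    """Exact MWU p-value by enumerating every group assignment."""
    x, y = list(x), list(y)
    combined = x + y
    nx = len(x)

    def u_of(xs, ys):
        return sum((xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys)

    observed = u_of(x, y)
    us = [u_of([combined[i] for i in idx],
               [combined[i] for i in range(len(combined)) if i not in idx])
          for idx in itertools.combinations(range(len(combined)), nx)]
    us = np.array(us)
    if alternative == "less":
        return np.mean(us <= observed)
    if alternative == "greater":
        return np.mean(us >= observed)
    return min(1.0, 2 * min(np.mean(us <= observed),
                            np.mean(us >= observed)))


class TestMannWhitney:
    def test_fully_separated_samples(self):
        u, p = vg.mann_whitney_u([1, 2, 3], [4, 5, 6], alternative="less")
        assert u == 0.0
        assert p == pytest.approx(1 / 20)

    def test_identical_tied_samples(self):
        _, p = vg.mann_whitney_u([1, 1, 2, 2, 3], [1, 1, 2, 2, 3])
        assert p >= 0.99

    def test_exact_matches_enumeration_oracle(self):
        """Implementation agrees with a brute-force permutation oracle for
        every sample-size combination up to 5 vs 5."""
        rng = np.random.default_rng(8)
        for nx in range(1, 6):
            for ny in range(1, 6):
                vals = rng.permutation(np.arange(1.0, nx + ny + 1.0))
                x, y = vals[:nx], vals[nx:]
                for alt in ("two-sided", "less", "greater"):
                    _, p = vg.mann_whitney_u(x, y, alternative=alt)
                    assert p == pytest.approx(
                        brute_force_mwu_p(x, y, alt), abs=1e-12), (nx, ny)

    def test_exact_and_asymptotic_branches_agree(self):
        rng = np.random.default_rng(12)
        x, y = rng.normal(0, 1, 8), rng.normal(0.5, 1, 8)
        _, p_exact = vg.mann_whitney_u(x, y)
        res = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic")
        assert abs(p_exact - res.pvalue) <= 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(InputError):
            vg.mann_whitney_u([], [1.0])


class TestNormalityAndVariance:
    def test_normal_sample_passes(self):
        x = np.random.default_rng(1).normal(0, 1, 500)
        assert vg.ks_normality(x) > 0.05

    def test_exponential_sample_fails(self):
        x = np.random.default_rng(1).exponential(1.0, 500)
        assert vg.ks_normality(x) < 0.01

    def test_degenerate_samples_rejected(self):
        with pytest.raises(InputError):
            vg.ks_normality([2.0, 2.0, 2.0, 2.0])
        with pytest.raises(InputError):
            vg.ks_normality([1.0, 2.0, 3.0])

    def test_equal_variances_detected(self):
        rng = np.random.default_rng(2)
        eq, p = vg.variance_equal([rng.normal(0, 1, 50),
                                   rng.normal(0, 1, 50)])
        assert eq and p > 0.05

    def test_unequal_variances_detected(self):
        rng = np.random.default_rng(2)
        eq, p = vg.variance_equal([rng.normal(0, 1, 50),
                                   rng.normal(0, 4, 50)])
        assert not eq and p < 0.01

    def test_identical_groups_trivially_equal(self):
        g = [1.0, 2.0, 3.0, 4.0]
        eq, p = vg.variance_equal([g, list(g)])
        assert eq and p == pytest.approx(1.0)


class TestOmnibus:
    def test_identical_groups_no_effect(self):
        name, stat, p = vg.omnibus_compare([[1, 2, 3], [1, 2, 3]])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_identical_tied_groups(self):
        name, stat, p = vg.omnibus_compare([[1.0, 1.0, 1.0],
                                            [1.0, 1.0, 1.0]])
        assert stat == 0.0 and p == 1.0

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(0, 1, 20), rng.normal(0, 1, 20),
                  rng.normal(2, 1, 20)]
        name, _, p = vg.omnibus_compare(groups)
        assert p < 0.001

    def test_anova_is_squared_pooled_t_for_two_groups(self):
        """F = t² links the omnibus ANOVA to the pooled two-sample t."""
        rng = np.random.default_rng(6)
        x, y = rng.normal(0, 1, 15), rng.normal(0.8, 1, 12)
        name, f_stat, p_f = vg.omnibus_compare([x, y])
        assert name == "anova"
        t_stat, p_t = sps.ttest_ind(x, y, equal_var=True)
        assert f_stat == pytest.approx(t_stat ** 2, abs=1e-9)
        assert p_f == pytest.approx(p_t, abs=1e-9)


class TestPosthoc:
    def test_identical_groups_lsd_p_one(self):
        g = [1.0, 2.0, 3.0, 4.0]
        (_, _, p), = vg.posthoc([g, list(g)], equal_variance=True)
        assert p == pytest.approx(1.0)

    def test_lsd_two_groups_equals_pooled_t(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(0, 1, 10), rng.normal(1, 1, 10)
        (_, _, p_lsd), = vg.posthoc([x, y], equal_variance=True)
        _, p_t = sps.ttest_ind(x, y, equal_var=True)
        assert p_lsd == pytest.approx(p_t, abs=1e-12)

    def test_t3_conservative_vs_welch(self):
        rng = np.random.default_rng(10)
        groups = [rng.normal(0, 1, 10), rng.normal(0.5, 2, 8),
                  rng.normal(1, 3, 12)]
        t3 = vg.posthoc(groups, equal_variance=False)
        for (i, j), (_, _, p_t3) in zip(
                itertools.combinations(range(3), 2), t3):
            _, p_welch = sps.ttest_ind(groups[i], groups[j],
                                       equal_var=False)
            assert p_t3 >= p_welch - 1e-12

    def test_single_group_rejected(self):
        with pytest.raises(InputError):
            vg.posthoc([[1.0, 2.0]], equal_variance=True)


class TestBonferroni:
    def test_textbook_examples(self):
        np.testing.assert_allclose(vg.bonferroni([0.01, 0.04], m=2),
                                   [0.02, 0.08])
        assert vg.bonferroni([0.9], m=3)[0] == 1.0

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=10))
    def test_adjusted_never_below_raw(self, pvals):
        adj = vg.bonferroni(pvals, m=len(pvals))
        assert np.all(adj >= np.asarray(pvals) - 1e-15)
        assert np.all(adj <= 1.0)


@pytest.fixture(scope="module")
def cohort_report():
    """10 control + 5 LVN + 5 RVN simulated walks, full pipeline."""
    configs = vg.cohort_configs(10, 5, 5, seed=31)
    summaries = vg.analyze_cohort(configs)
    return summaries, vg.build_report(summaries)


class TestBuildReport:
    def test_group_means_recover_presets(self, cohort_report):
        """Recovered group means sit within one pooled SEM of the preset
        values for the amplitude and timing parameters."""
        _, report = cohort_report
        by_param = {c.parameter: c for c in report}
        for column in ("normal", "lvn", "rvn"):
            for param, key in [("max_nav", "max_nav"),
                               ("min_nav", "min_nav"),
                               ("stride_time", "stride_time"),
                               ("stance_time", "stance_time")]:
                comp = by_param[param]
                sem = math.hypot(
                    comp.sds[column] / math.sqrt(comp.ns[column]),
                    vg.TABLE_SDS[column][key]
                    / math.sqrt(comp.ns[column]))
                assert abs(comp.means[column]
                           - TABLE_MEANS[column][key]) <= 2 * sem, \
                    (column, param)

    def test_routing_matches_frozen_table(self, cohort_report):
        _, report = cohort_report
        by_param = {c.parameter: c for c in report}
        assert by_param["stance_time"].posthoc_method == "MWU+Bonferroni"
        assert by_param["stance_ratio"].posthoc_method == "MWU+Bonferroni"
        for p in ("max_nav", "min_nav", "up_slope", "down_slope",
                  "stride_time", "swing_time"):
            assert by_param[p].posthoc_method in ("LSD", "DunnettT3")
            assert by_param[p].omnibus_name in ("anova", "kruskal_wallis")

    def test_adjusted_p_at_least_raw(self, cohort_report):
        _, report = cohort_report
        for comp in report:
            for pair, raw in comp.pairwise_raw.items():
                assert comp.pairwise_adjusted[pair] >= raw - 1e-12

    def test_single_group_rejected(self, cohort_report):
        summaries, _ = cohort_report
        only_control = [(g, s) for g, s in summaries if g == "normal"]
        with pytest.raises(InputError):
            vg.build_report(only_control)

    def test_report_frame_shape(self, cohort_report):
        _, report = cohort_report
        frame = vg.report_frame(report)
        assert len(frame) == len(vg.PARAMETERS)
        assert {"normal_mean", "lvn_mean", "rvn_mean"} <= set(frame.columns)
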