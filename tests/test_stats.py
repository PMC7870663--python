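"""Cohort statistics: Lilliefors normality, laterality battery, BH-FDR,
TIV correlation, sex ANCOVA, summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from innerear.phantom import CohortSpec, cohort_to_table, generate_cohort
from innerear.stats import (
    bh_fdr,
    gender_ancova,
    laterality_tests,
    lilliefors_normality,
    summarize_cohort,
    tiv_correlations,
)


class TestLilliefors:
    def test_normal_samples_rarely_rejected(self):
        # under H0 the rejection rate is the nominal 5% (Monte-Carlo p-values
        # are slightly conservative); allow the two-sigma binomial band
        rng = np.random.default_rng(42)
        n_draws = 200
        rejections = sum(
            lilliefors_normality(rng.standard_normal(50)).pvalue < 0.05
            for _ in range(n_draws)
        )
        bound = 0.05 * n_draws + 2 * np.sqrt(n_draws * 0.05 * 0.95)
        assert rejections <= bound

    def test_exponential_samples_usually_rejected(self):
        rng = np.random.default_rng(43)
        rejections = sum(
            lilliefors_normality(rng.exponential(size=50)).pvalue < 0.05
            for _ in range(100)
        )
        assert rejections >= 80

    def test_tiny_sample_rejected(self):
        with pytest.raises(ValueError, match="4 observations"):
            lilliefors_normality([1.0, 2.0, 3.0])

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            lilliefors_normality([2.0] * 10)

    def test_deterministic_given_sample(self):
        x = np.random.default_rng(1).normal(size=30)
        assert (lilliefors_normality(x).pvalue ==
                lilliefors_normality(x).pvalue)


def _brute_force_bh(p):
    """Literal step-up definition: find the largest k with
    p_(k) <= k/m * alpha; adjusted values by direct minimization."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        value = min(p[i] * m / rank, prev)
        adjusted[i] = value
        prev = value
    return np.minimum(adjusted, 1.0)


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_hand_applied_step_up(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            p = rng.random(rng.integers(1, 40))
            np.testing.assert_allclose(bh_fdr(p), _brute_force_bh(p),
                                       atol=1e-12)


def _paired_table(left, right):
    n = len(left)
    rows = []
    for i in range(n):
        rows.append(("s%d" % i, "L", "F" if i % 2 else "M", 1400.0, left[i]))
        rows.append(("s%d" % i, "R", "F" if i % 2 else "M", 1400.0, right[i]))
    return pd.DataFrame(rows, columns=["subject", "side", "sex", "tiv_cm3", "m"])


class TestLaterality:
    def test_identical_sides_give_null(self):
        vals = np.linspace(1, 2, 12)
        res = laterality_tests(_paired_table(vals, vals), ["m"])
        assert res[0].statistic == 0.0 and res[0].pvalue == 1.0
        assert not res[0].significant

    def test_strong_asymmetry_detected(self):
        rng = np.random.default_rng(0)
        base = rng.normal(10, 0.5, 20)
        res = laterality_tests(
            _paired_table(base * 1.2, base + rng.normal(0, 0.05, 20)), ["m"])
        assert res[0].significant

    def test_wilcoxon_mode(self):
        rng = np.random.default_rng(1)
        base = rng.normal(10, 0.5, 20)
        res = laterality_tests(_paired_table(base * 1.2, base), ["m"],
                               nonnormal_test="wilcoxon")
        assert res[0].test in ("paired_t", "wilcoxon")

    def test_null_cohort_type_one_control(self):
        """Per-decision false-rejection rate of the battery stays near the
        nominal level under the two-sided null (subset of the full
        acceptance-sized simulation)."""
        measures = None
        false_positives = total = 0
        for seed in range(25):
            tab = cohort_to_table(generate_cohort(
                CohortSpec(n_subjects=30, seed=9000 + seed)))
            if measures is None:
                measures = [c for c in tab.columns if c.startswith("scc_")]
            res = laterality_tests(tab, measures)
            false_positives += sum(r.significant for r in res)
            total += len(res)
        assert false_positives / total <= 0.07


class TestTivCorrelation:
    def test_perfect_linear_relation(self):
        tab = _paired_table(np.arange(10.0), np.arange(10.0))
        tab["tiv_cm3"] = np.repeat(np.arange(10.0) * 2 + 100, 2)
        res = tiv_correlations(tab, ["m"])[0]
        assert res.statistic == pytest.approx(1.0)

    def test_independent_variables_uncorrelated(self):
        rng = np.random.default_rng(5)
        n = 200
        left = rng.normal(size=n)
        tab = _paired_table(left, left)
        tab["tiv_cm3"] = np.repeat(rng.normal(1400, 100, n), 2)
        res = tiv_correlations(tab, ["m"])[0]
        assert abs(res.statistic) < 0.15

    def test_zero_variance_rejected(self):
        tab = _paired_table(np.ones(6), np.ones(6))
        with pytest.raises(ValueError, match="variance"):
            tiv_correlations(tab, ["m"])


class TestAncova:
    @staticmethod
    def _cohort(seed=0, sex_effect=0.0):
        return cohort_to_table(generate_cohort(
            CohortSpec(n_subjects=30, sex_effect=sex_effect, seed=seed)))

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        tab = self._cohort(seed=2)
        ours = gender_ancova(tab, "inner_ear_length_total")
        per_subject = tab.groupby("subject").agg(
            {"inner_ear_length_total": "mean", "tiv_cm3": "first",
             "sex": "first"}).reset_index()
        ref = pingouin.ancova(data=per_subject, dv="inner_ear_length_total",
                              between="sex", covar="tiv_cm3")
        row = ref[ref["Source"] == "sex"].iloc[0]
        assert ours.F == pytest.approx(float(row["F"]), rel=1e-6)
        assert ours.pvalue == pytest.approx(float(row["p_unc"]), rel=1e-6)

    def test_zero_variance_covariate_degrades_to_anova(self):
        rng = np.random.default_rng(3)
        tab = _paired_table(rng.normal(10, 1, 16), rng.normal(10, 1, 16))
        res = gender_ancova(tab, "m")
        per_subject = tab.groupby("subject").agg(
            {"m": "mean", "sex": "first"})
        groups = [g["m"].to_numpy() for _, g in per_subject.groupby("sex")]
        f_ref, _ = sps.f_oneway(*groups)
        assert res.F == pytest.approx(float(f_ref), abs=1e-9)

    def test_permuted_labels_follow_the_null_distribution(self):
        """Permutation oracle: the F statistic under shuffled sex labels must
        follow the theoretical F(1, df) distribution."""
        rng = np.random.default_rng(11)
        tab = self._cohort(seed=4)
        f_values = []
        df_resid = None
        subjects = tab["subject"].unique()
        for _ in range(300):
            perm = dict(zip(subjects,
                            rng.permutation(["F", "M"] * (len(subjects) // 2))))
            shuffled = tab.copy()
            shuffled["sex"] = shuffled["subject"].map(perm)
            res = gender_ancova(shuffled, "inner_ear_length_total")
            f_values.append(res.F)
            df_resid = res.df_residual
        ks = sps.kstest(f_values, sps.f(1, df_resid).cdf)
        assert ks.pvalue > 0.01

    def test_single_group_rejected(self):
        tab = _paired_table(np.arange(6.0), np.arange(6.0))
        tab["sex"] = "F"
        with pytest.raises(ValueError, match="two sex groups"):
            gender_ancova(tab, "m")


class TestSummaries:
    def test_hand_computed(self):
        tab = _paired_table([2.8], [3.0])
        out = summarize_cohort(tab, ["m"])
        assert out["mean"].iloc[0] == pytest.approx(2.9)
        assert out["sd"].iloc[0] == pytest.approx(0.1414, abs=1e-4)

    def test_constant_column(self):
        tab = _paired_table([1.0, 1.0], [1.0, 1.0])
        assert summarize_cohort(tab, ["m"])["sd"].iloc[0] == 0.0

    def test_cohort_mean_recovers_generator_truth(self):
        tab = cohort_to_table(generate_cohort(
            CohortSpec(n_subjects=30, scale_tiv_slope=0.0,
                       scale_noise_sd=0.05, seed=6)))
        out = summarize_cohort(tab, ["scc_lat_radius"])
        assert out["mean"].iloc[0] == pytest.approx(2.9, rel=0.02)
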