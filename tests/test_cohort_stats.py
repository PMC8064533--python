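"""Agreement, concordance, ROC, survival and logistic statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from psivol.cohort_stats import (
    StatsConfig, compare_groups, consensus_grade, contingency_test, fit_logistic,
    fleiss_kappa, km_logrank, lin_ccc, roc_cutoff, run_cohort_pipeline,
)
from psivol.cohort_synth import OutcomeModel, cohort_to_frame, default_cohort_spec, generate_cohort
from psivol.errors import DegenerateStatisticError, ParameterError


class TestConsensus:
    @pytest.mark.parametrize("row,expected", [
        (("G2", "G2", "G3"), "G2"),
        (("G2", "G2", "G2"), "G2"),
        (("G1", "G2", "G3"), None),
    ])
    def test_majority_rule(self, row, expected):
        assert consensus_grade([row]) == [expected]


class TestFleissKappa:
    def test_unanimous_two_categories(self):
        mat = [["A", "A", "A"]] * 5 + [["B", "B", "B"]] * 5
        assert fleiss_kappa(mat) == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # 2 items × 3 raters: {A,A,B}, {B,B,A}
        # P̄ = mean of (Σ n_ij² − m)/(m(m−1)) = ((4+1−3) + (1+4−3))/(2·6)... per item:
        # item Pᵢ = (2²+1² − 3)/6 = 1/3 each → P̄ = 1/3
        # category shares: A: 3/6, B: 3/6 → P̄ₑ = 1/4 + 1/4 = 1/2
        # κ = (1/3 − 1/2)/(1 − 1/2) = −1/3
        assert fleiss_kappa([["A", "A", "B"], ["B", "B", "A"]]) == pytest.approx(-1 / 3)

    def test_null_kappa_near_zero(self):
        rng = np.random.default_rng(0)
        mat = rng.choice(["A", "B", "C"], size=(10_000, 3))
        # asymptotic null SE ≈ 1/sqrt(n·m(m−1)/2)
        se = 1.0 / math.sqrt(10_000 * 3)
        assert abs(fleiss_kappa(mat)) < 3 * se

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(1)
        mat = rng.choice(["A", "B", "C"], size=(200, 3))
        relabeled = np.vectorize({"A": "Z", "B": "Y", "C": "X"}.get)(mat)
        assert fleiss_kappa(mat) == pytest.approx(fleiss_kappa(relabeled))

    def test_single_category_degenerate(self):
        with pytest.raises(DegenerateStatisticError):
            fleiss_kappa([["A", "A", "A"]] * 4)


class TestLinCCC:
    def test_identity_and_reversal(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert lin_ccc(x, x) == pytest.approx(1.0)
        y = [-1.0, 0.0, 1.0]
        assert lin_ccc(y, [1.0, 0.0, -1.0]) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # x={1,2,3}, y={1,2,4}: cov=1, var_x=2/3, var_y=14/9, Δmean²=1/9 → 6/7
        assert lin_ccc([1, 2, 3], [1, 2, 4]) == pytest.approx(6 / 7)

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=30), rng.normal(size=30)
        assert lin_ccc(x, y) == pytest.approx(lin_ccc(y, x))

    def test_degenerate_constant_series(self):
        with pytest.raises(DegenerateStatisticError):
            lin_ccc([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])


class TestCompareGroups:
    def test_identical_groups_welch_null(self):
        r = compare_groups([[1, 2, 3], [1, 2, 3]], "welch_t")
        assert r.statistic == 0.0 and r.pvalue == pytest.approx(1.0)

    def test_fully_separated_wilcoxon_extreme(self):
        r = compare_groups([[1, 2, 3], [10, 11, 12]], "wilcoxon")
        assert r.statistic == 0.0  # U for the first group: no wins

    def test_friedman_identical_columns_null(self):
        col = [1.0, 2.0, 3.0, 4.0]
        r = compare_groups([col] * 4, "friedman")
        assert r.statistic == 0.0 and r.pvalue == pytest.approx(1.0)

    def test_preconditions(self):
        with pytest.raises(ParameterError):
            compare_groups([[1.0], [2.0, 3.0]], "welch_t")
        with pytest.raises(ParameterError):
            compare_groups([[1, 2], [3, 4], [5, 6]], "wilcoxon")


class TestROC:
    def test_perfect_separation(self):
        r = roc_cutoff([1, 2, 3, 4], [0, 0, 1, 1])
        assert r.auc == 1.0 and r.cutoff == 3.0
        assert r.sensitivity == 1.0 and r.specificity == 1.0

    def test_one_discordant_pair(self):
        assert roc_cutoff([1, 3, 2, 4], [0, 0, 1, 1]).auc == pytest.approx(0.75)

    def test_auc_equals_brute_force_pair_fraction(self):
        # exhaustive concordant-pair oracle (½ credit for ties) on small data
        rng = np.random.default_rng(3)
        for _ in range(300):
            n = rng.integers(2, 9)
            labels = np.zeros(n, dtype=int)
            labels[: rng.integers(1, n)] = 1
            rng.shuffle(labels)
            if labels.min() == labels.max():
                continue
            values = rng.integers(0, 4, size=n).astype(float)  # ties likely
            pos, neg = values[labels == 1], values[labels == 0]
            pairs = [1.0 if p > q else 0.5 if p == q else 0.0
                     for p, q in itertools.product(pos, neg)]
            assert roc_cutoff(values, labels).auc == pytest.approx(np.mean(pairs))

    def test_null_auc_half(self):
        rng = np.random.default_rng(4)
        values = rng.normal(size=1000)
        aucs = []
        for _ in range(200):
            labels = np.zeros(1000, dtype=int)
            labels[:300] = 1
            rng.shuffle(labels)
            aucs.append(roc_cutoff(values, labels).auc)
        aucs = np.array(aucs)
        assert abs(aucs.mean() - 0.5) < 3 * aucs.std(ddof=1) / math.sqrt(len(aucs))

    def test_ci_contains_auc_and_is_ordered(self):
        rng = np.random.default_rng(5)
        v = rng.normal(size=60)
        y = (v + rng.normal(size=60) > 0).astype(int)
        r = roc_cutoff(v, y)
        assert r.ci[0] <= r.auc <= r.ci[1]
        assert 0.0 <= r.ci[0] and r.ci[1] <= 1.0

    def test_cutoff_equivariant_under_monotone_transform(self):
        rng = np.random.default_rng(6)
        v = rng.uniform(50, 250, size=40)
        y = (v > 140).astype(int)
        r1 = roc_cutoff(v, y)
        r2 = roc_cutoff(np.log(v), y)
        assert r2.cutoff == pytest.approx(math.log(r1.cutoff))
        assert r2.sensitivity == r1.sensitivity and r2.specificity == r1.specificity

    def test_single_class_rejected(self):
        with pytest.raises(ParameterError):
            roc_cutoff([1, 2, 3], [1, 1, 1])


class TestSurvival:
    def test_no_events_survival_stays_one(self):
        r = km_logrank([5, 8, 12], [False, False, False], ["a", "a", "a"])
        assert np.all(r.curves["a"]["survival"] == 1.0)
        assert r.statistic is None

    def test_identical_groups_null_logrank(self):
        t = [3, 6, 9, 12]
        e = [True, True, False, True]
        r = km_logrank(t + t, e + e, ["x"] * 4 + ["y"] * 4)
        assert r.statistic == pytest.approx(0.0, abs=1e-12)

    def test_product_limit_by_hand(self):
        # 3 distinct uncensored deaths: S steps 1 → 2/3 → 1/3 → 0
        r = km_logrank([2.0, 5.0, 9.0], [True] * 3, ["g"] * 3)
        np.testing.assert_allclose(r.curves["g"]["survival"], [1.0, 2 / 3, 1 / 3, 0.0])

    def test_uncensored_km_equals_empirical_survivor(self):
        rng = np.random.default_rng(7)
        t = rng.exponential(10, size=50).round(1)
        r = km_logrank(t, [True] * 50, ["g"] * 50)
        times, surv = r.curves["g"]["time"], r.curves["g"]["survival"]
        emp = [(t > u).mean() for u in times]
        np.testing.assert_allclose(surv, emp, atol=1e-12)

    def test_negative_times_rejected(self):
        with pytest.raises(ParameterError):
            km_logrank([-1.0, 2.0], [True, True], ["g", "g"])


class TestLogistic:
    def test_intercept_only_zero_pseudo_r2(self):
        df = pd.DataFrame({"outcome": [0, 1] * 10})
        r = fit_logistic(df, covariates=())
        assert r.mcfadden_r2 == 0.0

    def test_null_covariate_pseudo_r2_near_zero(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame({"outcome": rng.integers(0, 2, 10_000),
                           "vv_avg": rng.normal(150, 40, 10_000)})
        r = fit_logistic(df, covariates=("vv_avg",))
        assert r.mcfadden_r2 < 0.01 and not r.separation

    def test_separation_flagged(self):
        df = pd.DataFrame({"outcome": [0] * 10 + [1] * 10,
                           "vv_avg": list(range(10)) + list(range(100, 110))})
        with pytest.warns(UserWarning, match="separation"):
            r = fit_logistic(df, covariates=("vv_avg",))
        assert r.separation

    def test_constant_covariate_rejected(self):
        df = pd.DataFrame({"outcome": [0, 1, 0, 1], "vv_avg": [1.0] * 4})
        with pytest.raises(ParameterError):
            fit_logistic(df, covariates=("vv_avg",))


class TestContingency:
    def test_sparse_2x2_uses_fisher(self):
        assert contingency_test([[1, 9], [8, 2]]).method == "fisher_exact"

    def test_large_table_uses_chi2(self):
        assert contingency_test([[30, 40], [45, 35]]).method == "chi2"


class TestPipeline:
    @pytest.fixture(scope="class")
    @staticmethod
    def default_report():
        df = cohort_to_frame(generate_cohort(default_cohort_spec(seed=12)))
        return df, run_cohort_pipeline(df)

    def test_all_stages_complete(self, default_report):
        _, report = default_report
        stages = [k for k in report if k != "meta"]
        assert len(stages) == 11
        assert all(report[s]["status"] == "ok" for s in stages)

    def test_report_deterministic(self, default_report):
        import json
        df, report = default_report
        again = run_cohort_pipeline(df)
        assert json.dumps(report, sort_keys=True) == json.dumps(again, sort_keys=True)

    def test_threshold_cohort_recovers_cutoff(self):
        spec = default_cohort_spec(seed=13)
        spec.outcome_model = OutcomeModel(kind="threshold", tau=125.0, flip_prob=0.0)
        df = cohort_to_frame(generate_cohort(spec))
        report = run_cohort_pipeline(df)
        fu = df[df["in_followup"]]
        expected = fu.loc[fu["vv_avg"] >= 125.0, "vv_avg"].min()
        assert report["roc_outcome"]["cutoff"] == pytest.approx(expected)
        assert report["roc_outcome"]["sensitivity"] == 1.0

    def test_failed_stage_marked_not_fatal(self):
        df = cohort_to_frame(generate_cohort(default_cohort_spec(seed=14)))
        df["outcome"] = 0.0  # single-class outcome breaks the outcome stages
        report = run_cohort_pipeline(df)
        assert report["roc_outcome"]["status"] == "failed"
        assert report["patnaik_agreement"]["status"] == "ok"

    def test_margins_variant(self, default_report):
        df, _ = default_report
        report = run_cohort_pipeline(df, StatsConfig(include_margins=True))
        assert "margins_cm" in report["logistic"]["params"]
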