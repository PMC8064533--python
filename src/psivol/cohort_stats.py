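"""Cohort-level statistics for nuclear-volumetry grading studies.

Covers the full analysis chain run on a per-case table: multi-rater agreement
(Fleiss κ), replicate concordance (Friedman, Lin's concordance correlation
coefficient), between-grade comparison (Welch t), between-outcome comparison
(Wilcoxon rank-sum), ROC analysis with Youden-index cutoff discovery and
DeLong confidence intervals, Kaplan–Meier survival with log-rank tests, and
multivariate logistic regression reported with McFadden's pseudo-R².

Established implementations are used wherever they exist (statsmodels for
Fleiss κ and the logistic fit, scipy for the classical tests, scikit-learn for
ROC curves, lifelines for survival); the cutoff search, DeLong variance and
Lin's coefficient are implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_curve
from statsmodels.stats.inter_rater import aggregate_raters
from statsmodels.stats.inter_rater import fleiss_kappa as _sm_fleiss_kappa
import statsmodels.api as sm
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test

from psivol.errors import DegenerateStatisticError, ParameterError

__all__ = [
    "ROCResult", "SurvivalResult", "LogisticResult", "StatsConfig", "TestResult",
    "consensus_grade", "fleiss_kappa", "lin_ccc", "compare_groups",
    "roc_cutoff", "km_logrank", "fit_logistic", "run_cohort_pipeline",
    "contingency_test",
]


# ---------------------------------------------------------------- agreement

def consensus_grade(matrix: Sequence[Sequence[str]]) -> list[str | None]:
    """Majority grade per item from exactly 3 raters; ``None`` marks a
    three-way disagreement (flagged, never silently defaulted)."""
    arr = np.asarray(matrix, dtype=object)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ParameterError("consensus_grade expects an items × 3-raters matrix")
    out: list[str | None] = []
    for row in arr:
        vals, counts = np.unique(row, return_counts=True)
        out.append(str(vals[counts.argmax()]) if counts.max() >= 2 else None)
    return out


def fleiss_kappa(matrix: Sequence[Sequence[str]]) -> float:
    """Fleiss' κ = (P̄ − P̄ₑ)/(1 − P̄ₑ) for a fixed number of raters per item.

    Raises :class:`DegenerateStatisticError` when every rating falls in one
    single category (P̄ₑ = 1, κ undefined).
    """
    arr = np.asarray(matrix, dtype=object)
    if arr.ndim != 2:
        raise ParameterError("fleiss_kappa expects an items × raters matrix")
    if pd.isnull(arr).any():
        raise ParameterError("rating matrix must have no missing cells")
    cats = np.unique(arr)
    if cats.size < 2:
        raise DegenerateStatisticError(
            "all ratings fall in a single category; chance agreement is 1 and κ is undefined"
        )
    codes = np.searchsorted(cats, arr)
    table, _ = aggregate_raters(codes, n_cat=cats.size)
    return float(_sm_fleiss_kappa(table, method="fleiss"))


def lin_ccc(x: Sequence[float], y: Sequence[float]) -> float:
    """Lin's concordance correlation coefficient
    ρ_c = 2·cov(x,y) / (var x + var y + (mean x − mean y)²),
    with population (1/n) variances as in Lin's original definition."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ParameterError("lin_ccc expects two equal-length 1-d series of length >= 2")
    vx, vy = x.var(), y.var()
    dm = x.mean() - y.mean()
    denom = vx + vy + dm * dm
    if denom == 0.0:
        raise DegenerateStatisticError("both series constant and equal; CCC undefined")
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(2.0 * cov / denom)


# ---------------------------------------------------------------- comparisons

@dataclass(frozen=True)
class TestResult:
    method: str
    statistic: float
    pvalue: float


def compare_groups(groups: Sequence[Sequence[float]], method: str) -> TestResult:
    """Two-sided group comparison.

    ``welch_t``: Welch two-sample t (2 groups, unequal variances).
    ``wilcoxon``: Wilcoxon rank-sum / Mann–Whitney U (2 groups).
    ``friedman``: Friedman χ² across ≥2 paired series of equal length.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size < 2 for g in gs):
        raise ParameterError("every group needs at least 2 observations")
    if method == "welch_t":
        if len(gs) != 2:
            raise ParameterError("welch_t requires exactly 2 groups")
        r = sps.ttest_ind(gs[0], gs[1], equal_var=False)
        return TestResult("welch_t", float(r.statistic), float(r.pvalue))
    if method == "wilcoxon":
        if len(gs) != 2:
            raise ParameterError("wilcoxon requires exactly 2 groups")
        r = sps.mannwhitneyu(gs[0], gs[1], alternative="two-sided")
        return TestResult("wilcoxon", float(r.statistic), float(r.pvalue))
    if method == "friedman":
        if len(gs) < 2 or len({g.size for g in gs}) != 1:
            raise ParameterError("friedman requires >= 2 paired series of equal length")
        data = np.column_stack(gs)
        if np.all(data == data[:, [0]]):
            # all series identical: zero rank variance, test trivially null
            return TestResult("friedman", 0.0, 1.0)
        r = sps.friedmanchisquare(*gs)
        return TestResult("friedman", float(r.statistic), float(r.pvalue))
    raise ParameterError(f"unknown method {method!r}")


# ---------------------------------------------------------------- ROC

@dataclass
class ROCResult:
    auc: float
    ci: tuple[float, float]  # 95% CI by DeLong's method
    cutoff: float  # value attained in the data; predict positive iff value >= cutoff
    sensitivity: float
    specificity: float
    fpr: np.ndarray = field(repr=False, default=None)
    tpr: np.ndarray = field(repr=False, default=None)
    thresholds: np.ndarray = field(repr=False, default=None)


def _delong_auc_variance(values: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """AUC via the Mann–Whitney kernel (½ credit for ties) and its DeLong variance."""
    pos = values[labels == 1]
    neg = values[labels == 0]
    m, n = pos.size, neg.size
    psi = (pos[:, None] > neg[None, :]).astype(float)
    psi += 0.5 * (pos[:, None] == neg[None, :])
    v10 = psi.mean(axis=1)  # structural components over positives
    v01 = psi.mean(axis=0)
    auc = float(v10.mean())
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return auc, float(s10 / m + s01 / n)


def roc_cutoff(values: Sequence[float], labels: Sequence[int]) -> ROCResult:
    """ROC analysis with Youden-index operating point.

    The AUC uses the rank formulation with ½ credit for ties; the 95% CI is
    DeLong's.  The cutoff maximizes J = sensitivity + specificity − 1 over
    thresholds attained in the data (convention: positive iff value ≥ cutoff);
    ties are broken toward the lower cutoff, favoring sensitivity.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if values.shape != labels.shape or values.ndim != 1:
        raise ParameterError("values and labels must be equal-length 1-d arrays")
    if len(np.unique(labels)) != 2 or not set(np.unique(labels)) <= {0, 1}:
        raise ParameterError("labels must contain both classes, coded 0/1")

    fpr, tpr, thr = roc_curve(labels, values, drop_intermediate=False)
    auc, var = _delong_auc_variance(values, labels)
    half = 1.96 * np.sqrt(var)
    ci = (max(0.0, auc - half), min(1.0, auc + half))

    j = tpr - fpr
    finite = np.isfinite(thr)
    jmax = j[finite].max()
    # candidates achieving the maximum; thresholds are decreasing, so the
    # last candidate is the lowest cutoff (ties favor sensitivity)
    idx = np.flatnonzero(finite & (j >= jmax - 1e-12))[-1]
    return ROCResult(
        auc=auc, ci=ci, cutoff=float(thr[idx]),
        sensitivity=float(tpr[idx]), specificity=float(1.0 - fpr[idx]),
        fpr=fpr, tpr=tpr, thresholds=thr,
    )


# ---------------------------------------------------------------- survival

@dataclass
class SurvivalResult:
    curves: dict  # group -> {"time": array (months), "survival": array}
    statistic: float | None  # log-rank χ²; None with a single group
    pvalue: float | None


def km_logrank(
    times: Sequence[float],
    events: Sequence[bool],
    groups: Sequence,
) -> SurvivalResult:
    """Kaplan–Meier product-limit curves per group and the log-rank test.

    Two groups use the classical two-sample log-rank; more use its k-sample
    generalization.  With a single group no test is performed.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups, dtype=object)
    if np.any(times < 0):
        raise ParameterError("survival times must be >= 0")
    if times.shape != events.shape or times.shape != groups.shape:
        raise ParameterError("times, events and groups must align")

    curves = {}
    labels = pd.unique(groups)
    for g in labels:
        sel = groups == g
        kmf = KaplanMeierFitter()
        kmf.fit(times[sel], event_observed=events[sel])
        sf = kmf.survival_function_
        curves[g] = {
            "time": sf.index.to_numpy(dtype=float),
            "survival": sf.iloc[:, 0].to_numpy(dtype=float),
        }
    if len(labels) < 2:
        return SurvivalResult(curves, None, None)
    if len(labels) == 2:
        a, b = labels
        r = logrank_test(times[groups == a], times[groups == b],
                         event_observed_A=events[groups == a],
                         event_observed_B=events[groups == b])
    else:
        r = multivariate_logrank_test(times, groups, events)
    return SurvivalResult(curves, float(r.test_statistic), float(r.p_value))


# ---------------------------------------------------------------- logistic

@dataclass
class LogisticResult:
    params: dict  # name -> coefficient
    bse: dict
    pvalues: dict
    llf: float
    llnull: float
    mcfadden_r2: float
    converged: bool
    separation: bool


def fit_logistic(
    cohort: pd.DataFrame,
    covariates: Sequence[str] = ("vv_avg", "age_years", "sex"),
    outcome_col: str = "outcome",
) -> LogisticResult:
    """Maximum-likelihood logistic regression of the outcome on the covariates.

    ``sex`` is coded F=0 / M=1.  McFadden's pseudo-R² = 1 − llf/ll₀.  Perfect
    or quasi-separation is flagged (diverging coefficients), never silently
    returned as a clean fit.  An empty covariate list fits the intercept-only
    model (pseudo-R² = 0 by definition).
    """
    df = cohort.dropna(subset=[outcome_col])
    y = df[outcome_col].astype(float).to_numpy()
    if len(np.unique(y)) != 2:
        raise ParameterError("outcome must contain both classes")
    cols = []
    for c in covariates:
        v = df[c]
        if c == "sex":
            v = v.map({"F": 0.0, "M": 1.0}).astype(float)
        else:
            v = v.astype(float)
        if v.nunique() < 2:
            raise ParameterError(f"covariate {c!r} is constant")
        cols.append(v.to_numpy())
    X = sm.add_constant(np.column_stack(cols) if cols else np.empty((y.size, 0)),
                        has_constant="add")
    names = ["const", *covariates]

    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=0)
        except Exception:
            # Newton blows up under (quasi-)separation; fall back to BFGS and flag
            fit = sm.Logit(y, X).fit(method="bfgs", maxiter=500, disp=0)
            separation = True
    if np.any(np.abs(fit.params[1:] if len(fit.params) > 1 else []) > 50):
        separation = True
    if separation:
        warnings.warn("logistic fit shows (quasi-)separation; coefficients diverge")

    llf, llnull = float(fit.llf), float(fit.llnull)
    r2 = 0.0 if llnull == 0 else float(1.0 - llf / llnull)
    if len(names) == 1:
        r2 = 0.0
    return LogisticResult(
        params=dict(zip(names, map(float, fit.params))),
        bse=dict(zip(names, map(float, fit.bse))),
        pvalues=dict(zip(names, map(float, fit.pvalues))),
        llf=llf, llnull=llnull, mcfadden_r2=r2,
        converged=bool(getattr(fit, "mle_retvals", {}).get("converged", True)),
        separation=separation,
    )


# ---------------------------------------------------------------- utilities

def contingency_test(table: np.ndarray) -> TestResult:
    """χ² test of independence, or Fisher's exact test for sparse 2×2 tables."""
    table = np.asarray(table, dtype=float)
    if table.shape == (2, 2) and (sps.chi2_contingency(table)[3] < 5).any():
        odds, p = sps.fisher_exact(table)
        return TestResult("fisher_exact", float(odds), float(p))
    chi2, p, _, _ = sps.chi2_contingency(table)
    return TestResult("chi2", float(chi2), float(p))


# ---------------------------------------------------------------- pipeline

@dataclass
class StatsConfig:
    alpha: float = 0.05
    logistic_covariates: tuple[str, ...] = ("vv_avg", "age_years", "sex")
    include_margins: bool = False  # adds margins_cm to the logistic model

    def covariates(self) -> tuple[str, ...]:
        if self.include_margins and "margins_cm" not in self.logistic_covariates:
            return (*self.logistic_covariates, "margins_cm")
        return self.logistic_covariates


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def _stage(report: dict, name: str, fn) -> None:
    try:
        report[name] = {"status": "ok", **fn()}
    except Exception as exc:  # noqa: BLE001 - pipeline continues past failed stages
        report[name] = {"status": "failed", "error": f"{type(exc).__name__}: {exc}"}


def run_cohort_pipeline(cohort: pd.DataFrame, config: StatsConfig | None = None) -> dict:
    """Run the complete cohort analysis and return a JSON-serializable report.

    Stages (each marked failed individually if its preconditions break):
    per-scheme rater agreement (consensus counts + Fleiss κ), replicate
    concordance (Friedman + Lin CCC vs the average), Welch t between consensus
    grades, per-scheme grade ROC, Wilcoxon between outcomes, outcome ROC with
    cutoff, Kaplan–Meier + log-rank by grade and by cutoff strata, and the
    multivariate logistic model.  The cutoff criterion (Youden) and CI method
    (DeLong) are recorded in the report metadata.
    """
    cfg = config or StatsConfig()
    df = cohort.copy()
    rep_cols = ["vv_rep1", "vv_rep2", "vv_rep3", "vv_rep4"]
    report: dict = {
        "meta": {
            "n_cases": int(len(df)),
            "alpha": cfg.alpha,
            "cutoff_criterion": "youden_max_j (optimal-cutoff rule assumed, not reported by the study design)",
            "auc_ci_method": "delong",
        }
    }

    def agreement(prefix: str, scheme: str):
        def _run():
            mat = df[[f"{prefix}_r1", f"{prefix}_r2", f"{prefix}_r3"]].to_numpy(dtype=object)
            cons = consensus_grade(mat)
            counts = pd.Series([c for c in cons if c is not None]).value_counts().to_dict()
            unanimous = int(sum(len(set(row)) == 1 for row in mat))
            return {
                "scheme": scheme,
                "fleiss_kappa": fleiss_kappa(mat),
                "consensus_counts": counts,
                "unresolved": int(sum(c is None for c in cons)),
                "unanimous_items": unanimous,
            }
        return _run

    _stage(report, "patnaik_agreement", agreement("pat", "patnaik"))
    _stage(report, "kiupel_agreement", agreement("kiu", "kiupel"))

    def replicates():
        series = [df[c].to_numpy(dtype=float) for c in rep_cols]
        fried = compare_groups([*series, df["vv_avg"].to_numpy(dtype=float)], "friedman")
        ccc = {c: lin_ccc(df[c], df["vv_avg"]) for c in rep_cols}
        return {"friedman": vars(fried), "ccc_vs_average": ccc}

    _stage(report, "replicate_concordance", replicates)

    def grade_welch(col: str, low: str, high: str, key: str):
        def _run():
            sub = df[df[col].isin([low, high])]
            g_lo = sub.loc[sub[col] == low, "vv_avg"]
            g_hi = sub.loc[sub[col] == high, "vv_avg"]
            t = compare_groups([g_lo, g_hi], "welch_t")
            return {
                "groups": {low: {"n": int(len(g_lo)), "mean": float(g_lo.mean()), "sd": float(g_lo.std())},
                           high: {"n": int(len(g_hi)), "mean": float(g_hi.mean()), "sd": float(g_hi.std())}},
                "welch_t": vars(t),
            }
        return _run

    _stage(report, "grade_comparison_patnaik", grade_welch("pat_consensus", "G2", "G3", "patnaik"))
    _stage(report, "grade_comparison_kiupel", grade_welch("kiu_consensus", "LG", "HG", "kiupel"))

    def grade_roc(col: str, high: str):
        def _run():
            sub = df[df[col].notna()]
            r = roc_cutoff(sub["vv_avg"], (sub[col] == high).astype(int))
            return _roc_dict(r)
        return _run

    _stage(report, "roc_patnaik", grade_roc("pat_consensus", "G3"))
    _stage(report, "roc_kiupel", grade_roc("kiu_consensus", "HG"))

    fu = df[df["in_followup"] == True] if "in_followup" in df else df  # noqa: E712

    def outcome_wilcoxon():
        g0 = fu.loc[fu["outcome"] == 0, "vv_avg"]
        g1 = fu.loc[fu["outcome"] == 1, "vv_avg"]
        t = compare_groups([g0, g1], "wilcoxon")
        def q(s):
            return {"n": int(len(s)), "q1": float(s.quantile(0.25)),
                    "median": float(s.median()), "q3": float(s.quantile(0.75)),
                    "min": float(s.min()), "max": float(s.max())}
        return {"OC0": q(g0), "OC1": q(g1), "wilcoxon": vars(t)}

    _stage(report, "outcome_comparison", outcome_wilcoxon)

    def outcome_roc():
        sub = fu.dropna(subset=["outcome"])
        r = roc_cutoff(sub["vv_avg"], sub["outcome"].astype(int))
        return _roc_dict(r)

    _stage(report, "roc_outcome", outcome_roc)

    def survival():
        sub = fu.dropna(subset=["survival_months", "event"])
        out = {}
        for col, key in (("pat_consensus", "by_patnaik"), ("kiu_consensus", "by_kiupel")):
            s = sub[sub[col].notna()]
            r = km_logrank(s["survival_months"], s["event"].astype(bool), s[col])
            out[key] = {"curves": {k: v for k, v in r.curves.items()},
                        "logrank_statistic": r.statistic, "logrank_p": r.pvalue}
        cut = report.get("roc_outcome", {}).get("cutoff")
        if cut is not None:
            strata = np.where(sub["vv_avg"] >= cut, f">={cut:.1f}", f"<{cut:.1f}")
            r = km_logrank(sub["survival_months"], sub["event"].astype(bool), strata)
            out["by_vv_cutoff"] = {"cutoff": cut,
                                   "curves": {k: v for k, v in r.curves.items()},
                                   "logrank_statistic": r.statistic, "logrank_p": r.pvalue}
        return out

    _stage(report, "survival", survival)

    def logistic():
        r = fit_logistic(fu.dropna(subset=["outcome"]), cfg.covariates())
        return vars(r)

    _stage(report, "logistic", logistic)

    return _jsonable(report)


def _roc_dict(r: ROCResult) -> dict:
    return {
        "auc": r.auc, "ci95": list(r.ci), "cutoff": r.cutoff,
        "sensitivity": r.sensitivity, "specificity": r.specificity,
        "curve": {"fpr": r.fpr, "tpr": r.tpr, "thresholds": r.thresholds},
    }
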