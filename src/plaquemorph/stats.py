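"""Case-control statistical workflow for plaque feature tables.

Implements the full discrimination analysis: normality-routed univariate
comparisons (Shapiro-Wilk gating Welch's t vs Mann-Whitney U), 2×2
categorical tests (Yates-corrected χ², Fisher exact when expected counts
fall below 5), univariate and multivariable logistic regression with Wald
odds ratios, empirical ROC curves with DeLong AUC confidence intervals and
the Youden operating point, the closed-form binormal AUC, and inter-reader
agreement (ICC(2,1) plus Bland-Altman limits of agreement).

Tests are two-sided; significance is assessed at 0.05 with no
multiple-testing correction — raw p-values are always reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.tools.sm_exceptions import PerfectSeparationError


class StatsError(ValueError):
    pass


# --------------------------------------------------------------------------
# univariate comparisons
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ComparisonResult:
    feature: str
    test_used: str          # t | mann_whitney | chi2_yates | fisher
    statistic: float
    p_value: float
    summary_culprit: str
    summary_nonculprit: str


def _mean_sd(x: np.ndarray) -> str:
    return f"{x.mean():.2f} ± {x.std(ddof=1):.2f}"


def _median_range(x: np.ndarray) -> str:
    return f"{np.median(x):.2f} ({x.min():.2f}–{x.max():.2f})"


def _is_normal(x: np.ndarray, alpha: float) -> bool:
    if np.ptp(x) == 0:
        return False
    return sps.shapiro(x).pvalue > alpha


def compare_continuous(
    values_culprit: np.ndarray,
    values_nonculprit: np.ndarray,
    alpha_normality: float = 0.05,
    feature: str = "",
) -> ComparisonResult:
    """Shapiro-Wilk-routed two-group comparison.

    Both groups normal at ``alpha_normality`` → Welch's t-test with
    mean ± SD summaries; otherwise Mann-Whitney U with median (range).
    Constant columns are routed to Mann-Whitney with a warning.
    """
    x1 = np.asarray(values_culprit, dtype=float)
    x0 = np.asarray(values_nonculprit, dtype=float)
    if len(x1) < 3 or len(x0) < 3:
        raise StatsError(f"{feature}: need >= 3 observations per group")
    if np.ptp(x1) == 0 or np.ptp(x0) == 0:
        warnings.warn(
            f"{feature}: constant column, routed to Mann-Whitney",
            stacklevel=2,
        )
        normal = False
    else:
        normal = _is_normal(x1, alpha_normality) and _is_normal(x0, alpha_normality)
    if normal:
        res = sps.ttest_ind(x1, x0, equal_var=False)
        return ComparisonResult(
            feature=feature, test_used="t",
            statistic=float(res.statistic), p_value=float(res.pvalue),
            summary_culprit=_mean_sd(x1), summary_nonculprit=_mean_sd(x0),
        )
    if np.ptp(np.concatenate([x1, x0])) == 0:
        # identical constants: no evidence of any difference
        return ComparisonResult(
            feature=feature, test_used="mann_whitney",
            statistic=float(len(x1) * len(x0) / 2), p_value=1.0,
            summary_culprit=_median_range(x1),
            summary_nonculprit=_median_range(x0),
        )
    res = sps.mannwhitneyu(x1, x0, alternative="two-sided")
    return ComparisonResult(
        feature=feature, test_used="mann_whitney",
        statistic=float(res.statistic), p_value=float(res.pvalue),
        summary_culprit=_median_range(x1),
        summary_nonculprit=_median_range(x0),
    )


def compare_categorical(
    table: np.ndarray, feature: str = ""
) -> ComparisonResult:
    """2×2 contingency comparison.

    Yates-continuity-corrected χ² by default; Fisher's exact test when any
    expected cell count is below 5.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise StatsError(f"{feature}: need a 2x2 table of nonnegative counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise StatsError(f"{feature}: empty row or column margin")

    def _pct(row: np.ndarray) -> str:
        return f"{int(row[0])} ({100 * row[0] / row.sum():.1f}%)"

    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    if (expected < 5).any():
        res = sps.fisher_exact(t.astype(int))
        return ComparisonResult(
            feature=feature, test_used="fisher",
            statistic=float(res.statistic), p_value=float(res.pvalue),
            summary_culprit=_pct(t[0]), summary_nonculprit=_pct(t[1]),
        )
    res = sps.chi2_contingency(t.astype(int), correction=True)
    return ComparisonResult(
        feature=feature, test_used="chi2_yates",
        statistic=float(res.statistic), p_value=float(res.pvalue),
        summary_culprit=_pct(t[0]), summary_nonculprit=_pct(t[1]),
    )


# --------------------------------------------------------------------------
# logistic modelling
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TermFit:
    coefficient: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass(frozen=True)
class ModelFit:
    terms: dict[str, TermFit]
    intercept: float
    converged: bool
    separation: bool
    variables: tuple[str, ...]

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        missing = [v for v in self.variables if v not in X.columns]
        if missing:
            raise StatsError(f"missing feature columns: {missing}")
        lp = np.full(len(X), self.intercept)
        for name in self.variables:
            lp = lp + self.terms[name].coefficient * X[name].to_numpy(float)
        return lp


_SEPARATION_COEF = 20.0  # |beta| beyond this is treated as separation


def _check_collinearity(X: pd.DataFrame) -> None:
    if X.shape[1] < 2:
        return
    corr = X.corr().to_numpy()
    np.fill_diagonal(corr, 0.0)
    if np.nanmax(np.abs(corr)) > 0.999:
        i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        warnings.warn(
            f"collinear predictors: {X.columns[i]} and {X.columns[j]}",
            stacklevel=3,
        )


def _fit_logit(X: pd.DataFrame, y: np.ndarray) -> ModelFit:
    if len(np.unique(y)) != 2:
        raise StatsError("both classes must be present")
    _check_collinearity(X)
    Xc = sm.add_constant(X.astype(float), has_constant="add")
    degenerate = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
            params, bse, pvals = res.params, res.bse, res.pvalues
            converged = bool(res.mle_retvals.get("converged", False))
        except (PerfectSeparationError, np.linalg.LinAlgError):
            # separated or singular design: Newton's Hessian is unusable,
            # quasi-Newton still yields reportable coefficients; CIs are
            # unbounded and p-values undefined
            res = sm.Logit(y, Xc).fit(method="bfgs", disp=0, maxiter=500)
            params = res.params
            bse = pd.Series(np.nan, index=params.index)
            pvals = pd.Series(np.nan, index=params.index)
            converged = False
            degenerate = True
    separation = degenerate or bool(
        np.any(np.abs(params.drop("const")) > _SEPARATION_COEF)
    )
    terms = {}
    for name in X.columns:
        coef, se = float(params[name]), float(bse[name])
        if separation or not np.isfinite(se):
            lo, hi = 0.0, np.inf
        else:
            lo = float(np.exp(coef - 1.959963984540054 * se))
            hi = float(np.exp(coef + 1.959963984540054 * se))
        terms[name] = TermFit(
            coefficient=coef,
            odds_ratio=float(np.exp(coef)),
            ci_low=lo, ci_high=hi,
            p_value=float(pvals[name]),
        )
    return ModelFit(
        terms=terms,
        intercept=float(params["const"]),
        converged=converged,
        separation=separation,
        variables=tuple(X.columns),
    )


def univariate_logistic(
    feature: np.ndarray | pd.Series, labels: np.ndarray, name: str = "x"
) -> ModelFit:
    """Single-predictor maximum-likelihood logistic fit with Wald OR + CI."""
    X = pd.DataFrame({name: np.asarray(feature, dtype=float)})
    return _fit_logit(X, np.asarray(labels, dtype=int))


def multivariable_logistic(X: pd.DataFrame, labels: np.ndarray) -> ModelFit:
    """Joint logistic fit over a selected predictor set."""
    if X.shape[1] == 0:
        raise StatsError("no predictors selected")
    return _fit_logit(X, np.asarray(labels, dtype=int))


# --------------------------------------------------------------------------
# ROC / AUC
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RocResult:
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    youden_threshold: float
    sensitivity: float
    specificity: float
    degenerate: bool = False


def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _delong_auc_variance(scores: np.ndarray, labels: np.ndarray):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    tx = _midrank(pos)
    ty = _midrank(neg)
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v01 = (tz[:m] - tx) / n
    v10 = 1.0 - (tz[m:] - ty) / m
    var = 0.0
    if m > 1:
        var += np.var(v01, ddof=1) / m
    if n > 1:
        var += np.var(v10, ddof=1) / n
    return float(auc), float(var)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> RocResult:
    """Empirical ROC by threshold sweep.

    AUC is the trapezoidal area (equivalently the pairwise concordance /
    Mann-Whitney statistic); the confidence interval is DeLong's; the
    operating point maximizes Youden's J with ties broken toward higher
    specificity.  The decision rule is ``score >= threshold`` → positive.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if set(np.unique(y)) - {0, 1} or len(np.unique(y)) != 2:
        raise StatsError("labels must contain both classes, coded 0/1")
    n_pos, n_neg = int(y.sum()), int(len(y) - y.sum())

    if np.ptp(scores) == 0:
        return RocResult(
            auc=0.5, auc_ci_low=0.5, auc_ci_high=0.5,
            fpr=np.array([0.0, 1.0]), tpr=np.array([0.0, 1.0]),
            thresholds=np.array([np.inf, scores[0]]),
            youden_threshold=float(scores[0]),
            sensitivity=1.0, specificity=0.0, degenerate=True,
        )

    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    y_sorted = y[order]
    distinct = np.r_[np.nonzero(np.diff(s_sorted))[0], len(s_sorted) - 1]
    tp = np.cumsum(y_sorted)[distinct]
    fp = np.cumsum(1 - y_sorted)[distinct]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    thresholds = np.r_[np.inf, s_sorted[distinct]]

    auc, var = _delong_auc_variance(scores, y)
    half = 1.959963984540054 * np.sqrt(max(var, 0.0))
    j = tpr - fpr
    best = np.flatnonzero(j == j.max())
    k = best[np.argmin(fpr[best])]  # ties toward higher specificity
    return RocResult(
        auc=auc,
        auc_ci_low=float(max(0.0, auc - half)),
        auc_ci_high=float(min(1.0, auc + half)),
        fpr=fpr, tpr=tpr, thresholds=thresholds,
        youden_threshold=float(thresholds[k]),
        sensitivity=float(tpr[k]),
        specificity=float(1.0 - fpr[k]),
    )


def combined_score(fit: ModelFit, X: pd.DataFrame) -> np.ndarray:
    """Linear predictor of a fitted joint model, used as a combined index."""
    return fit.linear_predictor(X)


def binormal_auc(mean1: float, sd1: float, mean0: float, sd0: float) -> float:
    """Closed-form AUC of two normal score distributions:
    ``Phi((mean1 - mean0) / sqrt(sd1**2 + sd0**2))``."""
    if sd1 <= 0 or sd0 <= 0:
        raise StatsError("sds must be > 0")
    return float(sps.norm.cdf((mean1 - mean0) / np.hypot(sd1, sd0)))


# --------------------------------------------------------------------------
# reader agreement
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AgreementResult:
    feature: str
    icc: float
    icc_ci_low: float
    icc_ci_high: float
    bias: float
    loa_low: float
    loa_high: float


def icc_agreement(
    reader1: np.ndarray, reader2: np.ndarray, feature: str = ""
) -> AgreementResult:
    """ICC(2,1) (two-way, absolute agreement, single rater) + Bland-Altman.

    Bias is the mean of reader2 − reader1; limits of agreement are
    bias ± 1.96 × SD of the differences.
    """
    r1 = np.asarray(reader1, dtype=float)
    r2 = np.asarray(reader2, dtype=float)
    if len(r1) != len(r2) or len(r1) < 3:
        raise StatsError(f"{feature}: need >= 3 paired measurements")
    if np.ptp(r1) == 0 and np.ptp(r2) == 0:
        raise StatsError(f"{feature}: zero variance in both readers")
    n = len(r1)
    long = pd.DataFrame({
        "target": np.tile(np.arange(n), 2),
        "rater": np.repeat(["r1", "r2"], n),
        "rating": np.concatenate([r1, r2]),
    })
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        icc_table = pg.intraclass_corr(
            data=long, targets="target", raters="rater", ratings="rating"
        ).set_index("Type")
    # ICC(A,1): two-way, absolute agreement, single rater
    row = icc_table.loc["ICC(A,1)"] if "ICC(A,1)" in icc_table.index \
        else icc_table.loc["ICC2"]
    ci_col = "CI95" if "CI95" in icc_table.columns else "CI95%"
    ci = row[ci_col]
    diff = r2 - r1
    bias = float(diff.mean())
    spread = 1.959963984540054 * float(diff.std(ddof=1)) if n > 1 else 0.0
    return AgreementResult(
        feature=feature,
        icc=float(row["ICC"]),
        icc_ci_low=float(ci[0]),
        icc_ci_high=float(ci[1]),
        bias=bias,
        loa_low=bias - spread,
        loa_high=bias + spread,
    )


# --------------------------------------------------------------------------
# full workflow
# --------------------------------------------------------------------------

DEFAULT_CATEGORICAL = (
    "male", "smoking", "alcohol", "diabetes", "hypertension",
    "coronary_artery_disease", "hyperlipidemia", "iph",
)
DEFAULT_CONTINUOUS_COVARIATES = ("age", "nihss")
DEFAULT_FEATURES = (
    "wall_max", "wall_min", "stenosis_pct", "plaque_burden_pct",
    "remodeling_ratio_pct", "eccentricity_index_pct",
    "enhancement_ratio_stenosis_pct", "enhancement_ratio_whole_pct",
    "plaque_volume", "hist_mean", "hist_sd", "hist_median",
    "hist_minimum", "hist_maximum", "hist_cv", "hist_entropy",
)


@dataclass
class AnalysisConfig:
    label_col: str = "label"
    positive_label: str = "culprit"
    categorical_covariates: tuple[str, ...] = DEFAULT_CATEGORICAL
    continuous_covariates: tuple[str, ...] = DEFAULT_CONTINUOUS_COVARIATES
    features: tuple[str, ...] = DEFAULT_FEATURES
    selection_alpha: float = 0.05
    normality_alpha: float = 0.05
    agreement_subset_n: int = 30
    seed: int = 0


@dataclass
class ReportBundle:
    table1: pd.DataFrame
    table2: pd.DataFrame
    selected: tuple[str, ...]
    univariate: dict[str, ModelFit]
    multivariable: ModelFit | None
    rocs: dict[str, RocResult]
    combined_roc: RocResult | None
    combined_features: tuple[str, ...]
    agreement: pd.DataFrame | None = None

    def table3(self) -> pd.DataFrame:
        rows = []
        for name in self.selected:
            uni = self.univariate[name].terms[name]
            row = {
                "variable": name,
                "uni_or": uni.odds_ratio,
                "uni_p": uni.p_value,
            }
            if self.multivariable is not None:
                term = self.multivariable.terms[name]
                row.update(
                    multi_or=term.odds_ratio,
                    multi_ci_low=term.ci_low,
                    multi_ci_high=term.ci_high,
                    multi_p=term.p_value,
                )
            rows.append(row)
        return pd.DataFrame(rows)


def _comparison_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature": r.feature,
                "culprit": r.summary_culprit,
                "non_culprit": r.summary_nonculprit,
                "test": r.test_used,
                "statistic": r.statistic,
                "p_value": r.p_value,
            }
            for r in results
        ]
    )


def run_full_analysis(
    cohort: pd.DataFrame,
    config: AnalysisConfig | None = None,
    reader2: pd.DataFrame | None = None,
) -> ReportBundle:
    """The end-to-end case-control workflow on a cohort table.

    Produces the covariate comparison (table1), the imaging-feature
    comparison (table2), univariate + multivariable logistic models over
    variables passing the univariate screen, single-feature and combined
    ROC analyses, and (when a second-reader table is supplied) an
    inter-reader agreement sub-study on a seeded random subset.
    """
    config = config or AnalysisConfig()
    if config.label_col not in cohort.columns:
        raise StatsError(f"label column {config.label_col!r} absent")
    if len(cohort) == 0:
        raise StatsError("empty cohort")
    y = (cohort[config.label_col] == config.positive_label).to_numpy(int)
    if len(np.unique(y)) != 2:
        raise StatsError("cohort must contain both classes")
    pos = cohort[y == 1]
    neg = cohort[y == 0]

    table1_rows, table2_rows = [], []
    p_by_var: dict[str, float] = {}
    for name in config.categorical_covariates:
        if name not in cohort.columns:
            continue
        counts = np.array([
            [int(pos[name].sum()), int(len(pos) - pos[name].sum())],
            [int(neg[name].sum()), int(len(neg) - neg[name].sum())],
        ])
        if counts[:, 0].sum() == 0 or counts[:, 1].sum() == 0:
            # covariate constant across the whole cohort: nothing to test
            table1_rows.append(ComparisonResult(
                feature=name, test_used="none", statistic=np.nan,
                p_value=np.nan,
                summary_culprit=f"{counts[0, 0]} "
                                f"({100 * counts[0, 0] / len(pos):.1f}%)",
                summary_nonculprit=f"{counts[1, 0]} "
                                   f"({100 * counts[1, 0] / len(neg):.1f}%)",
            ))
            continue
        res = compare_categorical(counts, feature=name)
        table1_rows.append(res)
        p_by_var[name] = res.p_value
    for name in config.continuous_covariates:
        if name not in cohort.columns:
            continue
        res = compare_continuous(
            pos[name].to_numpy(float), neg[name].to_numpy(float),
            alpha_normality=config.normality_alpha, feature=name,
        )
        table1_rows.append(res)
        p_by_var[name] = res.p_value
    for name in config.features:
        if name not in cohort.columns:
            continue
        res = compare_continuous(
            pos[name].to_numpy(float), neg[name].to_numpy(float),
            alpha_normality=config.normality_alpha, feature=name,
        )
        table2_rows.append(res)
        p_by_var[name] = res.p_value

    selected = tuple(
        name for name in p_by_var if p_by_var[name] < config.selection_alpha
    )
    univariate = {
        name: univariate_logistic(cohort[name].to_numpy(float), y, name=name)
        for name in selected
    }
    multivariable = (
        multivariable_logistic(cohort[list(selected)].astype(float), y)
        if selected else None
    )

    continuous_selected = tuple(
        n for n in selected
        if n in config.features or n in config.continuous_covariates
    )
    rocs = {
        name: roc_auc(cohort[name].to_numpy(float), y)
        for name in continuous_selected
    }
    combined_roc = None
    combined_features: tuple[str, ...] = ()
    if multivariable is not None and len(selected) >= 2:
        significant = tuple(
            n for n in selected
            if multivariable.terms[n].p_value < config.selection_alpha
        )
        combined_features = significant if len(significant) >= 2 else selected
        fit = multivariable_logistic(
            cohort[list(combined_features)].astype(float), y
        )
        combined_roc = roc_auc(combined_score(fit, cohort), y)

    agreement = None
    if reader2 is not None:
        rng = np.random.default_rng(config.seed)
        n_sub = min(config.agreement_subset_n, len(cohort))
        idx = rng.choice(len(cohort), size=n_sub, replace=False)
        common = [
            c for c in config.features
            if c in cohort.columns and c in reader2.columns
        ]
        agreement = pd.DataFrame([
            vars(icc_agreement(
                cohort[c].to_numpy(float)[idx],
                reader2[c].to_numpy(float)[idx],
                feature=c,
            ))
            for c in common
        ])

    return ReportBundle(
        table1=_comparison_frame(table1_rows),
        table2=_comparison_frame(table2_rows),
        selected=selected,
        univariate=univariate,
        multivariable=multivariable,
        rocs=rocs,
        combined_roc=combined_roc,
        combined_features=combined_features,
        agreement=agreement,
    )
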