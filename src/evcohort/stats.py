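"""Conventional group statistics for the small-cohort comparison.

Rank tests (Mann–Whitney U, Kruskal–Wallis), Fisher's exact test for the
sex table, a covariate-adjusted linear-model comparison (age and BMI as
covariates), Pearson correlation with its t-based significance, and
Benjamini–Hochberg false-discovery-rate control with an explicit per-rank
threshold report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .cohort import CohortTable, DIAGNOSES


class StatsError(ValueError):
    """Invalid input to a statistical routine."""


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test.

    ``exact`` records whether an exact (enumeration/hypergeometric) path
    ran, as opposed to a large-sample approximation.
    """

    statistic: float
    p_value: float
    method: str
    n: tuple[int, ...]
    exact: bool
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0 + 1e-12:
            raise StatsError(f"p-value outside [0, 1]: {self.p_value}")


@dataclass(frozen=True)
class FDRReport:
    """Benjamini–Hochberg step-up report.

    ``thresholds[k-1] = alpha * k / m`` for ranks k = 1..m on the ascending
    p-values; ``k_star`` is the largest rank whose p-value sits at or below
    its threshold (0 when nothing rejects); ``critical_value`` is
    ``alpha * k_star / m`` — the procedure's effective per-comparison
    cutoff — or ``alpha / m`` with ``threshold_met=False`` when nothing
    rejects.
    """

    variables: tuple[str, ...]
    p_values: tuple[float, ...]  # ascending
    alpha: float
    thresholds: tuple[float, ...]
    k_star: int
    critical_value: float
    threshold_met: bool
    reject: dict

    @property
    def n_rejected(self) -> int:
        return self.k_star


def _clean_pair(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise StatsError("samples must be non-empty")
    if np.isnan(x).any() or np.isnan(y).any():
        raise StatsError("samples must not contain missing values")
    return x, y


def mann_whitney_u(x, y) -> TestResult:
    """Two-sided Mann–Whitney U test of two independent samples.

    Runs the exact null distribution (full enumeration over labelings) when
    both samples have ≤ 10 values and the pooled data are tie-free — the
    regime of an 8-vs-8 cohort — and otherwise the normal approximation with
    mid-ranks and tie-corrected variance.  ``exact`` records which path ran.
    """
    x, y = _clean_pair(x, y)
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == pooled.size
    use_exact = no_ties and len(x) <= 10 and len(y) <= 10
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if use_exact else "asymptotic"
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method="mann-whitney-u",
        n=(len(x), len(y)),
        exact=use_exact,
    )


def kruskal_wallis(samples) -> TestResult:
    """Kruskal–Wallis one-way ANOVA on ranks over ≥ 3 groups (e.g. control
    vs contralateral vs operated knee), tie-corrected H with a chi-square
    reference on k−1 degrees of freedom."""
    samples = [np.asarray(s, dtype=float) for s in samples]
    if len(samples) < 3:
        raise StatsError(f"kruskal_wallis needs >= 3 groups, got {len(samples)}")
    if any(len(s) < 2 for s in samples):
        raise StatsError("each group needs >= 2 values")
    if any(np.isnan(s).any() for s in samples):
        raise StatsError("samples must not contain missing values")
    if len(np.unique(np.concatenate(samples))) == 1:
        # scipy raises on all-identical data; H is 0 by definition
        return TestResult(0.0, 1.0, "kruskal-wallis", tuple(len(s) for s in samples), False)
    h, p = sps.kruskal(*samples)
    return TestResult(
        statistic=float(h),
        p_value=float(p),
        method="kruskal-wallis",
        n=tuple(len(s) for s in samples),
        exact=False,
    )


def fisher_exact_2x2(table) -> TestResult:
    """Two-sided Fisher's exact test on a 2×2 contingency table.

    Two-sided p by the probability-mass rule: the sum of hypergeometric
    probabilities of all same-margin tables no more probable than the
    observed one (the convention of major statistics packages).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise StatsError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise StatsError("table entries must be non-negative integers")
    odds, p = sps.fisher_exact(np.round(t).astype(int), alternative="two-sided")
    return TestResult(
        statistic=float(odds),
        p_value=float(min(p, 1.0)),
        method="fisher-exact",
        n=(int(t[0].sum()), int(t[1].sum())),
        exact=True,
        extras={"odds_ratio": float(odds)},
    )


def covariate_adjusted_test(y, group, covariates=None, interactions: bool = False) -> TestResult:
    """Group comparison adjusted for covariates via a Gaussian linear model.

    Fits ``y ~ intercept + group + covariates`` by ordinary least squares
    (identity link — the outcomes are continuous) and Wald-tests the group
    coefficient.  With ``interactions=True``, group × covariate terms are
    added and their p-values reported in ``extras``.  Raises on a
    rank-deficient design, naming a collinear column.
    """
    y = np.asarray(y, dtype=float)
    group = np.asarray(group)
    levels = pd.unique(group)
    if len(levels) != 2:
        raise StatsError(f"group must have exactly 2 levels, got {list(levels)}")
    g = (group == levels[1]).astype(float)
    names = ["intercept", f"group[{levels[1]}]"]
    X = [np.ones_like(y), g]
    cov_names: list[str] = []
    if covariates is not None:
        cov = pd.DataFrame(covariates)
        cov_names = [str(c) for c in cov.columns]
        for c in cov.columns:
            X.append(cov[c].to_numpy(dtype=float))
        names.extend(cov_names)
        if interactions:
            for c in cov.columns:
                X.append(g * cov[c].to_numpy(dtype=float))
                names.append(f"group:{c}")
    design = np.column_stack(X)
    if np.isnan(design).any() or np.isnan(y).any():
        raise StatsError("covariate_adjusted_test requires complete cases")
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        for j in range(design.shape[1] - 1, 0, -1):
            reduced = np.delete(design, j, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                raise StatsError(f"design is rank-deficient: column {names[j]!r} is collinear")
        raise StatsError("design is rank-deficient")
    fit = sm.OLS(y, design).fit()
    extras = {"coef": float(fit.params[1]), "params": dict(zip(names, map(float, fit.params)))}
    if interactions:
        extras["interaction_p"] = {
            name: float(p)
            for name, p in zip(names, fit.pvalues)
            if name.startswith("group:")
        }
    return TestResult(
        statistic=float(fit.tvalues[1]),
        p_value=float(fit.pvalues[1]),
        method="ols-wald",
        n=(int((g == 0).sum()), int((g == 1).sum())),
        exact=False,
        extras=extras,
    )


def pearson_correlation(x, y) -> TestResult:
    """Pearson correlation with two-sided significance from the t transform
    ``t = r·sqrt((n−2)/(1−r²))`` on n−2 degrees of freedom."""
    x, y = _clean_pair(x, y)
    if len(x) != len(y):
        raise StatsError("x and y must be paired (equal length)")
    if len(x) < 3:
        raise StatsError("pearson_correlation needs >= 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise StatsError("pearson_correlation undefined for zero-variance input")
    res = sps.pearsonr(x, y)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method="pearson",
        n=(len(x),),
        exact=False,
        extras={"r": float(res.statistic)},
    )


def benjamini_hochberg(p_values, alpha: float = 0.05, variables=None) -> FDRReport:
    """Benjamini–Hochberg step-up FDR control with a full threshold report.

    Sorts the m p-values ascending, compares p(k) to α·k/m, rejects all
    ranks up to the largest k with p(k) ≤ α·k/m, and reports the critical
    value α·k*/m (the effective per-comparison cutoff).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise StatsError("no p-values supplied")
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise StatsError("p-values must lie in [0, 1]")
    if not 0 < alpha < 1:
        raise StatsError(f"alpha must be in (0, 1), got {alpha}")
    m = p.size
    if variables is None:
        variables = [f"p{i+1}" for i in range(m)]
    variables = [str(v) for v in variables]
    if len(variables) != m:
        raise StatsError("variables must match p_values in length")
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    thresholds = alpha * np.arange(1, m + 1) / m
    passing = np.nonzero(p_sorted <= thresholds)[0]
    k_star = int(passing[-1] + 1) if passing.size else 0
    threshold_met = k_star > 0
    critical = alpha * k_star / m if threshold_met else alpha / m
    reject = {v: False for v in variables}
    for rank in range(k_star):
        reject[variables[order[rank]]] = True
    return FDRReport(
        variables=tuple(variables[i] for i in order),
        p_values=tuple(map(float, p_sorted)),
        alpha=alpha,
        thresholds=tuple(map(float, thresholds)),
        k_star=k_star,
        critical_value=float(critical),
        threshold_met=threshold_met,
        reject=reject,
    )


def run_univariate(table: CohortTable, alpha: float = 0.05) -> pd.DataFrame:
    """Batch Mann–Whitney comparison of every variable between diagnoses,
    with BH correction across the tested variables.

    Variables with fewer than 2 observed values in either diagnosis group
    are skipped.  Returns a frame with columns
    ``variable, method, statistic, p, exact, bh_reject``.
    """
    ctrl = table.diagnosis == DIAGNOSES[0]
    rows = []
    for v in table.variables:
        x = table.data.loc[ctrl, v].dropna().to_numpy()
        y = table.data.loc[~ctrl, v].dropna().to_numpy()
        if len(x) < 2 or len(y) < 2:
            continue
        res = mann_whitney_u(x, y)
        rows.append(
            {"variable": v, "method": res.method, "statistic": res.statistic,
             "p": res.p_value, "exact": res.exact}
        )
    if not rows:
        raise StatsError("no variable has >=2 observations per diagnosis group")
    out = pd.DataFrame(rows)
    report = benjamini_hochberg(out["p"].to_numpy(), alpha, out["variable"].tolist())
    out["bh_reject"] = out["variable"].map(report.reject)
    out.attrs["fdr_report"] = report
    return out


__all__ = [
    "StatsError",
    "TestResult",
    "FDRReport",
    "mann_whitney_u",
    "kruskal_wallis",
    "fisher_exact_2x2",
    "covariate_adjusted_test",
    "pearson_correlation",
    "benjamini_hochberg",
    "run_univariate",
]
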