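"""Group inference: descriptive tests, covariate screening, covariate-adjusted
between-group comparison of percent changes, and Holm step-down correction.

The primary analysis is an ordinary-least-squares model

    percent_change ~ group + covariates

fit per outcome variable; the reported group means are least-squares
(adjusted) means — model predictions for each group with every covariate
held at its sample mean — with their standard errors, and the group p-value
is the OLS t-test on the group coefficient. With no covariates this reduces
exactly to the pooled-variance two-sample t-test. Family-wise error over the
nine-variable battery is controlled with Holm's step-down procedure with
m = 9 comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps


class StatsError(RuntimeError):
    pass


class DegenerateCovariateWarning(UserWarning):
    """A covariate with zero variance was dropped from the model."""


@dataclass(frozen=True)
class GroupComparison:
    """Covariate-adjusted between-group result for one outcome variable."""

    variable: str
    adjusted_mean_diabetes: float
    se_diabetes: float
    adjusted_mean_control: float
    se_control: float
    difference: float           # diabetes − control (group coefficient)
    se_difference: float
    raw_p: float
    covariates: tuple[str, ...]
    n_diabetes: int
    n_control: int
    holm_p: float | None = None


@dataclass(frozen=True)
class CovariateScreen:
    """Pearson screen of one candidate covariate against the primary outcome."""

    covariate: str
    correlation_r: float
    screen_p: float
    included: bool


def descriptive_tests(values_by_group=None, *, kind: str = "continuous",
                      summary: dict | None = None,
                      pooled: bool = True, correction: bool = False) -> dict:
    """Between-group descriptive comparison.

    Continuous: unpaired Student's t-test (pooled variance by default; set
    ``pooled=False`` for Welch), either from two arrays of raw values or from
    ``summary={'mean': (m1, m2), 'sd': (s1, s2), 'n': (n1, n2)}``.
    Categorical: chi-square test on a contingency table (2×k array), without
    continuity correction by default.

    Returns a dict with the statistic, p-value and per-group summaries.
    """
    if kind == "continuous":
        if summary is not None:
            (m1, m2), (s1, s2), (n1, n2) = (summary["mean"], summary["sd"],
                                            summary["n"])
            t, p = sps.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2,
                                            equal_var=pooled)
            groups = [{"mean": m1, "sd": s1, "n": n1},
                      {"mean": m2, "sd": s2, "n": n2}]
        else:
            a, b = (np.asarray(g, dtype=float) for g in values_by_group)
            if a.size < 2 or b.size < 2:
                raise StatsError("need at least 2 observations per group")
            if np.ptp(np.concatenate([a, b])) == 0:
                raise StatsError("all-constant variable: t-test undefined")
            t, p = sps.ttest_ind(a, b, equal_var=pooled)
            groups = [{"mean": float(g.mean()), "sd": float(g.std(ddof=1)),
                       "n": int(g.size)} for g in (a, b)]
        return {"statistic": float(t), "p": float(p), "groups": groups,
                "test": "t" if pooled else "welch"}
    if kind == "categorical":
        table = np.asarray(values_by_group, dtype=float)
        if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
            raise StatsError("contingency table has a zero margin")
        chi2, p, dof, _ = sps.chi2_contingency(table, correction=correction)
        n = table.sum(axis=1, keepdims=True)
        return {"statistic": float(chi2), "p": float(p), "dof": int(dof),
                "groups": [{"n": row.tolist(),
                            "pct": (100 * row / row.sum()).tolist()}
                           for row in table],
                "test": "chi-square"}
    raise ValueError(f"unknown kind: {kind!r}")


def screen_covariate(covariate, outcome, *, alpha: float = 0.05,
                     name: str = "covariate") -> CovariateScreen:
    """Pearson correlation screen: include the covariate when p < alpha."""
    x = np.asarray(covariate, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if x.shape != y.shape:
        raise StatsError("covariate and outcome must be paired")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if np.ptp(x) == 0:
        warnings.warn(f"covariate {name!r} has zero variance; excluded",
                      DegenerateCovariateWarning, stacklevel=2)
        return CovariateScreen(covariate=name, correlation_r=np.nan,
                               screen_p=np.nan, included=False)
    r, p = sps.pearsonr(x, y)
    return CovariateScreen(covariate=name, correlation_r=float(r),
                           screen_p=float(p), included=bool(p < alpha))


def _drop_degenerate(X: pd.DataFrame) -> pd.DataFrame:
    keep = []
    for c in X.columns:
        if np.ptp(X[c].to_numpy(dtype=float)) == 0:
            warnings.warn(f"covariate {c!r} has zero variance; dropped from "
                          "the model", DegenerateCovariateWarning, stacklevel=3)
        else:
            keep.append(c)
    return X[keep]


def adjusted_group_comparison(
    percent_change,
    group_labels,
    covariates: pd.DataFrame | None = None,
    *,
    variable: str = "",
    diabetes_label: str = "diabetes",
) -> GroupComparison:
    """OLS percent_change ~ group + covariates; least-squares means per group.

    Adjusted means are model predictions for each group at the grand
    covariate means; their SEs come from the coefficient covariance. The
    between-group p-value is the t-test on the group coefficient.
    """
    y = np.asarray(percent_change, dtype=float)
    g = np.asarray([1.0 if lab == diabetes_label else 0.0
                    for lab in group_labels])
    n1, n0 = int(g.sum()), int((1 - g).sum())
    if covariates is not None and len(covariates.columns):
        cov = _drop_degenerate(covariates.reset_index(drop=True))
    else:
        cov = pd.DataFrame(index=range(len(y)))
    n_cov = len(cov.columns)
    if min(n1, n0) < n_cov + 2:
        raise StatsError(
            f"need at least {n_cov + 2} subjects per group for {n_cov} "
            "covariate(s)")

    X = pd.DataFrame({"const": np.ones_like(y), "group": g})
    for c in cov.columns:
        X[c] = cov[c].to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the offending columns via pivoted QR
        from scipy.linalg import qr
        _, _, piv = qr(X.to_numpy(), pivoting=True)
        bad = sorted(X.columns[i] for i in piv[rank:])
        raise StatsError(f"collinear design; offending columns: {bad}")

    fit = sm.OLS(y, X).fit()
    cov_means = {c: float(cov[c].mean()) for c in cov.columns}

    def lsmean(group_value: float) -> tuple[float, float]:
        x = np.array([1.0, group_value] + [cov_means[c] for c in cov.columns])
        mean = float(x @ fit.params.to_numpy())
        se = float(np.sqrt(x @ fit.cov_params().to_numpy() @ x))
        return mean, se

    m1, se1 = lsmean(1.0)
    m0, se0 = lsmean(0.0)
    return GroupComparison(
        variable=variable,
        adjusted_mean_diabetes=m1, se_diabetes=se1,
        adjusted_mean_control=m0, se_control=se0,
        difference=float(fit.params["group"]),
        se_difference=float(fit.bse["group"]),
        raw_p=float(fit.pvalues["group"]),
        covariates=tuple(cov.columns),
        n_diabetes=n1, n_control=n0,
    )


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values, in the input order.

    Sort ascending; the i-th smallest (1-based) is multiplied by (m − i + 1),
    running maxima enforce monotonicity, and values are capped at 1, with
    m = the number of comparisons supplied.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise StatsError("p_values must be a non-empty 1-D sequence")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise StatsError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.maximum.accumulate(p[order] * (m - np.arange(m)))
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(adj_sorted, 1.0)
    return adjusted


def compare_battery(
    changes: pd.DataFrame,
    *,
    variables,
    group_col: str = "group",
    covariate_cols=(),
    pct_prefix: str = "pct_",
) -> pd.DataFrame:
    """Adjusted between-group comparison of all variables with Holm correction.

    ``changes`` has one row per subject with percent-change columns
    ``pct_<variable>``, a group column, and any covariate columns. Returns a
    Table-3-style frame with adjusted means (SE), raw and Holm-adjusted p.
    """
    results = []
    cov = changes[list(covariate_cols)] if covariate_cols else None
    for v in variables:
        results.append(adjusted_group_comparison(
            changes[f"{pct_prefix}{v}"], changes[group_col], cov, variable=v))
    holm = holm_adjust([r.raw_p for r in results])
    return pd.DataFrame([{
        "variable": r.variable,
        "adj_mean_diabetes": r.adjusted_mean_diabetes,
        "se_diabetes": r.se_diabetes,
        "adj_mean_control": r.adjusted_mean_control,
        "se_control": r.se_control,
        "difference": r.difference,
        "se_difference": r.se_difference,
        "raw_p": r.raw_p,
        "holm_p": float(h),
        "n_diabetes": r.n_diabetes,
        "n_control": r.n_control,
        "covariates": ",".join(r.covariates),
    } for r, h in zip(results, holm)])
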