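"""Edge-wise group inference: GLMs, permutation tests, FDR, effect sizes.

Each edge's Fisher-z partial correlation is the dependent variable of an
ordinary least-squares model with a group factor of interest and sex/age
covariates.  The omnibus test is the partial F comparing the full model with
the reduced (covariate-only) model; discoveries across edges are controlled
with Benjamini-Hochberg FDR.  Pairwise follow-up contrasts use Freedman-Lane
permutation: residuals of the reduced model are permuted, added back to the
reduced fit, and the group coefficient refit, which preserves the covariate
structure under the null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import (
    DegenerateDataError,
    DesignError,
    EstimabilityError,
    ValidationError,
)

__all__ = [
    "EdgeGLMResult",
    "PairwiseComparison",
    "build_design_matrix",
    "fit_edge_glm",
    "fdr_bh",
    "permutation_pairwise",
    "cohens_d",
    "contingency_chi2",
    "oneway_anova",
]


@dataclass
class EdgeGLMResult:
    """Omnibus group test for one edge."""

    edge: object
    omnibus_F: float
    df: tuple[int, int]
    p_value: float
    partial_eta_sq: float
    coefficients: dict[str, float]
    residuals: np.ndarray = field(repr=False)
    rss: float = 0.0
    n_params: int = 0
    n: int = 0


@dataclass
class PairwiseComparison:
    """Permutation contrast of two groups on one edge."""

    edge: object
    group_a: str
    group_b: str
    cohens_d: float
    observed_stat: float
    perm_p: float
    n_perm: int
    fdr_q: float | None = None


def build_design_matrix(
    group_values: pd.Series | dict,
    covariates: pd.DataFrame | None = None,
    continuous: bool = False,
) -> tuple[np.ndarray, list[str], int]:
    """Design matrix [intercept | group columns | covariates].

    Categorical groups are dummy-coded against the first level in sorted
    order; a continuous predictor (transdiagnostic scheme) contributes a
    single column.  Returns (X, column names, number of group columns).
    """
    g = pd.Series(group_values)
    n = len(g)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["intercept"]
    if continuous:
        cols.append(g.astype(float).to_numpy())
        names.append("pct_geo")
        n_group_cols = 1
    else:
        levels = sorted(pd.unique(g.astype(str)))
        if len(levels) < 2:
            raise DesignError("group factor needs at least two levels")
        for lev in levels[1:]:
            cols.append((g.astype(str) == lev).to_numpy(dtype=float))
            names.append(f"group[{lev}]")
        n_group_cols = len(levels) - 1
    if covariates is not None:
        for c in covariates.columns:
            cols.append(covariates[c].to_numpy(dtype=float))
            names.append(str(c))
    x = np.column_stack(cols)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise DesignError("design matrix is rank deficient")
    return x, names, n_group_cols


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return beta, resid, float(resid @ resid)


def fit_edge_glm(
    edge_values: np.ndarray,
    group_values,
    covariates: pd.DataFrame | None = None,
    continuous: bool = False,
    edge: object = None,
) -> EdgeGLMResult:
    """OLS fit of one edge with an omnibus partial-F test for the group term.

    With 4 group levels plus age and sex on n=195 the omnibus test is
    F(3, 189).  ``partial_eta_sq`` is SS_group / (SS_group + SS_residual).
    """
    y = np.asarray(edge_values, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValidationError("edge values contain non-finite entries")
    x, names, n_group_cols = build_design_matrix(group_values, covariates, continuous)
    n, p = x.shape
    if n <= p:
        raise EstimabilityError(f"n={n} too small for {p} parameters")

    beta, resid, rss_full = _ols(x, y)
    group_idx = slice(1, 1 + n_group_cols)
    x_reduced = np.delete(x, range(1, 1 + n_group_cols), axis=1)
    _, _, rss_reduced = _ols(x_reduced, y)

    df1 = n_group_cols
    df2 = n - p
    ss_group = max(rss_reduced - rss_full, 0.0)
    if rss_full <= 0:
        raise DegenerateDataError("zero residual sum of squares (perfect fit)")
    f_stat = (ss_group / df1) / (rss_full / df2)
    p_value = float(stats.f.sf(f_stat, df1, df2))
    return EdgeGLMResult(
        edge=edge,
        omnibus_F=float(f_stat),
        df=(df1, df2),
        p_value=p_value,
        partial_eta_sq=float(ss_group / (ss_group + rss_full)),
        coefficients=dict(zip(names, beta)),
        residuals=resid,
        rss=rss_full,
        n_params=p,
        n=n,
    )


def fdr_bh(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (discovery mask, adjusted p-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValidationError("empty p-value list")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    reject, adjusted, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, adjusted


def permutation_pairwise(
    edge_values: np.ndarray,
    labels,
    group_a: str,
    group_b: str,
    covariates: pd.DataFrame | None = None,
    n_perm: int = 10000,
    seed: int | None = 0,
    edge: object = None,
) -> PairwiseComparison:
    """Two-sided Freedman-Lane permutation test of a two-group contrast.

    The statistic is the group-indicator coefficient from the covariate-
    adjusted OLS model.  p = (1 + #{|stat*| >= |stat|}) / (n_perm + 1), so the
    smallest attainable p is 1/(n_perm+1).
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    labels = pd.Series(list(labels))
    y = np.asarray(edge_values, dtype=float)
    mask = labels.isin([group_a, group_b]).to_numpy()
    y = y[mask]
    g = (labels[mask] == group_a).to_numpy(dtype=float)
    n = y.size
    if (g == 1).sum() < 2 or (g == 0).sum() < 2:
        raise EstimabilityError("both groups need at least 2 subjects")
    if covariates is not None:
        cov_arr = covariates.to_numpy(dtype=float)[mask]
    else:
        cov_arr = np.empty((n, 0))

    x_full = np.column_stack([np.ones(n), g, cov_arr])
    x_reduced = np.column_stack([np.ones(n), cov_arr])
    if np.linalg.matrix_rank(x_full) < x_full.shape[1]:
        raise DesignError("design matrix is rank deficient")

    pinv_full = np.linalg.pinv(x_full)
    coef_row = pinv_full[1]  # maps y -> group coefficient
    obs = float(coef_row @ y)

    beta_r, *_ = np.linalg.lstsq(x_reduced, y, rcond=None)
    fitted_r = x_reduced @ beta_r
    resid_r = y - fitted_r

    rng = np.random.default_rng(seed)
    perm = np.argsort(rng.random((n_perm, n)), axis=1)
    y_star = fitted_r[None, :] + resid_r[perm]
    stats_star = y_star @ coef_row
    p = float((1 + np.sum(np.abs(stats_star) >= abs(obs))) / (n_perm + 1))

    try:
        d = cohens_d(y[g == 1], y[g == 0])
    except DegenerateDataError:
        # perfectly separated constant groups: the contrast is still testable
        d = float("nan")
    return PairwiseComparison(
        edge=edge,
        group_a=group_a,
        group_b=group_b,
        cohens_d=d,
        observed_stat=obs,
        perm_p=p,
        n_perm=n_perm,
    )


def cohens_d(x, y) -> float:
    """Standardized mean difference with the pooled (n-2)-weighted SD."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise EstimabilityError("each sample needs at least 2 observations")
    nx, ny = x.size, y.size
    pooled_var = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if pooled_var <= 0:
        raise DegenerateDataError("zero pooled variance")
    return float((x.mean() - y.mean()) / np.sqrt(pooled_var))


def contingency_chi2(table) -> tuple[float, int, float]:
    """Pearson chi-square (no continuity correction) on an r x c count table."""
    t = np.asarray(table, dtype=float)
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValidationError("table must hold non-negative integer counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise DegenerateDataError("table has an empty margin")
    chi2, p, df, _ = stats.chi2_contingency(t, correction=False)
    return float(chi2), int(df), float(p)


def oneway_anova(values, labels) -> tuple[float, tuple[int, int], float]:
    """Classical one-way ANOVA F across the groups defined by ``labels``."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = [values[labels == lev] for lev in pd.unique(labels)]
    if len(groups) < 2:
        raise DegenerateDataError("need at least two groups")
    if any(g.size < 2 for g in groups):
        raise EstimabilityError("each group needs at least 2 observations")
    if values.var() == 0:
        raise DegenerateDataError("all observations identical; F undefined")
    f, p = stats.f_oneway(*groups)
    df1 = len(groups) - 1
    df2 = values.size - len(groups)
    return float(f), (df1, df2), float(p)
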