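"""AIC and cross-validated MAPE comparison of competing design schemes.

For a given edge, the case-control, subtype, and transdiagnostic labelings
are fit as OLS models (always with sex and age covariates) on the *identical*
subject set — subjects lacking eye tracking are dropped from every scheme
being compared, otherwise AICs would be computed on different data and be
incomparable.

AIC uses the full Gaussian log-likelihood with the residual variance counted
as a parameter,

    AIC = n * [ln(2*pi) + ln(RSS/n) + 1] + 2 * (k + 1),

the convention of common statistical environments, so absolute values are
comparable to those produced by standard `lm`-style fits on the same data.
Support bands for Delta-AIC = AIC_i - AIC_min: <= 2 "equivalent",
[2, 4) "intermediate", [4, 7] "considerably less support",
> 7 "essentially no support".

Predictive accuracy is compared with k-fold cross-validated mean absolute
percentage error, MAPE = mean(|(A - P) / A|) * 100 on held-out subjects, with
the same fold assignment reused for every scheme in a comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from .exceptions import DegenerateDataError, EstimabilityError, ValidationError
from .group_stats import EdgeGLMResult, build_design_matrix
from .subtyping import SCHEMES, build_design

__all__ = [
    "SchemeFit",
    "ModelComparisonReport",
    "gaussian_aic",
    "delta_aic",
    "kfold_mape",
    "compare_models",
]

SUPPORT_EQUIVALENT = "equivalent"
SUPPORT_INTERMEDIATE = "intermediate"
SUPPORT_CONSIDERABLY_LESS = "considerably less support"
SUPPORT_ESSENTIALLY_NONE = "essentially no support"


@dataclass
class SchemeFit:
    """Per-scheme entry of a model comparison."""

    scheme: str
    aic: float
    rss: float
    n_params: int
    delta_aic: float = np.nan
    support: str = ""
    mape_folds: list[float] = field(default_factory=list)
    mape_mean: float = np.nan
    n_zero_actuals: int = 0


@dataclass
class ModelComparisonReport:
    edge: object
    n_subjects: int
    fits: dict[str, SchemeFit]
    preferred_by_aic: str
    preferred_by_mape: str
    fold_assignment: np.ndarray = field(repr=False, default=None)

    def mape_reduction(self, better: str, worse: str) -> float:
        """Percentage-point MAPE difference between two schemes."""
        return self.fits[worse].mape_mean - self.fits[better].mape_mean


def gaussian_aic(fit: EdgeGLMResult | None = None, *, rss=None, n=None, n_params=None) -> float:
    """Gaussian AIC with sigma^2 counted as an extra parameter."""
    if fit is not None:
        rss, n, n_params = fit.rss, fit.n, fit.n_params
    if rss is None or n is None or n_params is None:
        raise ValidationError("provide either a fit or rss, n and n_params")
    if rss <= 0:
        raise DegenerateDataError("rss must be positive for a Gaussian AIC")
    return float(n * (np.log(2 * np.pi) + np.log(rss / n) + 1) + 2 * (n_params + 1))


def _support_label(delta: float) -> str:
    if delta <= 2:
        return SUPPORT_EQUIVALENT
    if 4 <= delta <= 7:
        return SUPPORT_CONSIDERABLY_LESS
    if delta > 7:
        return SUPPORT_ESSENTIALLY_NONE
    return SUPPORT_INTERMEDIATE


def delta_aic(aics) -> tuple[np.ndarray, list[str]]:
    """Delta-AIC relative to the best model plus interpretation labels."""
    a = np.asarray(aics, dtype=float)
    if a.size < 1 or not np.all(np.isfinite(a)):
        raise ValidationError("AICs must be finite")
    deltas = a - a.min()
    return deltas, [_support_label(d) for d in deltas]


def _make_folds(
    n: int, k: int, seed: int | None, stratify_labels=None
) -> np.ndarray:
    """Fold index per subject; stratified by design label when available."""
    if n < 2 * k:
        raise EstimabilityError(f"need n >= 2k subjects for {k}-fold CV, got n={n}")
    assignment = np.empty(n, dtype=int)
    if stratify_labels is not None:
        labels = np.asarray([str(v) for v in stratify_labels])
        counts = pd.Series(labels).value_counts()
        if counts.min() >= k:
            skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
            for fold, (_, test_idx) in enumerate(skf.split(np.zeros(n), labels)):
                assignment[test_idx] = fold
            return assignment
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    for fold, (_, test_idx) in enumerate(kf.split(np.zeros(n))):
        assignment[test_idx] = fold
    return assignment


def kfold_mape(
    edge_values: np.ndarray,
    design_matrix: np.ndarray,
    k: int = 5,
    seed: int | None = 0,
    fold_assignment: np.ndarray | None = None,
    stratify_labels=None,
) -> tuple[list[float], float, int]:
    """k-fold cross-validated MAPE of an OLS model.

    Returns (per-fold MAPEs, mean MAPE, number of excluded zero actuals).
    Held-out actuals of exactly zero make the percentage error undefined and
    are excluded with a count.  MAPE can exceed 100 when actuals are near
    zero, which is expected for Fisher-z edges centred close to 0.
    """
    y = np.asarray(edge_values, dtype=float)
    x = np.asarray(design_matrix, dtype=float)
    n = y.size
    if fold_assignment is None:
        fold_assignment = _make_folds(n, k, seed, stratify_labels)
    folds = np.unique(fold_assignment)
    per_fold: list[float] = []
    n_zero = 0
    for fold in folds:
        test = fold_assignment == fold
        train = ~test
        if train.sum() <= x.shape[1]:
            raise EstimabilityError("training split too small for the design")
        beta, *_ = np.linalg.lstsq(x[train], y[train], rcond=None)
        pred = x[test] @ beta
        actual = y[test]
        keep = actual != 0
        n_zero += int((~keep).sum())
        if keep.sum() == 0:
            raise DegenerateDataError("all held-out actuals are zero in a fold")
        ape = np.abs((actual[keep] - pred[keep]) / actual[keep]) * 100.0
        per_fold.append(float(ape.mean()))
    return per_fold, float(np.mean(per_fold)), n_zero


def compare_models(
    edge_values: pd.Series,
    records,
    schemes: tuple[str, ...] = ("case_control", "subtype", "transdiagnostic"),
    k: int = 5,
    seed: int | None = 0,
    edge: object = None,
) -> ModelComparisonReport:
    """Fit the requested schemes on the identical subject set and compare.

    ``edge_values`` is indexed by subject_id.  Subjects excluded by *any*
    requested scheme (no eye tracking) are dropped from all of them, so every
    AIC refers to the same data.  Fold assignments for CV MAPE are computed
    once and reused bit-identically across schemes.
    """
    for s in schemes:
        if s not in SCHEMES:
            raise ValidationError(f"unknown scheme {s!r}")
    if len(schemes) == 0:
        raise ValidationError("no schemes to compare")

    designs = {s: build_design(list(records), s) for s in schemes}
    common = set(edge_values.index)
    for d in designs.values():
        common &= set(d.labels)
    if not common:
        raise EstimabilityError("no subjects shared by all schemes")
    rec_by_id = {r.subject_id: r for r in records}
    ids = [r.subject_id for r in records if r.subject_id in common]
    y = edge_values.loc[ids].to_numpy(dtype=float)
    covars = pd.DataFrame(
        {
            "age_scan_months": [rec_by_id[i].age_scan_months for i in ids],
            "sex_male": [1.0 if rec_by_id[i].sex == "M" else 0.0 for i in ids],
        }
    )

    # shared folds, stratified by the finest categorical labeling available
    strat_scheme = "subtype" if "subtype" in schemes else (
        "case_control" if "case_control" in schemes else None
    )
    strat = (
        [designs[strat_scheme].labels[i] for i in ids] if strat_scheme else None
    )
    fold_assignment = _make_folds(len(ids), k, seed, strat)

    fits: dict[str, SchemeFit] = {}
    for s in schemes:
        lab = [designs[s].labels[i] for i in ids]
        continuous = s == "transdiagnostic"
        x, _, _ = build_design_matrix(pd.Series(lab), covars, continuous=continuous)
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        rss = float(np.sum((y - x @ beta) ** 2))
        aic = gaussian_aic(rss=rss, n=len(ids), n_params=x.shape[1])
        folds_mape, mean_mape, n_zero = kfold_mape(
            y, x, k=k, fold_assignment=fold_assignment
        )
        fits[s] = SchemeFit(
            scheme=s,
            aic=aic,
            rss=rss,
            n_params=x.shape[1],
            mape_folds=folds_mape,
            mape_mean=mean_mape,
            n_zero_actuals=n_zero,
        )

    deltas, labels = delta_aic([fits[s].aic for s in schemes])
    for s, d, lbl in zip(schemes, deltas, labels):
        fits[s].delta_aic = float(d)
        fits[s].support = lbl
    preferred_by_aic = min(schemes, key=lambda s: fits[s].aic)
    preferred_by_mape = min(schemes, key=lambda s: fits[s].mape_mean)
    return ModelComparisonReport(
        edge=edge,
        n_subjects=len(ids),
        fits=fits,
        preferred_by_aic=preferred_by_aic,
        preferred_by_mape=preferred_by_mape,
        fold_assignment=fold_assignment,
    )
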