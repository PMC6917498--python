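"""Ridge-regularized partial correlation networks from component time series.

Each subject contributes a T x K matrix of ICA component time courses.  Direct
(conditional) coupling between components i and j is estimated as the partial
correlation derived from a Tikhonov-regularized precision matrix

    P = (C + rho * I)^{-1},      r_ij = -p_ij / sqrt(p_ii * p_jj)

with C the (optionally diagonal-normalized) sample covariance.  Partial
correlations are variance-stabilized with Fisher's z transform (arctanh) and the
lower triangle is flattened into a canonical edge vector for group analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import DegenerateDataError, ValidationError

__all__ = [
    "ConnectivityConfig",
    "EdgeVector",
    "ridge_partial_correlation",
    "fisher_z",
    "extract_edges",
    "rebuild_matrix",
    "edge_labels",
    "compute_edge_vectors",
]


@dataclass(frozen=True)
class ConnectivityConfig:
    """Parameters of the partial-correlation estimator.

    rho
        Non-negative ridge strength added to the covariance diagonal before
        inversion.  The default of 1 matches the convention of reference
        netmat toolboxes when the covariance is diagonal-normalized.
    normalize_covariance
        Rescale the covariance by the root-mean-square of its diagonal so that
        a given rho has comparable strength across subjects with different
        signal scales.  Disable for oracle comparisons against a known
        precision matrix.
    fisher
        Apply arctanh to the extracted edges.
    """

    rho: float = 1.0
    normalize_covariance: bool = True
    fisher: bool = True

    def __post_init__(self) -> None:
        if not np.isfinite(self.rho) or self.rho < 0:
            raise ValidationError(f"rho must be finite and >= 0, got {self.rho}")


@dataclass
class EdgeVector:
    """Flattened lower triangle of one subject's connectivity matrix.

    Edges follow the canonical row-major lower-triangle order
    (2,1),(3,1),(3,2),(4,1),... so that position is comparable across
    subjects.  ``labels[k]`` is the (component_i, component_j) pair with i > j.
    """

    subject_id: str
    labels: list[tuple[str, str]]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.labels) != self.values.shape[0]:
            raise ValidationError("edge labels and values disagree in length")

    def __len__(self) -> int:
        return self.values.shape[0]

    def as_dict(self) -> dict[tuple[str, str], float]:
        return dict(zip(self.labels, self.values))


def _validate_timeseries(values: np.ndarray) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.ndim != 2:
        raise ValidationError("time series must be a 2-D T x K array")
    if not np.all(np.isfinite(x)):
        raise ValidationError("time series contains non-finite values")
    t, k = x.shape
    if t < k + 2:
        raise ValidationError(f"need T >= K + 2 time points, got T={t}, K={k}")
    if np.any(np.ptp(x, axis=0) == 0):
        bad = np.nonzero(np.ptp(x, axis=0) == 0)[0].tolist()
        raise DegenerateDataError(f"constant component column(s): {bad}")
    return x


def ridge_partial_correlation(
    timeseries, config: ConnectivityConfig | None = None
) -> np.ndarray:
    """Tikhonov-regularized partial correlation matrix of one subject.

    ``timeseries`` may be a plain T x K array or any object with a ``values``
    attribute holding one (e.g. :class:`geoconn.cohort.ComponentTimeSeries`).
    Returns a symmetric K x K matrix with zero diagonal and entries in [-1, 1].
    """
    config = config or ConnectivityConfig()
    values = getattr(timeseries, "values", timeseries)
    x = _validate_timeseries(values)
    t = x.shape[0]

    x = x - x.mean(axis=0)
    cov = (x.T @ x) / (t - 1)
    if config.normalize_covariance:
        scale = np.sqrt(np.mean(np.diag(cov) ** 2))
        cov = cov / scale
    prec = np.linalg.inv(cov + config.rho * np.eye(cov.shape[0]))
    d = np.sqrt(np.diag(prec))
    r = -prec / np.outer(d, d)
    np.fill_diagonal(r, 0.0)
    # exact symmetry despite floating-point inversion noise
    r = (r + r.T) / 2.0
    return np.clip(r, -1.0, 1.0)


def fisher_z(r):
    """Fisher's variance-stabilizing transform z = arctanh(r).

    Accepts scalars or arrays; requires |r| < 1 elementwise.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) >= 1) or not np.all(np.isfinite(arr)):
        raise ValidationError("fisher_z requires |r| < 1")
    out = np.arctanh(arr)
    return float(out) if np.isscalar(r) or arr.ndim == 0 else out


def edge_labels(component_labels: Sequence[str]) -> list[tuple[str, str]]:
    """Canonical lower-triangle edge order for a component list."""
    k = len(component_labels)
    rows, cols = np.tril_indices(k, -1)
    return [(component_labels[i], component_labels[j]) for i, j in zip(rows, cols)]


def extract_edges(
    matrix: np.ndarray,
    subject_id: str,
    component_labels: Sequence[str] | None = None,
    fisher: bool = False,
) -> EdgeVector:
    """Flatten the lower triangle of a symmetric connectivity matrix.

    Raises if the matrix is asymmetric beyond 1e-10.  With ``fisher=True`` the
    extracted correlations are arctanh-transformed (the diagonal is never
    touched, so the +-1 diagonal of a full-correlation matrix is harmless).
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValidationError("connectivity matrix must be square")
    if np.max(np.abs(m - m.T)) > 1e-10:
        raise ValidationError("connectivity matrix is asymmetric beyond 1e-10")
    k = m.shape[0]
    if component_labels is None:
        component_labels = [f"C{i + 1}" for i in range(k)]
    if len(component_labels) != k:
        raise ValidationError("component_labels length must match matrix size")
    rows, cols = np.tril_indices(k, -1)
    vals = m[rows, cols]
    if fisher:
        vals = fisher_z(vals)
    return EdgeVector(
        subject_id=subject_id, labels=edge_labels(component_labels), values=vals
    )


def rebuild_matrix(edges: EdgeVector, diagonal: float = 0.0) -> np.ndarray:
    """Inverse of :func:`extract_edges` up to the (unanalyzed) diagonal."""
    n_edges = len(edges)
    k = int(round((1 + np.sqrt(1 + 8 * n_edges)) / 2))
    if k * (k - 1) // 2 != n_edges:
        raise ValidationError(f"{n_edges} edges do not form a triangular number")
    m = np.full((k, k), diagonal, dtype=float)
    rows, cols = np.tril_indices(k, -1)
    m[rows, cols] = edges.values
    m[cols, rows] = edges.values
    return m


def compute_edge_vectors(
    timeseries_list, config: ConnectivityConfig | None = None
) -> list[EdgeVector]:
    """Per-subject edge vectors for a whole cohort (Fisher-z by default)."""
    config = config or ConnectivityConfig()
    out = []
    for ts in timeseries_list:
        r = ridge_partial_correlation(ts, config)
        out.append(
            extract_edges(
                r,
                subject_id=ts.subject_id,
                component_labels=list(ts.component_labels),
                fisher=config.fisher,
            )
        )
    return out
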