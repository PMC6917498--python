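"""Synthetic toddler cohorts with group-structured component time series.

The generator emulates the data layout of an eye-tracking-stratified toddler
rsfMRI study: six groups (two eye-tracking-defined ASD subtypes, ASD without
eye tracking, language/developmental delay, TD siblings of ASD children, and
TD), per-subject T x K component time series whose stationary precision matrix
carries planted group-specific partial correlations, percent-geometric
fixation distributions straddling the 69% subtype cutoff, ADOS social affect
scores optionally coupled to a subject's true connectivity on a chosen edge,
and random-walk motion traces with a controlled mean framewise displacement.

Planting works on the precision (inverse covariance) scale: the base precision
is the identity, and a target partial correlation r on edge (i, j) is planted
as the off-diagonal entry -r.  With a unit diagonal the partial correlation of
the resulting matrix equals r exactly, which makes the generator its own
closed-form oracle (see :func:`true_edge_values`).  Per-subject heterogeneity
is added by jittering planted entries around the group target; positive
definiteness is enforced by shrinking off-diagonals when needed.

Temporal structure is AR(1): innovations are drawn with covariance
(1 - phi^2) * Sigma so the filtered process has stationary covariance Sigma,
the inverse of the group precision.  The oracle is therefore exact at any T.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np

from .exceptions import ConfigurationError, ValidationError

__all__ = [
    "ASD_GROUPS",
    "NON_ASD_GROUPS",
    "ALL_GROUPS",
    "EdgeEffect",
    "BehaviorCoupling",
    "FixationDistribution",
    "CohortConfig",
    "SubjectRecord",
    "ComponentTimeSeries",
    "MotionTrace",
    "Cohort",
    "generate_cohort",
    "true_edge_values",
]

ASD_GROUPS = ("GeoPref ASD", "nonGeo ASD", "ASD-noET")
NON_ASD_GROUPS = ("LD/DD", "TD ASDSib", "TD")
ALL_GROUPS = ASD_GROUPS + NON_ASD_GROUPS

#: Group sizes of the reference design (total n = 195).
DEFAULT_GROUP_SIZES: dict[str, int] = {
    "GeoPref ASD": 16,
    "nonGeo ASD": 62,
    "ASD-noET": 31,
    "LD/DD": 15,
    "TD ASDSib": 16,
    "TD": 55,
}

#: Male fraction per group (reference design sex counts).
DEFAULT_SEX_RATIO: dict[str, float] = {
    "GeoPref ASD": 11 / 16,
    "nonGeo ASD": 49 / 62,
    "ASD-noET": 27 / 31,
    "LD/DD": 10 / 15,
    "TD ASDSib": 8 / 16,
    "TD": 37 / 55,
}

#: Mean framewise displacement (mm) per group in the reference design.
DEFAULT_MOTION_LEVEL: dict[str, float] = {
    "GeoPref ASD": 0.06,
    "nonGeo ASD": 0.09,
    "ASD-noET": 0.09,
    "LD/DD": 0.10,
    "TD ASDSib": 0.08,
    "TD": 0.10,
}

#: Between-subject SD of mean FD per group (reference design).
DEFAULT_MOTION_SD: dict[str, float] = {
    "GeoPref ASD": 0.02,
    "nonGeo ASD": 0.12,
    "ASD-noET": 0.08,
    "LD/DD": 0.05,
    "TD ASDSib": 0.04,
    "TD": 0.11,
}


class EdgeEffect(NamedTuple):
    """Planted group-level partial correlation on one component pair."""

    edge: tuple[str, str]
    group: str
    partial_r: float


class BehaviorCoupling(NamedTuple):
    """Linear coupling of ADOS social affect to a subject's true edge value.

    ``target_r`` is the correlation (on the true-edge scale) the generated
    scores are calibrated to; ``noise_sd`` is the residual SD on the ADOS
    scale.
    """

    edge: tuple[str, str]
    group: str
    target_r: float
    noise_sd: float = 3.5


class FixationDistribution(NamedTuple):
    """Per-group normal law (mean, sd) of percent-geometric fixation."""

    mean: float
    sd: float


def _default_edge_effects() -> list[EdgeEffect]:
    """DMN hypoconnectivity with visual/attention components, strongest and
    OTC-specific in the GeoPref subtype."""
    effects: list[EdgeEffect] = []
    plan = {
        ("DMN", "OTC"): {
            "TD": 0.30, "TD ASDSib": 0.30, "LD/DD": 0.30,
            "nonGeo ASD": 0.18, "ASD-noET": 0.18, "GeoPref ASD": 0.02,
        },
        ("DMN", "PVC"): {
            "TD": 0.28, "TD ASDSib": 0.28, "LD/DD": 0.28,
            "nonGeo ASD": 0.15, "ASD-noET": 0.15, "GeoPref ASD": 0.12,
        },
        ("DMN", "DAN"): {
            "TD": 0.25, "TD ASDSib": 0.25, "LD/DD": 0.25,
            "nonGeo ASD": 0.13, "ASD-noET": 0.13, "GeoPref ASD": 0.13,
        },
    }
    for edge, per_group in plan.items():
        for group, r in per_group.items():
            effects.append(EdgeEffect(edge, group, r))
    return effects


def _default_fixation() -> dict[str, FixationDistribution]:
    return {
        "GeoPref ASD": FixationDistribution(80.0, 8.0),
        "nonGeo ASD": FixationDistribution(40.0, 14.0),
        "LD/DD": FixationDistribution(45.0, 15.0),
        "TD ASDSib": FixationDistribution(30.0, 12.0),
        "TD": FixationDistribution(32.0, 12.0),
    }


@dataclass
class CohortConfig:
    """Everything the generator needs; defaults mirror the reference design."""

    group_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    n_timepoints: int = 150
    repetition_time: float = 2.5
    component_labels: Sequence[str] = (
        "DMN", "OTC", "PVC", "DAN", "IC05", "IC06", "IC07", "IC08", "IC09", "IC10",
    )
    ar_coefficient: float = 0.3
    edge_effects: list[EdgeEffect] = field(default_factory=_default_edge_effects)
    behavior_coupling: list[BehaviorCoupling] = field(
        default_factory=lambda: [
            BehaviorCoupling(("DMN", "OTC"), "GeoPref ASD", -0.78, 3.5)
        ]
    )
    #: Between-subject SD of the true planted partial correlations.
    subject_edge_sd: float = 0.2
    fixation_distributions: dict[str, FixationDistribution] = field(
        default_factory=_default_fixation
    )
    geo_cutoff_pct: float = 69.0
    age_range_months: tuple[float, float] = (12.0, 48.0)
    sex_ratio: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SEX_RATIO))
    motion_level: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MOTION_LEVEL)
    )
    #: Between-subject SD of each subject's expected mean FD (lognormal law).
    motion_sd: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MOTION_SD)
    )
    seed: int = 0

    @property
    def n_components(self) -> int:
        return len(self.component_labels)

    @property
    def n_subjects(self) -> int:
        return sum(self.group_sizes.values())

    def validate(self) -> None:
        if not self.group_sizes:
            raise ConfigurationError("group_sizes is empty")
        for g, n in self.group_sizes.items():
            if g not in ALL_GROUPS:
                raise ConfigurationError(f"unknown group label {g!r}")
            if n <= 0:
                raise ConfigurationError(f"group size for {g!r} must be > 0")
        if self.n_components < 2:
            raise ConfigurationError("need at least 2 components")
        if len(set(self.component_labels)) != self.n_components:
            raise ConfigurationError("component labels must be unique")
        if self.n_timepoints < self.n_components + 2:
            raise ConfigurationError("n_timepoints must be >= n_components + 2")
        if not 0 <= self.ar_coefficient < 1:
            raise ConfigurationError("ar_coefficient must be in [0, 1)")
        if self.repetition_time <= 0:
            raise ConfigurationError("repetition_time must be positive")
        if not 0 < self.geo_cutoff_pct < 100:
            raise ConfigurationError("geo_cutoff_pct must be in (0, 100)")
        if self.subject_edge_sd < 0:
            raise ConfigurationError("subject_edge_sd must be >= 0")
        labels = set(self.component_labels)
        for eff in self.edge_effects:
            ci, cj = eff.edge
            if ci not in labels or cj not in labels or ci == cj:
                raise ConfigurationError(f"edge effect on invalid pair {eff.edge!r}")
            if eff.group not in ALL_GROUPS:
                raise ConfigurationError(f"edge effect on unknown group {eff.group!r}")
            if not -1 < eff.partial_r < 1:
                raise ConfigurationError(
                    f"target partial correlation {eff.partial_r} outside (-1, 1)"
                )
        for bc in self.behavior_coupling:
            ci, cj = bc.edge
            if ci not in labels or cj not in labels or ci == cj:
                raise ConfigurationError(f"behavior coupling on invalid pair {bc.edge!r}")
            if bc.group not in ASD_GROUPS:
                raise ConfigurationError(
                    "behavior coupling only meaningful for ASD groups (ADOS carriers)"
                )
            if not -1 < bc.target_r < 1 or bc.noise_sd <= 0:
                raise ConfigurationError("invalid behavior coupling parameters")
        lo, hi = self.age_range_months
        if not lo < hi:
            raise ConfigurationError("age_range_months must be an increasing interval")


@dataclass
class SubjectRecord:
    """One row of the tidy per-subject table."""

    subject_id: str
    group: str
    sex: str  # "M" or "F"
    age_scan_months: float
    age_et_months: float | None = None
    pct_geo: float | None = None
    ados_sa: float | None = None
    mean_fd: float | None = None
    mean_dvars: float | None = None

    def __post_init__(self) -> None:
        if self.group not in ALL_GROUPS:
            raise ValidationError(f"unknown group label {self.group!r}")
        if self.sex not in ("M", "F"):
            raise ValidationError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if self.pct_geo is not None and not 0 <= self.pct_geo <= 100:
            raise ValidationError(f"pct_geo {self.pct_geo} outside [0, 100]")
        if self.mean_fd is not None and self.mean_fd < 0:
            raise ValidationError("mean_fd must be >= 0")
        if self.ados_sa is not None and self.ados_sa < 0:
            raise ValidationError("ados_sa must be >= 0")

    @property
    def is_asd(self) -> bool:
        return self.group in ASD_GROUPS


@dataclass
class ComponentTimeSeries:
    """T x K component time courses of one subject."""

    subject_id: str
    values: np.ndarray = field(repr=False)
    component_labels: Sequence[str] = ()
    repetition_time: float = 2.5

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be T x K")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("values contain non-finite entries")
        t, k = self.values.shape
        if len(self.component_labels) != k:
            raise ValidationError("component_labels must have K entries")
        if t < k + 2:
            raise ValidationError("need T >= K + 2 for estimability")


@dataclass
class MotionTrace:
    """T x 6 rigid-body parameters: 3 translations (mm), 3 rotations (rad)."""

    subject_id: str
    params: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValidationError("motion params must be T x 6")


class Cohort(NamedTuple):
    records: list[SubjectRecord]
    timeseries: list[ComponentTimeSeries]
    motion: list[MotionTrace]


# ---------------------------------------------------------------------------
# precision-matrix construction


def _build_precision(
    k: int,
    planted: Mapping[tuple[int, int], float],
    min_eig: float = 0.05,
    shrink: float = 0.9,
    max_shrink: int = 200,
) -> np.ndarray:
    """Unit-diagonal precision with off-diagonal -r per planted edge.

    If the result is not comfortably positive definite, all off-diagonals are
    shrunk geometrically until it is (reject-and-shrink).
    """
    theta = np.eye(k)
    for (i, j), r in planted.items():
        theta[i, j] = theta[j, i] = -r
    for _ in range(max_shrink):
        if np.linalg.eigvalsh(theta).min() >= min_eig:
            return theta
        off = theta - np.diag(np.diag(theta))
        theta = np.eye(k) + shrink * off
    raise ConfigurationError("could not make planted precision positive definite")


def _group_planted(
    config: CohortConfig, group: str
) -> dict[tuple[int, int], float]:
    idx = {c: i for i, c in enumerate(config.component_labels)}
    planted: dict[tuple[int, int], float] = {}
    for eff in config.edge_effects:
        if eff.group != group:
            continue
        i, j = idx[eff.edge[0]], idx[eff.edge[1]]
        key = (max(i, j), min(i, j))
        planted[key] = eff.partial_r
    return planted


def true_edge_values(config: CohortConfig) -> dict[tuple[tuple[str, str], str], float]:
    """Exact partial correlations implied by each group's generating precision.

    Keys are ((component_i, component_j), group) with the edge in canonical
    lower-triangle orientation; covers every component pair, including the
    (zero) unplanted ones.
    """
    config.validate()
    out: dict[tuple[tuple[str, str], str], float] = {}
    labels = list(config.component_labels)
    for group in config.group_sizes:
        theta = _build_precision(config.n_components, _group_planted(config, group))
        d = np.sqrt(np.diag(theta))
        r = -theta / np.outer(d, d)
        rows, cols = np.tril_indices(config.n_components, -1)
        for i, j in zip(rows, cols):
            out[((labels[i], labels[j]), group)] = float(r[i, j])
    return out


# ---------------------------------------------------------------------------
# sampling helpers


def _sample_timeseries(
    rng: np.random.Generator, sigma_chol: np.ndarray, t: int, phi: float
) -> np.ndarray:
    """Stationary AR(1) draw with stationary covariance L @ L.T."""
    k = sigma_chol.shape[0]
    e = rng.standard_normal((t, k)) @ sigma_chol.T
    x = np.empty((t, k))
    x[0] = e[0]
    scale = np.sqrt(1.0 - phi**2)
    for i in range(1, t):
        x[i] = phi * x[i - 1] + scale * e[i]
    return x


def _sample_pct_geo(
    rng: np.random.Generator, dist: FixationDistribution, group: str, cutoff: float
) -> float:
    """Truncated-normal fixation percentage consistent with the subtype label."""
    for _ in range(10000):
        v = rng.normal(dist.mean, dist.sd)
        v = float(np.clip(v, 0.0, 100.0))
        if group == "GeoPref ASD" and v < cutoff:
            continue
        if group != "GeoPref ASD" and v >= cutoff:
            continue
        return v
    raise ConfigurationError(
        f"fixation distribution for {group!r} incompatible with the {cutoff}% cutoff"
    )


def _subject_fd_target(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Subject-level expected mean FD: lognormal with the group's moments.

    A lognormal keeps FD positive and right-skewed, matching how a few
    high-movers inflate group SDs in toddler scans.
    """
    if sd <= 0:
        return mean
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, np.sqrt(sigma2)))


def _motion_trace(
    rng: np.random.Generator, t: int, mean_fd: float, radius: float = 50.0
) -> np.ndarray:
    """Random-walk motion parameters with expected mean FD ``mean_fd``.

    Each of the six parameters is a cumulative sum of Gaussian steps; rotation
    step size is divided by the FD rotation radius so translations and
    rotations contribute equally.  E|step| = s * sqrt(2/pi) per parameter, so
    s = mean_fd / (6 * sqrt(2/pi)).
    """
    s = mean_fd / (6.0 * np.sqrt(2.0 / np.pi))
    steps = rng.normal(0.0, s, size=(t, 6))
    steps[:, 3:] /= radius
    steps[0] = 0.0
    return np.cumsum(steps, axis=0)


def _ados_scores(
    rng: np.random.Generator,
    n: int,
    subject_edges: np.ndarray | None,
    coupling: BehaviorCoupling | None,
    base_mean: float,
    base_sd: float = 4.0,
) -> np.ndarray:
    """ADOS social affect totals, optionally coupled to true edge values.

    With coupling, scores are mu + b*(e - mean(e)) + noise where b is
    calibrated against the realized spread of the group's true edge values so
    the generating correlation equals ``target_r``.
    """
    if coupling is None or subject_edges is None:
        return np.clip(rng.normal(base_mean, base_sd, size=n), 0.0, None)
    e = subject_edges - subject_edges.mean()
    sd_e = e.std(ddof=1) if n > 1 else 0.0
    rho = coupling.target_r
    if sd_e > 0:
        b = rho / np.sqrt(1.0 - rho**2) * coupling.noise_sd / sd_e
    else:
        b = 0.0
    scores = base_mean + b * e + rng.normal(0.0, coupling.noise_sd, size=n)
    return np.clip(scores, 0.0, None)


# ---------------------------------------------------------------------------
# main generator


def generate_cohort(config: CohortConfig | None = None) -> Cohort:
    """Draw a full cohort: subject records, time series, and motion traces.

    Deterministic given (config, config.seed): identical inputs reproduce the
    outputs bit-for-bit.
    """
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    k = config.n_components
    labels = list(config.component_labels)
    idx = {c: i for i, c in enumerate(labels)}

    records: list[SubjectRecord] = []
    timeseries: list[ComponentTimeSeries] = []
    motion: list[MotionTrace] = []

    sid = 0
    for group in config.group_sizes:
        n = config.group_sizes[group]
        planted = _group_planted(config, group)
        coupling = next(
            (bc for bc in config.behavior_coupling if bc.group == group), None
        )
        coupling_key = None
        if coupling is not None:
            i, j = idx[coupling.edge[0]], idx[coupling.edge[1]]
            coupling_key = (max(i, j), min(i, j))

        # deterministic sex counts, shuffled order
        n_male = int(round(config.sex_ratio.get(group, 0.5) * n))
        sexes = np.array(["M"] * n_male + ["F"] * (n - n_male))
        rng.shuffle(sexes)

        lo, hi = config.age_range_months
        ages = rng.uniform(lo, hi, size=n)

        group_sids = [f"sub-{sid + i + 1:04d}" for i in range(n)]
        sid += n

        # per-subject true edges and time series
        subject_coupled_edge = np.empty(n)
        for s in range(n):
            subj_planted: dict[tuple[int, int], float] = {}
            for key, r in planted.items():
                jitter = rng.normal(0.0, config.subject_edge_sd)
                subj_planted[key] = float(np.clip(r + jitter, -0.9, 0.9))
            theta = _build_precision(k, subj_planted)
            d = np.sqrt(np.diag(theta))
            partials = -theta / np.outer(d, d)
            if coupling_key is not None:
                subject_coupled_edge[s] = partials[coupling_key]
            sigma = np.linalg.inv(theta)
            chol = np.linalg.cholesky(sigma)
            x = _sample_timeseries(
                rng, chol, config.n_timepoints, config.ar_coefficient
            )
            timeseries.append(
                ComponentTimeSeries(
                    subject_id=group_sids[s],
                    values=x,
                    component_labels=labels,
                    repetition_time=config.repetition_time,
                )
            )
            fd_target = _subject_fd_target(
                rng,
                config.motion_level.get(group, 0.09),
                config.motion_sd.get(group, 0.0),
            )
            motion.append(
                MotionTrace(
                    subject_id=group_sids[s],
                    params=_motion_trace(rng, config.n_timepoints, fd_target),
                )
            )

        # behavior: ADOS only for ASD groups, more severe in the GeoPref subtype
        if group in ASD_GROUPS:
            base_mean = 14.0 if group == "GeoPref ASD" else 11.0
            ados = _ados_scores(
                rng,
                n,
                subject_coupled_edge if coupling_key is not None else None,
                coupling,
                base_mean,
            )
        else:
            ados = None

        # eye tracking: missing for ASD-noET
        has_et = group != "ASD-noET"
        dist = config.fixation_distributions.get(group)
        for s in range(n):
            pct = None
            age_et = None
            if has_et and dist is not None:
                pct = _sample_pct_geo(rng, dist, group, config.geo_cutoff_pct)
                age_et = float(np.clip(ages[s] - abs(rng.normal(1.5, 2.0)), 6.0, None))
            records.append(
                SubjectRecord(
                    subject_id=group_sids[s],
                    group=group,
                    sex=str(sexes[s]),
                    age_scan_months=float(ages[s]),
                    age_et_months=age_et,
                    pct_geo=pct,
                    ados_sa=float(ados[s]) if ados is not None else None,
                )
            )

    return Cohort(records, timeseries, motion)
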