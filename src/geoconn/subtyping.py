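"""Eye-tracking subtype classification and competing design labelings.

ASD toddlers who fixate the dynamic geometric stimulus for at least 69% of
test time are labeled "GeoPref ASD"; the rest are "nonGeo ASD".  Three design
labelings compete downstream:

* ``case_control`` — all ASD collapsed to one label; LD/DD, TD ASDSib and TD
  kept as separate comparison groups (never pooled into one "control" level).
* ``subtype`` — ASD split into GeoPref/nonGeo; ASD subjects without eye
  tracking cannot be stratified and are excluded.
* ``transdiagnostic`` — the continuous percent-geometric fixation replaces any
  group label; subjects without eye tracking are excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .cohort import ASD_GROUPS, SubjectRecord
from .exceptions import DesignError, ValidationError

__all__ = ["SCHEMES", "SubtypingConfig", "DesignLabeling", "classify_geopref", "build_design"]

SCHEMES = ("case_control", "subtype", "transdiagnostic")


@dataclass(frozen=True)
class SubtypingConfig:
    """69% cutoff on percent-geometric fixation; "69% or more" is inclusive."""

    cutoff_pct: float = 69.0
    inclusive: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.cutoff_pct < 100:
            raise ValidationError("cutoff_pct must be in (0, 100)")


@dataclass
class DesignLabeling:
    """Per-subject label (or continuous value) under one modeling scheme.

    ``labels`` maps subject_id to a group label for the categorical schemes or
    to the pct_geo value for the transdiagnostic scheme.  ``excluded`` lists
    subjects the scheme cannot accommodate (no eye tracking).
    """

    scheme: str
    labels: dict[str, object]
    excluded: list[str]

    @property
    def n(self) -> int:
        return len(self.labels)


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def classify_geopref(
    pct_geo: float | None, config: SubtypingConfig | None = None
) -> str | None:
    """Subtype label from percent-geometric fixation.

    Returns "GeoPref ASD" at/above the cutoff, "nonGeo ASD" below, and None
    (unstratifiable) for missing input.
    """
    config = config or SubtypingConfig()
    if _is_missing(pct_geo):
        return None
    if not 0 <= pct_geo <= 100:
        raise ValidationError(f"pct_geo {pct_geo} outside [0, 100]")
    if config.inclusive:
        return "GeoPref ASD" if pct_geo >= config.cutoff_pct else "nonGeo ASD"
    return "GeoPref ASD" if pct_geo > config.cutoff_pct else "nonGeo ASD"


def build_design(
    records: list[SubjectRecord],
    scheme: str,
    config: SubtypingConfig | None = None,
) -> DesignLabeling:
    """Construct one of the three competing design labelings.

    Exclusions are explicit: the subtype and transdiagnostic schemes drop
    subjects lacking eye tracking (on the reference design exactly the 31
    ASD-noET toddlers).
    """
    if scheme not in SCHEMES:
        raise ValidationError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    if not records:
        raise ValidationError("records is empty")
    config = config or SubtypingConfig()

    labels: dict[str, object] = {}
    excluded: list[str] = []
    for rec in records:
        if scheme == "case_control":
            labels[rec.subject_id] = "ASD" if rec.group in ASD_GROUPS else rec.group
        elif scheme == "subtype":
            if rec.group in ASD_GROUPS:
                sub = classify_geopref(rec.pct_geo, config)
                if sub is None:
                    excluded.append(rec.subject_id)
                else:
                    labels[rec.subject_id] = sub
            else:
                labels[rec.subject_id] = rec.group
        else:  # transdiagnostic: continuous fixation, no group variable
            if _is_missing(rec.pct_geo):
                excluded.append(rec.subject_id)
            else:
                labels[rec.subject_id] = float(rec.pct_geo)

    if scheme == "subtype" and not any(
        v in ("GeoPref ASD", "nonGeo ASD") for v in labels.values()
    ):
        raise DesignError("subtype scheme requires at least one eye-tracked ASD subject")
    if scheme == "case_control" and len(set(labels.values())) < 2:
        raise DesignError("case-control scheme needs at least two group labels")
    if scheme == "transdiagnostic" and not labels:
        raise DesignError("transdiagnostic scheme has no eye-tracked subjects")
    return DesignLabeling(scheme=scheme, labels=labels, excluded=excluded)
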