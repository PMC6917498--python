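"""Head-motion quality control: framewise displacement and DVARS.

Framewise displacement (FD) at frame transition t is the sum of absolute
backward differences of the three translations (mm) plus the three rotations
converted to arc length on a sphere of configurable radius (default 50 mm).
DVARS is the root-mean-square, across signal dimensions, of the backward
temporal difference — computed here on component time series, since this
pipeline carries no voxel data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import group_stats
from .exceptions import ValidationError

__all__ = ["QCSummary", "framewise_displacement", "dvars", "qc_group_balance"]

DEFAULT_ROTATION_RADIUS_MM = 50.0


@dataclass
class QCSummary:
    subject_id: str
    mean_fd: float
    fd_series: np.ndarray = field(repr=False)
    rotation_radius: float = DEFAULT_ROTATION_RADIUS_MM
    mean_dvars: float | None = None
    dvars_series: np.ndarray | None = field(repr=False, default=None)


def framewise_displacement(
    trace,
    rotation_radius: float = DEFAULT_ROTATION_RADIUS_MM,
    degrees: bool = False,
) -> QCSummary:
    """FD series and mean for one motion trace (T x 6, translations then
    rotations).  Rotations are radians unless ``degrees=True``."""
    params = np.asarray(getattr(trace, "params", trace), dtype=float)
    if params.ndim != 2 or params.shape[1] != 6:
        raise ValidationError("motion trace must be T x 6")
    if params.shape[0] < 2:
        raise ValidationError("need at least 2 frames")
    if not np.all(np.isfinite(params)):
        raise ValidationError("non-finite motion parameters")
    rot = params[:, 3:]
    if degrees:
        rot = np.deg2rad(rot)
    diffs_t = np.abs(np.diff(params[:, :3], axis=0)).sum(axis=1)
    diffs_r = (np.abs(np.diff(rot, axis=0)) * rotation_radius).sum(axis=1)
    fd = diffs_t + diffs_r
    return QCSummary(
        subject_id=getattr(trace, "subject_id", ""),
        mean_fd=float(fd.mean()),
        fd_series=fd,
        rotation_radius=rotation_radius,
    )


def dvars(signal) -> tuple[np.ndarray, float]:
    """Per-transition RMS of the backward difference of a T x M signal."""
    x = np.asarray(getattr(signal, "values", signal), dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[0] < 2:
        raise ValidationError("need at least 2 time points")
    if not np.all(np.isfinite(x)):
        raise ValidationError("non-finite signal values")
    series = np.sqrt(np.mean(np.diff(x, axis=0) ** 2, axis=1))
    return series, float(series.mean())


def qc_group_balance(values, groups) -> tuple[float, tuple[int, int], float]:
    """One-way ANOVA of a QC summary (mean FD or mean DVARS) across groups."""
    return group_stats.oneway_anova(values, groups)
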