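"""Power analysis for the unbalanced two-sample design (n=16 vs n=55).

Monte-Carlo power draws both groups from unit-variance normal populations
separated by a standardized difference d and applies the two-sided
pooled-variance (Student) t-test; the analytic oracle is the noncentral-t
power with noncentrality delta = d * sqrt(n1*n2/(n1+n2)) and df = n1+n2-2.
The minimum detectable effect for a target power is found by bisection on the
analytic curve.

Samples are drawn i.i.d. from the normal law rather than without replacement
from a large finite population: at n = 16/55 the two are statistically
indistinguishable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import ConfigurationError, GeoconnError

__all__ = ["PowerSimResult", "empirical_power", "analytic_power", "min_detectable_d"]


@dataclass
class PowerSimResult:
    d: float
    n1: int
    n2: int
    alpha: float
    n_experiments: int
    power_hat: float
    se_hat: float
    method: str = "simulation"


def _validate(d: float, n1: int, n2: int, alpha: float) -> None:
    if not np.isfinite(d):
        raise ConfigurationError("d must be finite")
    if n1 < 2 or n2 < 2:
        raise ConfigurationError("both group sizes must be >= 2")
    if not 0 < alpha < 1:
        raise ConfigurationError("alpha must be in (0, 1)")


def empirical_power(
    d: float,
    n1: int,
    n2: int,
    alpha: float = 0.05,
    n_experiments: int = 100000,
    seed: int | None = 0,
) -> PowerSimResult:
    """Monte-Carlo rejection rate of the two-sided pooled-variance t-test.

    Each experiment draws n1 values from Normal(d, 1) and n2 from
    Normal(0, 1).  Vectorized across experiments; deterministic given seed.
    """
    _validate(d, n1, n2, alpha)
    if n_experiments < 1:
        raise ConfigurationError("n_experiments must be >= 1")
    rng = np.random.default_rng(seed)
    df = n1 + n2 - 2
    t_crit = stats.t.ppf(1 - alpha / 2, df)
    n_reject = 0
    remaining = n_experiments
    while remaining > 0:
        m = min(remaining, 200000)
        x = rng.standard_normal((m, n1)) + d
        y = rng.standard_normal((m, n2))
        vx = x.var(axis=1, ddof=1)
        vy = y.var(axis=1, ddof=1)
        sp = np.sqrt(((n1 - 1) * vx + (n2 - 1) * vy) / df)
        t = (x.mean(axis=1) - y.mean(axis=1)) / (sp * np.sqrt(1 / n1 + 1 / n2))
        n_reject += int(np.sum(np.abs(t) > t_crit))
        remaining -= m
    power_hat = n_reject / n_experiments
    se_hat = float(np.sqrt(power_hat * (1 - power_hat) / n_experiments))
    return PowerSimResult(
        d=d, n1=n1, n2=n2, alpha=alpha, n_experiments=n_experiments,
        power_hat=float(power_hat), se_hat=se_hat, method="simulation",
    )


def analytic_power(d: float, n1: int, n2: int, alpha: float = 0.05) -> float:
    """Noncentral-t power of the two-sided two-sample t-test."""
    _validate(d, n1, n2, alpha)
    df = n1 + n2 - 2
    t_crit = stats.t.ppf(1 - alpha / 2, df)
    delta = abs(d) * np.sqrt(n1 * n2 / (n1 + n2))
    if delta == 0:
        return float(alpha)
    return float(stats.nct.sf(t_crit, df, delta) + stats.nct.cdf(-t_crit, df, delta))


def min_detectable_d(
    n1: int,
    n2: int,
    alpha: float = 0.05,
    target_power: float = 0.80,
    tol: float = 1e-6,
) -> float:
    """Smallest d whose analytic power reaches the target, by bisection."""
    _validate(1.0, n1, n2, alpha)
    if not alpha < target_power < 1:
        raise ConfigurationError("target_power must lie in (alpha, 1)")
    lo, hi = 0.0, 1.0
    while analytic_power(hi, n1, n2, alpha) < target_power:
        hi *= 2.0
        if hi > 1e3:
            raise GeoconnError("bisection bracket expansion failed")
    for _ in range(200):
        mid = (lo + hi) / 2.0
        p = analytic_power(mid, n1, n2, alpha)
        if abs(p - target_power) < tol:
            return mid
        if p < target_power:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0
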