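"""Exact power mathematics for the two-sided two-sample t-test.

Every other stage of the adaptive design (futility cutoffs, interim efficacy
effects, simulator oracles) is derived from these three functions, so they use
the exact noncentral-t distribution rather than the large-sample normal
approximation: with per-group sizes in the 7-50 range the approximation is off
in the second decimal place of the minimum detectable effect.

The test modelled is the pooled-variance, equal-n, two-sided independent
t-test with ``df = 2n - 2`` and noncentrality ``ncp = d * sqrt(n / 2)`` where
``d`` is Cohen's d, the standardized mean difference ``(mu_test - mu_control)
/ sigma``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import InvalidParameterError, UnachievablePowerError

__all__ = [
    "EffectSpec",
    "power_t2",
    "required_n",
    "minimum_detectable_d",
]

#: Upper bracket for effect-size root finding; no sensory endpoint plausibly
#: exceeds a standardized difference of 20.
D_MAX = 20.0


@dataclass(frozen=True)
class EffectSpec:
    """A standardized effect with its raw-scale counterpart.

    Parameters
    ----------
    d : float
        Cohen's d (signed, dimensionless).
    sd : float
        Endpoint standard deviation in degrees C; must be positive.

    The raw mean difference is ``delta = d * sd`` (degrees C).
    """

    d: float
    sd: float = 2.5

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise InvalidParameterError(f"sd must be positive, got {self.sd}")

    @property
    def delta(self) -> float:
        return self.d * self.sd

    @classmethod
    def from_delta(cls, delta: float, sd: float = 2.5) -> "EffectSpec":
        if not sd > 0:
            raise InvalidParameterError(f"sd must be positive, got {sd}")
        return cls(d=delta / sd, sd=sd)


def _validate(n_per_group: int, alpha: float) -> None:
    if n_per_group < 2 or int(n_per_group) != n_per_group:
        raise InvalidParameterError(
            f"n_per_group must be an integer >= 2, got {n_per_group}"
        )
    if not 0 < alpha < 1:
        raise InvalidParameterError(f"alpha must be in (0, 1), got {alpha}")


def power_t2(d: float, n_per_group: int, alpha: float) -> float:
    """Exact power of the two-sided pooled two-sample t-test.

    Parameters
    ----------
    d : float
        True standardized effect (Cohen's d); the result is symmetric in its
        sign.
    n_per_group : int
        Participants per group (equal allocation), at least 2.
    alpha : float
        Two-sided significance level in (0, 1).

    Returns
    -------
    float
        P(reject H0) under the noncentral-t alternative with
        ``df = 2n - 2`` and ``ncp = d * sqrt(n / 2)``. Equals ``alpha``
        exactly at ``d = 0``.
    """
    _validate(n_per_group, alpha)
    df = 2 * n_per_group - 2
    ncp = d * math.sqrt(n_per_group / 2.0)
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    # nct tail probabilities underflow to NaN far beyond double precision;
    # those terms are zero for any representable power.
    upper = stats.nct.sf(t_crit, df, ncp)
    lower = stats.nct.cdf(-t_crit, df, ncp)
    upper = np.nan_to_num(upper, nan=0.0)
    lower = np.nan_to_num(lower, nan=0.0)
    return float(upper + lower)


def power_t2_vec(d: np.ndarray, n_per_group: int, alpha: float) -> np.ndarray:
    """Vectorized :func:`power_t2` over an array of effect sizes."""
    _validate(n_per_group, alpha)
    df = 2 * n_per_group - 2
    ncp = np.asarray(d, dtype=float) * math.sqrt(n_per_group / 2.0)
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    upper = np.nan_to_num(stats.nct.sf(t_crit, df, ncp), nan=0.0)
    lower = np.nan_to_num(stats.nct.cdf(-t_crit, df, ncp), nan=0.0)
    return upper + lower


def required_n(d: float, power: float = 0.80, alpha: float = 0.05) -> int:
    """Smallest per-group n with ``power_t2(d, n, alpha) >= power``.

    Seeds the search with the normal-approximation sample size
    ``n0 = 2 * ((z_{1-alpha/2} + z_power) / d)**2`` and walks to the exact
    boundary; ties (power exactly equal to the target) resolve to the smaller
    n.

    Raises
    ------
    UnachievablePowerError
        If ``d == 0`` (power never exceeds alpha for any finite n).
    """
    if not 0 < power < 1:
        raise InvalidParameterError(f"power must be in (0, 1), got {power}")
    if not 0 < alpha < 1:
        raise InvalidParameterError(f"alpha must be in (0, 1), got {alpha}")
    if d == 0:
        raise UnachievablePowerError(
            "d = 0: power equals alpha for every n; no finite sample size "
            f"reaches {power}"
        )
    if power <= alpha:
        return 2
    d = abs(d)
    z_a = stats.norm.ppf(1.0 - alpha / 2.0)
    z_b = stats.norm.ppf(power)
    n = max(2, int(math.floor(2.0 * ((z_a + z_b) / d) ** 2)) - 2)
    while power_t2(d, n, alpha) < power:
        n += 1
    while n > 2 and power_t2(d, n - 1, alpha) >= power:
        n -= 1
    return n


def minimum_detectable_d(
    n_per_group: int, power: float = 0.80, alpha: float = 0.05
) -> float:
    """Effect size at which the test attains the target power.

    Root-finds ``power_t2(d, n, alpha) = power`` on ``(0, D_MAX]`` and returns
    the (unique, by monotonicity) positive root.
    """
    _validate(n_per_group, alpha)
    if not 0 < power < 1:
        raise InvalidParameterError(f"power must be in (0, 1), got {power}")
    if power <= alpha:
        return 0.0

    def gap(d: float) -> float:
        return power_t2(d, n_per_group, alpha) - power

    if gap(D_MAX) < 0:
        raise InvalidParameterError(
            f"no effect size in (0, {D_MAX}] reaches power {power} at "
            f"n = {n_per_group}, alpha = {alpha}"
        )
    return float(optimize.brentq(gap, 1e-9, D_MAX, xtol=1e-12))
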