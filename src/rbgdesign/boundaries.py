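"""Alpha-spending and group-sequential boundary computation.

The adaptive design performs one interim look per allele group followed by a
final analysis, so the boundary machinery here is a two-look design: a look at
information fraction ``t1`` (interim per-group n over final per-group n) and a
look at 1. Under the canonical joint model the standardized test statistics at
the looks are multivariate normal with ``corr(Z_j, Z_k) = sqrt(t_j / t_k)``
for ``j <= k``, which is what :func:`crossing_probability` integrates over.

Two boundary constructions are offered:

``ldof_spending``
    Lan-DeMets O'Brien-Fleming spending, cumulative spend
    ``a(t) = 2 * (1 - Phi(z_{alpha/2} / sqrt(t)))``; the interim nominal level
    is the spend at ``t1`` and the final level is solved so the overall
    two-sided crossing probability equals ``alpha_total``.

``classic_of``
    The original O'Brien-Fleming boundary ``z_k = C / sqrt(t_k)`` with the
    constant ``C`` solved against the same joint crossing probability.

Note the deployed interim efficacy levels of the default study schedule are
design constants carried by the planner, not recomputed here; this module is
the from-first-principles calculator used when no constants are supplied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import InvalidParameterError

__all__ = [
    "LookSchedule",
    "of_spending_cumulative",
    "two_look_nominal_alphas",
    "crossing_probability",
]

#: Beyond this many looks the quasi-Monte-Carlo integrator becomes unreliable
#: at the 1e-4 tolerance the boundary solver needs; fall back to plain MC.
_MAX_EXACT_LOOKS = 4


@dataclass(frozen=True)
class LookSchedule:
    """An ordered set of analysis looks with their nominal two-sided levels.

    fractions are information fractions in (0, 1], strictly increasing with
    the last equal to 1; nominal_alphas are the per-look two-sided levels.
    """

    fractions: tuple[float, ...]
    alpha_total: float
    nominal_alphas: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        fr = self.fractions
        if not fr or any(not 0 < t <= 1 for t in fr):
            raise InvalidParameterError("fractions must lie in (0, 1]")
        if any(b <= a for a, b in zip(fr, fr[1:])):
            raise InvalidParameterError("fractions must be strictly increasing")
        if abs(fr[-1] - 1.0) > 1e-12:
            raise InvalidParameterError("last information fraction must be 1")
        if not 0 < self.alpha_total < 1:
            raise InvalidParameterError("alpha_total must be in (0, 1)")
        if self.nominal_alphas:
            if len(self.nominal_alphas) != len(fr):
                raise InvalidParameterError(
                    "nominal_alphas must match fractions in length"
                )
            if any(not 0 <= a <= self.alpha_total for a in self.nominal_alphas):
                raise InvalidParameterError(
                    "each nominal alpha must lie in [0, alpha_total]"
                )


def of_spending_cumulative(t: float, alpha_total: float = 0.05) -> float:
    """Cumulative alpha spent by information fraction ``t``.

    Lan-DeMets O'Brien-Fleming spending function
    ``a(t) = 2 * (1 - Phi(z_{alpha/2} / sqrt(t)))``; spends essentially
    nothing early and exhausts ``alpha_total`` at ``t = 1``.
    """
    if not 0 < t <= 1:
        raise InvalidParameterError(f"information fraction must be in (0, 1], got {t}")
    if not 0 < alpha_total < 1:
        raise InvalidParameterError(f"alpha_total must be in (0, 1), got {alpha_total}")
    z = stats.norm.ppf(1.0 - alpha_total / 2.0)
    return float(2.0 * stats.norm.sf(z / np.sqrt(t)))


def _look_correlation(fractions: Sequence[float]) -> np.ndarray:
    t = np.asarray(fractions, dtype=float)
    return np.sqrt(np.minimum.outer(t, t) / np.maximum.outer(t, t))


def _no_cross_probability(crit: np.ndarray, corr: np.ndarray) -> float:
    """P(|Z_k| < c_k for all k) for standard MVN Z with correlation corr."""
    finite = np.isfinite(crit)
    if not finite.any():
        return 1.0
    crit = crit[finite]
    corr = corr[np.ix_(finite, finite)]
    if crit.size == 1:
        return float(stats.norm.cdf(crit[0]) - stats.norm.cdf(-crit[0]))
    dist = stats.multivariate_normal(mean=np.zeros(crit.size), cov=corr)
    return float(dist.cdf(crit, lower_limit=-crit))


def _no_cross_probability_mc(
    crit: np.ndarray, corr: np.ndarray, draws: int = 2_000_000
) -> float:
    rng = np.random.default_rng(853_904_201)
    z = rng.multivariate_normal(np.zeros(len(crit)), corr, size=draws)
    return float(np.mean(np.all(np.abs(z) < crit, axis=1)))


def crossing_probability(
    nominal_alphas: Sequence[float], fractions: Sequence[float]
) -> float:
    """Overall two-sided type-1 error of a look schedule under H0.

    Computes ``P(any look rejects at its nominal level)`` by integrating the
    multivariate normal with ``corr(Z_j, Z_k) = sqrt(t_j / t_k)``. A nominal
    alpha of 0 makes a look unrejectable (infinite boundary). With more than
    four looks a Monte-Carlo fallback is used, with a warning.
    """
    fr = tuple(fractions)
    if not fr or any(not 0 < t <= 1 for t in fr):
        raise InvalidParameterError("fractions must lie in (0, 1]")
    if any(b <= a for a, b in zip(fr, fr[1:])):
        raise InvalidParameterError("fractions must be strictly increasing")
    alphas = np.asarray(nominal_alphas, dtype=float)
    if alphas.shape != (len(fr),):
        raise InvalidParameterError("nominal_alphas must match fractions in length")
    if np.any((alphas < 0) | (alphas >= 1)):
        raise InvalidParameterError("nominal alphas must lie in [0, 1)")
    with np.errstate(divide="ignore"):
        crit = stats.norm.ppf(1.0 - alphas / 2.0)
    corr = _look_correlation(fr)
    if len(fr) > _MAX_EXACT_LOOKS:
        warnings.warn(
            f"more than {_MAX_EXACT_LOOKS} looks: falling back to Monte-Carlo "
            "integration",
            stacklevel=2,
        )
        return 1.0 - _no_cross_probability_mc(crit, corr)
    return 1.0 - _no_cross_probability(crit, corr)


BoundaryMethod = Literal["ldof_spending", "classic_of"]


def two_look_nominal_alphas(
    t1: float,
    alpha_total: float = 0.05,
    method: BoundaryMethod = "ldof_spending",
) -> tuple[float, float]:
    """Nominal two-sided levels for an interim-at-``t1``-plus-final design.

    The pair ``(alpha_1, alpha_2)`` satisfies
    ``crossing_probability((alpha_1, alpha_2), (t1, 1)) == alpha_total``
    under the bivariate-normal joint model with correlation ``sqrt(t1)``.

    Parameters
    ----------
    t1 : float
        Interim information fraction, strictly inside (0, 1).
    alpha_total : float
        Overall two-sided level to preserve.
    method : {"ldof_spending", "classic_of"}
        Boundary family (see module docstring).
    """
    if not 0 < t1 < 1:
        raise InvalidParameterError(f"t1 must be in (0, 1), got {t1}")
    if not 0 < alpha_total < 1:
        raise InvalidParameterError(f"alpha_total must be in (0, 1), got {alpha_total}")
    corr = _look_correlation((t1, 1.0))

    if method == "ldof_spending":
        alpha_1 = of_spending_cumulative(t1, alpha_total)
        c1 = stats.norm.ppf(1.0 - alpha_1 / 2.0)

        def gap(c2: float) -> float:
            return (
                1.0 - _no_cross_probability(np.array([c1, c2]), corr)
            ) - alpha_total

        c2 = optimize.brentq(gap, 1e-6, 10.0, xtol=1e-10)
        alpha_2 = float(2.0 * stats.norm.sf(c2))
        return alpha_1, alpha_2

    if method == "classic_of":

        def gap_c(c: float) -> float:
            crit = c / np.sqrt(np.array([t1, 1.0]))
            return (1.0 - _no_cross_probability(crit, corr)) - alpha_total

        c = optimize.brentq(gap_c, 1e-6, 10.0, xtol=1e-10)
        a1 = float(2.0 * stats.norm.sf(c / np.sqrt(t1)))
        a2 = float(2.0 * stats.norm.sf(c))
        return a1, a2

    raise InvalidParameterError(f"unknown boundary method: {method!r}")
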