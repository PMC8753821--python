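"""Sequential allele-group budget planning.

Turns a participant budget and a list of candidate allele groups into the full
adaptive schedule: per-stage final sample sizes, futility effect-size cutoffs,
interim efficacy levels, and the interim effect required to stop early for
efficacy.

Budget rule
-----------
The study recruits allele groups sequentially against a single shared control
arm, keeping the arms equally sized at the end. Each test group stopped at its
interim has consumed ``interim_n`` participants, so the stage-``k`` final
per-group size is::

    final_n(k) = floor((total_n - interim_n * (k - 1)) / 2)

With the defaults (budget 100, interim 15) this gives 50 / 42 / 35 for the
three stages, and minimum detectable effects of 0.57 / 0.62 / 0.68 at 80%
power — the futility cutoffs: an observed interim effect below the stage
cutoff means the stage cannot reach the target power by its planned end.

Efficacy levels
---------------
The default schedule ships the deployed study's interim efficacy alphas
(0.0013, 0.0023, 0.0055) as design constants (``alpha_source =
"design_constant"``). Passing ``efficacy_alphas=None`` with
``compute_alphas=True`` instead derives each stage's interim level from
:func:`rbgdesign.boundaries.two_look_nominal_alphas` at that stage's
information fraction (``alpha_source = "computed"``); the two routes do not
coincide (the O'Brien-Fleming spend at t = 0.3 is an order of magnitude
smaller than 0.0013), so provenance is always recorded on the plan.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

from . import boundaries
from .errors import InfeasibleDesignError, InvalidParameterError
from .power import minimum_detectable_d

__all__ = [
    "DesignParams",
    "StagePlan",
    "DEFAULT_EFFICACY_ALPHAS",
    "final_n_per_group",
    "plan_design",
]

#: Interim efficacy levels of the default three-stage schedule (two-sided),
#: fixed design constants of the deployed study.
DEFAULT_EFFICACY_ALPHAS: tuple[float, ...] = (0.0013, 0.0023, 0.0055)


@dataclass(frozen=True)
class DesignParams:
    """Global constants of the adaptive recall-by-genotype design.

    Parameters
    ----------
    total_n : int
        Total participant budget across all arms (default 100).
    interim_n : int
        Per-group size at which each interim analysis is performed
        (default 15).
    sd : float
        Endpoint standard deviation in degrees C (default 2.5, the reference
        heat-pain-threshold spread).
    alpha_final : float
        Two-sided level of the final test (default 0.05).
    power_target : float
        Power used for futility prediction and cutoff calculation
        (default 0.80).
    n_groups : int
        Number of sequential allele test groups (default 3).
    efficacy_alphas : tuple of float, optional
        Per-stage interim efficacy levels. Defaults to the shipped design
        constants when ``n_groups == 3``; otherwise must be supplied or
        computed.
    strict_spending : bool
        If True, the final test level is reduced by the alpha spent at the
        stage's interim rather than kept at ``alpha_final``.
    boundary_method : str
        Boundary family used when efficacy alphas are computed rather than
        supplied.
    """

    total_n: int = 100
    interim_n: int = 15
    sd: float = 2.5
    alpha_final: float = 0.05
    power_target: float = 0.80
    n_groups: int = 3
    efficacy_alphas: Optional[tuple[float, ...]] = None
    strict_spending: bool = False
    boundary_method: boundaries.BoundaryMethod = "ldof_spending"

    def __post_init__(self) -> None:
        if self.interim_n < 2:
            raise InvalidParameterError("interim_n must be >= 2")
        if self.total_n < 2 * self.interim_n:
            raise InfeasibleDesignError(
                f"budget {self.total_n} cannot seat two groups of "
                f"{self.interim_n} at the first interim"
            )
        if not self.sd > 0:
            raise InvalidParameterError("sd must be positive")
        if not 0 < self.alpha_final < 1:
            raise InvalidParameterError("alpha_final must be in (0, 1)")
        if not 0 < self.power_target < 1:
            raise InvalidParameterError("power_target must be in (0, 1)")
        if self.n_groups < 1:
            raise InvalidParameterError("n_groups must be >= 1")
        if self.efficacy_alphas is not None:
            if len(self.efficacy_alphas) != self.n_groups:
                raise InvalidParameterError(
                    "efficacy_alphas must have one entry per group"
                )
            if any(not 0 < a < 1 for a in self.efficacy_alphas):
                raise InvalidParameterError("efficacy alphas must be in (0, 1)")


@dataclass(frozen=True)
class StagePlan:
    """Derived design quantities for one allele-group stage.

    ``futility_d`` is the minimum detectable effect at this stage's final
    size: observing less at interim predicts under-target power.
    ``required_interim_d`` is the effect at which the interim test itself
    reaches the power target at the stage's efficacy level.
    """

    stage: int
    final_n_per_group: int
    info_fraction: float
    futility_d: float
    efficacy_alpha: float
    alpha_source: Literal["design_constant", "supplied", "computed"]
    required_interim_d: float
    required_interim_delta: float
    final_alpha: float = 0.05

    def __post_init__(self) -> None:
        # equality only in the degenerate interim-equals-final design
        if self.futility_d > self.required_interim_d + 1e-9:
            raise InvalidParameterError(
                "futility cutoff must not exceed the required interim effect"
            )


def final_n_per_group(params: DesignParams, stage: int) -> int:
    """Final per-group size for stage ``stage`` (1-based) under the budget rule."""
    if not 1 <= stage <= params.n_groups:
        raise InvalidParameterError(
            f"stage must be in 1..{params.n_groups}, got {stage}"
        )
    remainder = params.total_n - params.interim_n * (stage - 1)
    if remainder < 2 * params.interim_n:
        raise InfeasibleDesignError(
            f"stage {stage}: remaining budget {remainder} cannot seat two "
            f"groups of {params.interim_n}"
        )
    return math.floor(remainder / 2)


def plan_design(params: DesignParams | None = None) -> list[StagePlan]:
    """Compute the full adaptive schedule, one :class:`StagePlan` per group.

    Raises
    ------
    InfeasibleDesignError
        Naming the first stage whose residual budget cannot seat both groups
        at the interim size.
    """
    if params is None:
        params = DesignParams()

    if params.efficacy_alphas is not None:
        alphas: Sequence[float] = params.efficacy_alphas
        source = "supplied"
    elif params.n_groups == len(DEFAULT_EFFICACY_ALPHAS) and (
        params.total_n,
        params.interim_n,
    ) == (100, 15):
        alphas = DEFAULT_EFFICACY_ALPHAS
        source = "design_constant"
    else:
        alphas = []
        source = "computed"

    plans: list[StagePlan] = []
    for k in range(1, params.n_groups + 1):
        try:
            n_final = final_n_per_group(params, k)
        except InfeasibleDesignError as exc:
            raise InfeasibleDesignError(
                f"planning failed at stage {k}: {exc}"
            ) from exc
        t_k = params.interim_n / n_final
        if source == "computed":
            if t_k >= 1.0:
                a_k = params.alpha_final
            else:
                a_k, _ = boundaries.two_look_nominal_alphas(
                    t_k, params.alpha_final, params.boundary_method
                )
        else:
            a_k = alphas[k - 1]
        futility = minimum_detectable_d(
            n_final, params.power_target, params.alpha_final
        )
        req_d = minimum_detectable_d(params.interim_n, params.power_target, a_k)
        if params.strict_spending:
            spent = boundaries.of_spending_cumulative(
                min(t_k, 1.0), params.alpha_final
            )
            final_alpha = max(params.alpha_final - spent, 1e-12)
        else:
            final_alpha = params.alpha_final
        plans.append(
            StagePlan(
                stage=k,
                final_n_per_group=n_final,
                info_fraction=t_k,
                futility_d=futility,
                efficacy_alpha=a_k,
                alpha_source=source,
                required_interim_d=req_d,
                required_interim_delta=req_d * params.sd,
                final_alpha=final_alpha,
            )
        )
    return plans
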