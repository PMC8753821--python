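"""Interim and final analysis of a recall-by-genotype stage.

The pre-specified decision algorithm at each interim:

1. Estimate the standardized effect (Cohen's d, test minus control, pooled
   SD) from the interim data.
2. Predict the power of the *final* analysis at the stage's final per-group
   size and final alpha, treating the observed effect as the true one.
3. If predicted power is below the target, stop the group for futility.
4. Otherwise perform the interim hypothesis test at the stage's efficacy
   alpha: rejection stops the group for efficacy (the effect is established
   early); failure to reject continues recruitment to the planned end.

Because power is monotone in the effect size, step 3 is equivalent to
comparing ``|observed d|`` against the stage futility cutoff; both routes are
implemented and asserted equivalent in the test suite.

The decision input is deliberately genotype-free — group label plus endpoint
value only — mirroring the analyst blinding of the deployed study.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, InvalidParameterError, UndefinedEffectError
from .planner import DesignParams, StagePlan
from .power import power_t2

__all__ = [
    "GroupSample",
    "InterimResult",
    "cohens_d",
    "interim_decide",
    "interim_decide_summary",
    "final_analyze",
    "load_group_samples",
]

Decision = Literal["continue", "stop_futility", "stop_efficacy"]


@dataclass(frozen=True)
class GroupSample:
    """Endpoint measurements (degrees C) for one arm."""

    label: Literal["control", "test"]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=float).ravel()
        )
        if self.values.size < 2:
            raise InvalidParameterError(
                f"group {self.label!r} needs >= 2 values, got {self.values.size}"
            )
        if not np.all(np.isfinite(self.values)):
            raise InvalidParameterError(f"group {self.label!r} has non-finite values")

    @property
    def n(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class InterimResult:
    """Outcome of one interim analysis."""

    observed_d: float
    pooled_sd: float
    predicted_power: float
    p_value: float
    decision: Decision
    stage: int


ArrayLike = Union[GroupSample, Sequence[float], np.ndarray]


def _as_values(sample: ArrayLike, label: str) -> np.ndarray:
    if isinstance(sample, GroupSample):
        return sample.values
    return GroupSample(label=label, values=np.asarray(sample)).values  # type: ignore[arg-type]


def cohens_d(test: ArrayLike, control: ArrayLike) -> tuple[float, float]:
    """Cohen's d (test minus control) with Bessel-corrected pooled SD.

    No small-sample (Hedges) correction is applied; the observed effect feeds
    the power prediction as-is.

    Raises
    ------
    UndefinedEffectError
        If the pooled standard deviation is zero.
    """
    x = _as_values(test, "test")
    y = _as_values(control, "control")
    var_x = x.var(ddof=1)
    var_y = y.var(ddof=1)
    pooled = np.sqrt(
        ((x.size - 1) * var_x + (y.size - 1) * var_y) / (x.size + y.size - 2)
    )
    if pooled == 0:
        raise UndefinedEffectError("zero pooled SD: standardized effect undefined")
    return float((x.mean() - y.mean()) / pooled), float(pooled)


def interim_decide(
    test: ArrayLike,
    control: ArrayLike,
    stage_plan: StagePlan,
    params: DesignParams | None = None,
    *,
    equal_var: bool = True,
) -> InterimResult:
    """Apply the pre-specified interim decision rule to one stage's data.

    ``predicted_power`` is the exact power of the final test at the stage's
    final per-group size and final alpha, evaluated at the observed
    ``|d|``. Ties at exactly the power target continue (the rule stops for
    futility only on strictly *under*-target predictions).

    ``equal_var=False`` switches the interim p-value to the Welch test; the
    power prediction always uses the pooled planning model.
    """
    if params is None:
        params = DesignParams()
    x = _as_values(test, "test")
    y = _as_values(control, "control")
    if x.size < params.interim_n or y.size < params.interim_n:
        raise ConfigError(
            f"interim requires >= {params.interim_n} per group; "
            f"got test n = {x.size}, control n = {y.size}"
        )
    d_obs, pooled = cohens_d(x, y)
    predicted = power_t2(
        abs(d_obs), stage_plan.final_n_per_group, stage_plan.final_alpha
    )
    p_value = float(stats.ttest_ind(x, y, equal_var=equal_var).pvalue)
    if predicted < params.power_target:
        decision: Decision = "stop_futility"
    elif p_value <= stage_plan.efficacy_alpha:
        decision = "stop_efficacy"
    else:
        decision = "continue"
    return InterimResult(
        observed_d=d_obs,
        pooled_sd=pooled,
        predicted_power=float(predicted),
        p_value=p_value,
        decision=decision,
        stage=stage_plan.stage,
    )


def interim_decide_summary(
    mean_test: float,
    sd_test: float,
    n_test: int,
    mean_control: float,
    sd_control: float,
    n_control: int,
    stage_plan: StagePlan,
    params: DesignParams | None = None,
) -> InterimResult:
    """Summary-statistic entry point for the interim rule.

    Accepts per-group means, SDs (Bessel-corrected) and sizes instead of raw
    measurements; otherwise identical to :func:`interim_decide`.
    """
    if params is None:
        params = DesignParams()
    if min(n_test, n_control) < 2:
        raise InvalidParameterError("each group needs n >= 2")
    pooled = np.sqrt(
        ((n_test - 1) * sd_test**2 + (n_control - 1) * sd_control**2)
        / (n_test + n_control - 2)
    )
    if pooled == 0:
        raise UndefinedEffectError("zero pooled SD: standardized effect undefined")
    d_obs = (mean_test - mean_control) / pooled
    se = pooled * np.sqrt(1.0 / n_test + 1.0 / n_control)
    t_stat = (mean_test - mean_control) / se
    df = n_test + n_control - 2
    p_value = float(2.0 * stats.t.sf(abs(t_stat), df))
    predicted = power_t2(
        abs(d_obs), stage_plan.final_n_per_group, stage_plan.final_alpha
    )
    if predicted < params.power_target:
        decision: Decision = "stop_futility"
    elif p_value <= stage_plan.efficacy_alpha:
        decision = "stop_efficacy"
    else:
        decision = "continue"
    return InterimResult(
        observed_d=float(d_obs),
        pooled_sd=float(pooled),
        predicted_power=float(predicted),
        p_value=p_value,
        decision=decision,
        stage=stage_plan.stage,
    )


def final_analyze(
    test: ArrayLike,
    control: ArrayLike,
    params: DesignParams | None = None,
    *,
    final_alpha: float | None = None,
    equal_var: bool = True,
) -> tuple[float, bool]:
    """Two-sided t-test at the end of a stage.

    Returns ``(p_value, significant)`` with significance at ``final_alpha``
    (default: ``params.alpha_final``; a strict-spending schedule passes the
    stage's reduced level here).
    """
    if params is None:
        params = DesignParams()
    alpha = params.alpha_final if final_alpha is None else final_alpha
    if not 0 < alpha <= 1:
        raise InvalidParameterError("final alpha must be in (0, 1]")
    x = _as_values(test, "test")
    y = _as_values(control, "control")
    p = float(stats.ttest_ind(x, y, equal_var=equal_var).pvalue)
    return p, p <= alpha


def load_group_samples(
    path: str | Path,
    *,
    group_col: str = "group",
    value_col: str = "endpoint",
) -> tuple[GroupSample, GroupSample]:
    """Read a participant-level CSV into (test, control) samples.

    Expected columns: a participant identifier (ignored), ``group`` with
    values 'test'/'control', and ``endpoint`` (degrees C). The file carries
    no genotype information by design.
    """
    df = pd.read_csv(path)
    for col in (group_col, value_col):
        if col not in df.columns:
            raise ConfigError(f"column {col!r} missing from {path}")
    labels = set(df[group_col].unique())
    if not labels <= {"test", "control"}:
        raise ConfigError(
            f"unexpected group labels {sorted(labels - {'test', 'control'})}"
        )
    test = GroupSample("test", df.loc[df[group_col] == "test", value_col].to_numpy())
    control = GroupSample(
        "control", df.loc[df[group_col] == "control", value_col].to_numpy()
    )
    return test, control
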