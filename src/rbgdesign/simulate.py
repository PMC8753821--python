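"""Monte-Carlo operating characteristics of the adaptive design.

Three entry points:

:func:`simulate_fixed_effect`
    Draws complete two-arm trials at fixed true effect sizes, applies the real
    interim rule (futility prediction plus efficacy test) to the first
    ``interim_n`` participants per arm, then the final test to the full data,
    and classifies each interim decision against the completed trial's
    outcome. A premature halt of a trial that would have ended significant is
    a false-negative halt; passing a trial that ends non-significant is a
    false-positive continuation.

:func:`interim_timing_sweep`
    The design question "when should the interim happen?": correct-decision
    percentage versus interim size, with bootstrap confidence intervals, and
    the marginal gain per added interim participant. By default the emulated
    interim decision is a significance check on the interim subset (the
    simplest emulation, and the one whose correctness reaches 100% when the
    interim includes everyone); the actual futility and full rules are also
    available.

:func:`simulate_adaptive_study`
    The whole sequential multi-group study with budget bookkeeping: each
    stopped group frees budget for the next, the shared control arm persists
    across stages, and a stage that passes its interim runs to its planned
    final analysis, ending the study.

All randomness flows from a single root ``SeedSequence``; each grid cell and
each purpose (data, bootstrap) gets its own spawned stream, so results are
bit-reproducible under a fixed seed regardless of evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidParameterError
from .planner import DesignParams, StagePlan
from .power import power_t2_vec

__all__ = [
    "SimulationSpec",
    "SimulationSummary",
    "simulate_fixed_effect",
    "interim_timing_sweep",
    "simulate_adaptive_study",
]

_METRICS = (
    "halt",
    "continue",
    "stop_efficacy",
    "false_negative_halt",
    "false_positive_continue",
    "correct_decision",
)


@dataclass(frozen=True)
class SimulationSpec:
    """Configuration of a fixed-effect operating-characteristics run.

    ``true_d`` values are standardized effects; draws are
    ``N(mu, sd)`` for control and ``N(mu + d * sd, sd)`` for test, so the
    default ``mu = 0, sd = 1`` simulates directly on the d scale and any
    other scale gives identical decisions.
    """

    true_d: tuple[float, ...] = (0.0, 0.6)
    n_final_per_group: int = 50
    interim_n_grid: tuple[int, ...] = (15,)
    reps: int = 10_000
    seed: int = 0
    boot_resample: int = 100
    boot_reps: int = 1000
    efficacy_testing: bool = True
    mu: float = 0.0
    sd: float = 1.0

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise InvalidParameterError("reps must be >= 1")
        if any(
            not 2 <= m <= self.n_final_per_group for m in self.interim_n_grid
        ):
            raise InvalidParameterError(
                "every interim_n must be in [2, n_final_per_group]"
            )
        if not self.sd > 0:
            raise InvalidParameterError("sd must be positive")


@dataclass(frozen=True)
class SimulationSummary:
    """Per-(interim_n, true_d) decision rates with bootstrap 95% CIs."""

    table: pd.DataFrame
    spec: SimulationSpec


def _pooled_d_and_p(
    x: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Cohen's d and two-sided pooled-t p-value for equal-n arms."""
    n = x.shape[1]
    mx, my = x.mean(axis=1), y.mean(axis=1)
    vx, vy = x.var(axis=1, ddof=1), y.var(axis=1, ddof=1)
    pooled = np.sqrt((vx + vy) / 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        d_hat = (mx - my) / pooled
    t_stat = d_hat * np.sqrt(n / 2.0)
    p = 2.0 * stats.t.sf(np.abs(t_stat), 2 * n - 2)
    return d_hat, p


def _bootstrap_ci(
    indicator: np.ndarray, rng: np.random.Generator, resample: int, reps: int
) -> tuple[float, float]:
    """Percentile 95% CI of a rate, resampling `resample` results `reps` times."""
    idx = rng.integers(0, indicator.size, size=(reps, resample))
    rates = indicator[idx].mean(axis=1)
    lo, hi = np.percentile(rates, [2.5, 97.5])
    return float(lo), float(hi)


def _decide_cell(
    x: np.ndarray,
    y: np.ndarray,
    interim_n: int,
    stage_plan: StagePlan,
    params: DesignParams,
    efficacy_testing: bool,
) -> dict[str, np.ndarray]:
    """Vectorized interim rule + final analysis over replicate trials."""
    d_hat, p_int = _pooled_d_and_p(x[:, :interim_n], y[:, :interim_n])
    predicted = power_t2_vec(
        np.abs(d_hat), stage_plan.final_n_per_group, stage_plan.final_alpha
    )
    halt = predicted < params.power_target
    if efficacy_testing:
        efficacy = ~halt & (p_int <= stage_plan.efficacy_alpha)
    else:
        efficacy = np.zeros_like(halt)
    cont = ~halt & ~efficacy
    _, p_fin = _pooled_d_and_p(x, y)
    sig = p_fin <= stage_plan.final_alpha
    return {
        "halt": halt,
        "continue": cont,
        "stop_efficacy": efficacy,
        "false_negative_halt": halt & sig,
        "false_positive_continue": ~halt & ~sig,
        "correct_decision": (halt & ~sig) | (~halt & sig),
        "final_significant": sig,
        "p_interim": p_int,
    }


def simulate_fixed_effect(
    spec: SimulationSpec,
    stage_plan: StagePlan,
    params: DesignParams | None = None,
) -> SimulationSummary:
    """Operating characteristics of the interim rule at fixed true effects.

    For each ``(interim_n, true_d)`` cell, ``spec.reps`` complete trials of
    ``spec.n_final_per_group`` per arm are drawn; the interim rule sees the
    first ``interim_n`` per arm and is scored against the completed trial's
    final test. Rates carry bootstrap 95% CIs.
    """
    if params is None:
        params = DesignParams()
    root = np.random.SeedSequence(spec.seed)
    rows = []
    for cell, (interim_n, true_d) in enumerate(
        (m, d) for m in spec.interim_n_grid for d in spec.true_d
    ):
        data_ss, boot_ss = np.random.SeedSequence(
            entropy=root.entropy, spawn_key=(cell,)
        ).spawn(2)
        rng = np.random.default_rng(data_ss)
        shape = (spec.reps, spec.n_final_per_group)
        x = rng.normal(spec.mu + true_d * spec.sd, spec.sd, size=shape)
        y = rng.normal(spec.mu, spec.sd, size=shape)
        out = _decide_cell(
            x, y, interim_n, stage_plan, params, spec.efficacy_testing
        )
        boot_rng = np.random.default_rng(boot_ss)
        row: dict[str, float] = {"interim_n": interim_n, "true_d": true_d}
        for metric in _METRICS:
            ind = out[metric].astype(float)
            row[metric] = float(ind.mean())
            lo, hi = _bootstrap_ci(
                ind, boot_rng, spec.boot_resample, spec.boot_reps
            )
            row[f"{metric}_lo"], row[f"{metric}_hi"] = lo, hi
        rows.append(row)
    return SimulationSummary(table=pd.DataFrame(rows), spec=spec)


SweepRule = Literal["significance", "futility", "full"]


def interim_timing_sweep(
    spec: SimulationSpec,
    stage_plan: StagePlan,
    params: DesignParams | None = None,
    rule: SweepRule = "significance",
) -> pd.DataFrame:
    """Correct-decision percentage and marginal gain versus interim size.

    ``rule`` selects the emulated interim decision:

    - ``"significance"`` — pass iff the interim t-test rejects at the final
      level; correct iff the decision matches the completed trial's outcome.
    - ``"futility"`` — pass iff predicted final power reaches the target
      (no efficacy stopping); halting is correct iff the completed trial is
      non-significant.
    - ``"full"`` — the deployed futility-plus-efficacy rule, scored as in
      :func:`simulate_fixed_effect`.

    Returns a long DataFrame with columns interim_n, true_d, correct_pct,
    ci_lo, ci_hi and marginal_gain_pct_per_subject (gain over the previous
    grid point per added participant).
    """
    if params is None:
        params = DesignParams()
    if not spec.interim_n_grid:
        raise InvalidParameterError("interim_n_grid must be nonempty")
    root = np.random.SeedSequence(spec.seed)
    rows = []
    for cell, (interim_n, true_d) in enumerate(
        (m, d) for m in spec.interim_n_grid for d in spec.true_d
    ):
        data_ss, boot_ss = np.random.SeedSequence(
            entropy=root.entropy, spawn_key=(cell,)
        ).spawn(2)
        rng = np.random.default_rng(data_ss)
        shape = (spec.reps, spec.n_final_per_group)
        x = rng.normal(spec.mu + true_d * spec.sd, spec.sd, size=shape)
        y = rng.normal(spec.mu, spec.sd, size=shape)
        out = _decide_cell(
            x, y, interim_n, stage_plan, params, spec.efficacy_testing
        )
        if rule == "significance":
            passes = out["p_interim"] <= stage_plan.final_alpha
            correct = passes == out["final_significant"]
        elif rule == "futility":
            passes = ~out["halt"]
            correct = passes == out["final_significant"]
        elif rule == "full":
            correct = out["correct_decision"]
        else:
            raise InvalidParameterError(f"unknown sweep rule: {rule!r}")
        ind = correct.astype(float)
        boot_rng = np.random.default_rng(boot_ss)
        lo, hi = _bootstrap_ci(ind, boot_rng, spec.boot_resample, spec.boot_reps)
        rows.append(
            {
                "interim_n": interim_n,
                "true_d": true_d,
                "correct_pct": 100.0 * float(ind.mean()),
                "ci_lo": 100.0 * lo,
                "ci_hi": 100.0 * hi,
            }
        )
    df = (
        pd.DataFrame(rows)
        .sort_values(["true_d", "interim_n"])
        .reset_index(drop=True)
    )
    df["marginal_gain_pct_per_subject"] = df.groupby("true_d")[
        "correct_pct"
    ].diff() / df.groupby("true_d")["interim_n"].diff()
    return df


@dataclass(frozen=True)
class AdaptiveStudyResult:
    """Pathway frequencies of the full sequential study."""

    pathways: pd.DataFrame
    group_decisions: pd.DataFrame
    max_consumed: int
    reps: int


def simulate_adaptive_study(
    design: Sequence[StagePlan],
    true_ds: Sequence[float],
    reps: int = 10_000,
    seed: int = 0,
    params: DesignParams | None = None,
) -> AdaptiveStudyResult:
    """Simulate the sequential multi-group study end to end.

    Groups are tested in order against the single shared control arm. A
    stopped group (futility or interim efficacy) hands recruitment to the
    next group; a group that passes its interim recruits to its stage's final
    size, is analysed, and ends the study. Budget is conserved by
    construction: a completed stage k consumes
    ``interim_n * (k - 1) + 2 * final_n(k) <= total_n`` participants, and a
    study in which every group stops consumes
    ``interim_n * (n_groups + 1)``.
    """
    if params is None:
        params = DesignParams()
    if len(true_ds) != len(design):
        raise InvalidParameterError("true_ds must supply one effect per stage")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n_max = design[0].final_n_per_group
    m = params.interim_n
    control = rng.normal(0.0, 1.0, size=(reps, n_max))
    tests = [
        rng.normal(true_ds[k], 1.0, size=(reps, plan.final_n_per_group))
        for k, plan in enumerate(design)
    ]

    active = np.ones(reps, dtype=bool)
    decisions = np.full((reps, len(design)), "", dtype=object)
    final_sig = np.zeros(reps, dtype=bool)
    completed_stage = np.zeros(reps, dtype=int)  # 0 = no stage ran to its end
    consumed = np.full(reps, 0, dtype=int)

    for k, plan in enumerate(design):
        if not active.any():
            break
        x, y = tests[k][active], control[active]
        d_hat, p_int = _pooled_d_and_p(x[:, :m], y[:, :m])
        predicted = power_t2_vec(
            np.abs(d_hat), plan.final_n_per_group, plan.final_alpha
        )
        halt = predicted < params.power_target
        efficacy = ~halt & (p_int <= plan.efficacy_alpha)
        cont = ~halt & ~efficacy
        idx = np.flatnonzero(active)
        decisions[idx[halt], k] = "stop_futility"
        decisions[idx[efficacy], k] = "stop_efficacy"
        decisions[idx[cont], k] = "continue"
        if cont.any():
            rows = idx[cont]
            nf = plan.final_n_per_group
            _, p_fin = _pooled_d_and_p(
                tests[k][rows, :nf], control[rows, :nf]
            )
            final_sig[rows] = p_fin <= plan.final_alpha
            completed_stage[rows] = k + 1
            consumed[rows] = m * k + 2 * nf
            active[rows] = False

    consumed[active] = m * (len(design) + 1)
    assert consumed.max() <= params.total_n

    def _pathway(i: int) -> str:
        parts = []
        for k in range(len(design)):
            dec = decisions[i, k]
            if dec == "":
                break
            if dec == "continue":
                parts.append(
                    "continue(final significant)"
                    if final_sig[i]
                    else "continue(final non-significant)"
                )
                break
            parts.append(dec)
        return " > ".join(parts)

    paths = pd.Series([_pathway(i) for i in range(reps)], name="pathway")
    pathways = (
        paths.value_counts(normalize=True)
        .rename("frequency")
        .rename_axis("pathway")
        .reset_index()
    )
    group_rows = []
    for k in range(len(design)):
        col = decisions[:, k]
        reached = col != ""
        group_rows.append(
            {
                "stage": k + 1,
                "reached": float(reached.mean()),
                "stop_futility": float((col == "stop_futility").mean()),
                "stop_efficacy": float((col == "stop_efficacy").mean()),
                "continue": float((col == "continue").mean()),
            }
        )
    return AdaptiveStudyResult(
        pathways=pathways,
        group_decisions=pd.DataFrame(group_rows),
        max_consumed=int(consumed.max()),
        reps=reps,
    )
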