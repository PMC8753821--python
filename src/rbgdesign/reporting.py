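"""Result serialization: schedule tables, manifests, decision logs.

JSON artifacts carry full numeric precision; display rounding (effect sizes
to 2 decimal places, degrees C to 1) happens only in the human-readable
report tables.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd

from . import __version__
from .decision import InterimResult
from .planner import DesignParams, StagePlan

__all__ = [
    "RunManifest",
    "schedule_frame",
    "schedule_report_table",
    "schedule_to_json",
    "decision_to_json",
]


@dataclasses.dataclass
class RunManifest:
    """Provenance record attached to every pipeline artifact."""

    command: str
    seed: int | None
    config: dict[str, Any]
    stage_provenance: list[dict[str, Any]] = dataclasses.field(
        default_factory=list
    )
    version: str = __version__
    python: str = platform.python_version()
    created: str = dataclasses.field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def schedule_frame(plans: Sequence[StagePlan]) -> pd.DataFrame:
    """Full-precision schedule as a DataFrame (one row per stage)."""
    return pd.DataFrame([dataclasses.asdict(p) for p in plans])


def _fmt_effect(d: float, delta: float) -> str:
    return f"{d:.2f} (Δ{delta:.1f} °C)"


def schedule_report_table(plans: Sequence[StagePlan]) -> pd.DataFrame:
    """Display table mirroring the interim-schedule layout.

    Columns: interim analysis number, futility effect size (2 dp), efficacy
    cut-off alpha, and the effect size required for statistical efficacy with
    its degrees-C equivalent (1 dp).
    """
    return pd.DataFrame(
        {
            "interim_analysis": [p.stage for p in plans],
            "futility_effect_size": [round(p.futility_d, 2) for p in plans],
            "efficacy_cutoff_alpha": [p.efficacy_alpha for p in plans],
            "required_interim_effect": [
                _fmt_effect(p.required_interim_d, p.required_interim_delta)
                for p in plans
            ],
        }
    )


def schedule_to_json(
    plans: Sequence[StagePlan],
    params: DesignParams,
    manifest: RunManifest | None = None,
) -> str:
    payload: dict[str, Any] = {
        "design_params": dataclasses.asdict(params),
        "stages": [dataclasses.asdict(p) for p in plans],
    }
    if manifest is not None:
        payload["manifest"] = dataclasses.asdict(manifest)
    return json.dumps(payload, indent=2)


def decision_to_json(result: InterimResult) -> str:
    return json.dumps(dataclasses.asdict(result), indent=2)
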