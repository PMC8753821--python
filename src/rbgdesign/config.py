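"""Configuration loading and validation (YAML or JSON, same schema).

Design keys (all optional, defaults are the deployed study's):
``total_n``, ``interim_n``, ``sd``, ``alpha_final``, ``power_target``,
``n_groups``, ``efficacy_alphas`` (list), ``strict_spending``,
``boundary_method``.

Cohort keys: ``pool_size``, ``group_sizes`` (mapping), ``effects`` (mapping
of recall group to degrees-C shift), ``exclusion_prevalences`` (mapping),
``groups`` (list of {name, snps: [{rsid, maf}], r2}) to override the default
five-SNP panel.

Simulation keys: ``true_d`` (list), ``n_final_per_group``,
``interim_n_grid`` (list), ``reps``, ``boot_resample``, ``boot_reps``,
``efficacy_testing``, ``rule``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping, Optional

import yaml

from .cohort import LDPair, SNPSpec, TRPA1_LD_PAIRS, TRPA1_SNPS
from .errors import ConfigError
from .planner import DesignParams
from .simulate import SimulationSpec

__all__ = ["load_config", "design_params_from_config", "simulation_spec_from_config", "snp_panel_from_config"]

_DESIGN_KEYS = {
    "total_n",
    "interim_n",
    "sd",
    "alpha_final",
    "power_target",
    "n_groups",
    "efficacy_alphas",
    "strict_spending",
    "boundary_method",
}

_SIM_KEYS = {
    "true_d",
    "n_final_per_group",
    "interim_n_grid",
    "reps",
    "boot_resample",
    "boot_reps",
    "efficacy_testing",
    "mu",
    "sd",
}


def load_config(path: str | Path | None) -> dict[str, Any]:
    """Read a YAML or JSON config file; ``None`` yields an empty config."""
    if path is None:
        return {}
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    try:
        if path.suffix == ".json":
            cfg = json.loads(text)
        else:
            cfg = yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return cfg


def design_params_from_config(cfg: Mapping[str, Any]) -> DesignParams:
    kwargs = {k: cfg[k] for k in _DESIGN_KEYS if k in cfg}
    if "efficacy_alphas" in kwargs and kwargs["efficacy_alphas"] is not None:
        kwargs["efficacy_alphas"] = tuple(kwargs["efficacy_alphas"])
    try:
        return DesignParams(**kwargs)
    except TypeError as exc:
        raise ConfigError(f"invalid design config: {exc}") from exc


def simulation_spec_from_config(
    cfg: Mapping[str, Any], seed: int = 0
) -> SimulationSpec:
    kwargs: dict[str, Any] = {k: cfg[k] for k in _SIM_KEYS if k in cfg}
    for key in ("true_d", "interim_n_grid"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    try:
        return SimulationSpec(seed=seed, **kwargs)
    except TypeError as exc:
        raise ConfigError(f"invalid simulation config: {exc}") from exc


def snp_panel_from_config(
    cfg: Mapping[str, Any],
) -> tuple[tuple[SNPSpec, ...], tuple[LDPair, ...]]:
    """Build an SNP panel from a ``groups`` config section, or the default."""
    groups = cfg.get("groups")
    if not groups:
        return TRPA1_SNPS, TRPA1_LD_PAIRS
    snps: list[SNPSpec] = []
    pairs: list[LDPair] = []
    for i, grp in enumerate(groups, start=1):
        try:
            members = [
                SNPSpec(s["rsid"], float(s["maf"]), i) for s in grp["snps"]
            ]
        except (KeyError, TypeError) as exc:
            raise ConfigError(
                f"group {i}: each SNP needs rsid and maf ({exc})"
            ) from exc
        snps.extend(members)
        if len(members) == 2:
            pairs.append(
                LDPair(
                    members[0].rsid,
                    members[1].rsid,
                    float(grp.get("r2", 0.0)),
                    int(grp.get("sign", 1)),
                )
            )
        elif len(members) > 2:
            raise ConfigError(f"group {i}: at most two linked SNPs per group")
    return tuple(snps), tuple(pairs)
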