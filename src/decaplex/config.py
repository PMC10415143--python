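"""Structured pipeline configuration (YAML) with strict key validation.

All thresholds used by the pipeline stages live here as defaults — the
significance classes with their (FDR, s0) pairs, imputation parameters,
cascade rules, imaging geometry and simulation sizes — so no analysis
constant is hard-coded in a subcommand. Unknown keys are rejected to catch
typos, and every stochastic stage takes an explicit seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .volcano import DEFAULT_CUTOFFS, CutoffSpec

__all__ = [
    "ImputationConfig",
    "CascadeConfig",
    "ImagingConfig",
    "LfqSimConfig",
    "CellSimConfig",
    "PipelineConfig",
    "load_config",
]


@dataclass
class ImputationConfig:
    width: float = 0.3        # SD multiplier for the imputation distribution width
    downshift: float = 1.8    # SD multiplier for the downshift below the column mean


@dataclass
class CascadeConfig:
    min_class: str = "SigB"                       # rule (i): at least this class in all FL baits
    control_classes: tuple[str, ...] = ("SigA", "SigB")  # rule (ii) subtraction classes
    fold_change: float = 2.5                      # inclusive keep-threshold on linear ratio
    min_bait_replicates: int = 2                  # replicate-evidence rule (of the bait group)


@dataclass
class ImagingConfig:
    camera_pitch_um: float = 6.45
    magnification: float = 100.0
    pp_radius_px: float = 12.0
    granule_n_sd: float = 2.0
    granule_min_size: int = 4
    border_width: int = 5
    bait_channel: str = "bait"
    reference_channel: str = "marker"


@dataclass
class LfqSimConfig:
    n_proteins: int = 1500
    n_interactors: int = 20
    effect: float = 4.0
    bystander_frac: float = 0.05
    noise_sd: float = 0.4
    missing_steepness: float = 0.8
    missing_midpoint: float = 22.0
    with_missingness: bool = True


@dataclass
class CellSimConfig:
    n_cells: int = 50
    pp_fraction_bait: float = 2.6
    pp_fraction_reference: float = 2.0
    n_granules: int = 0
    granule_share_bait: float = 0.0
    granule_share_marker: float = 0.0
    background: float = 10.0
    noise_sd: float = 5.0


@dataclass
class PipelineConfig:
    seed: int = 0
    min_values: int = 3           # minimum observed quantifications over all samples
    permutations: int = 250
    cutoffs: tuple[CutoffSpec, ...] = DEFAULT_CUTOFFS
    imputation: ImputationConfig = field(default_factory=ImputationConfig)
    cascade: CascadeConfig = field(default_factory=CascadeConfig)
    imaging: ImagingConfig = field(default_factory=ImagingConfig)
    lfq_sim: LfqSimConfig = field(default_factory=LfqSimConfig)
    cell_sim: CellSimConfig = field(default_factory=CellSimConfig)


def _build(cls, data: Mapping[str, Any], context: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(f"unknown config key(s) under {context!r}: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        ftype = fields[name].type
        if dataclasses.is_dataclass(_resolve(ftype)):
            kwargs[name] = _build(_resolve(ftype), value, f"{context}.{name}")
        elif name == "cutoffs":
            kwargs[name] = tuple(
                CutoffSpec(str(c["name"]), float(c["fdr"]), float(c["s0"]))
                for c in value
            )
        elif isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


_SECTION_TYPES = {
    "ImputationConfig": ImputationConfig,
    "CascadeConfig": CascadeConfig,
    "ImagingConfig": ImagingConfig,
    "LfqSimConfig": LfqSimConfig,
    "CellSimConfig": CellSimConfig,
}


def _resolve(ftype):
    if isinstance(ftype, str):
        return _SECTION_TYPES.get(ftype, str)
    return ftype


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML config; a missing path yields the defaults."""
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    return _build(PipelineConfig, raw, "config")
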