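"""Parameter-file loading and validation.

Model parameters live in small YAML documents whose keys mirror the
dataclass field names; the packaged default file carries the elicited
timings, the observed category mix and the published unit costs. Errors
name the offending field so a malformed file is diagnosable from the
message alone.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, fields
from pathlib import Path

import yaml

from .economics import CostParameters
from .scenarios import InducedDemand
from .timings import ActivityTimings, CategoryMix, NoteUseModel

__all__ = ["ModelParameters", "load_parameters", "load_default_parameters"]


@dataclass(frozen=True)
class ModelParameters:
    timings: ActivityTimings
    notes: NoteUseModel
    mix: CategoryMix
    costs: CostParameters
    induced: InducedDemand


def _build(cls, section: dict, section_name: str):
    valid = {f.name for f in fields(cls)}
    unknown = set(section) - valid
    if unknown:
        raise ValueError(
            f"unknown field(s) in section {section_name!r}: {sorted(unknown)}"
        )
    try:
        return cls(**section)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid section {section_name!r}: {exc}") from exc


def load_parameters(path: "str | Path | None" = None) -> ModelParameters:
    """Load model parameters from a YAML file (packaged defaults if None).

    Any section omitted from a user file falls back to its defaults.
    """
    if path is None:
        text = (
            importlib.resources.files("econsult.data").joinpath("defaults.yaml").read_text()
        )
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text) or {}
    known = {"timings", "notes", "category_mix", "costs", "induced_demand"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown top-level section(s): {sorted(unknown)}")
    mix_raw = raw.get("category_mix")
    try:
        mix = CategoryMix.from_labels(mix_raw) if mix_raw is not None else CategoryMix()
    except ValueError as exc:
        raise ValueError(f"invalid section 'category_mix': {exc}") from exc
    return ModelParameters(
        timings=_build(ActivityTimings, raw.get("timings", {}), "timings"),
        notes=_build(NoteUseModel, raw.get("notes", {}), "notes"),
        mix=mix,
        costs=_build(CostParameters, raw.get("costs", {}), "costs"),
        induced=_build(InducedDemand, raw.get("induced_demand", {}), "induced_demand"),
    )


def load_default_parameters() -> ModelParameters:
    return load_parameters(None)
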