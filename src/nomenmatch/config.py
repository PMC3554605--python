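"""YAML run configuration.

A single document with two optional sections, ``scoring:`` (fields of
:class:`~nomenmatch.scoring.ScoringParams`) and ``run:`` (fields of
:class:`~nomenmatch.resolve.RunSettings`).  Omitted keys keep their
defaults; unknown keys are an error so typos do not pass silently.
"""

from __future__ import annotations

from dataclasses import fields
from typing import Optional

import yaml

from .resolve import RunSettings
from .scoring import ScoringParams

__all__ = ["load_config", "settings_report"]


def _build(cls, data: dict):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


def load_config(path: Optional[str]) -> tuple[ScoringParams, RunSettings]:
    """Load (ScoringParams, RunSettings) from a YAML file (defaults if None)."""
    if path is None:
        return ScoringParams(), RunSettings()
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ValueError("config must be a mapping")
    unknown = set(doc) - {"scoring", "run"}
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    params = _build(ScoringParams, doc.get("scoring") or {})
    settings = _build(RunSettings, doc.get("run") or {})
    return params, settings


def settings_report(params: ScoringParams, settings: RunSettings) -> list[str]:
    """Human-readable settings dump, one "key: value" line each."""
    lines = []
    for section, obj in (("run", settings), ("scoring", params)):
        for f in fields(obj):
            lines.append(f"{section}.{f.name}: {getattr(obj, f.name)}")
    return lines
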