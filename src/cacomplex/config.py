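"""Structured-text (YAML/JSON) configuration for all model components.

One document with optional sections per module; every section is validated
by the corresponding pydantic model, so unknown keys or out-of-range
values fail with a precise message.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict

from .bk import BKRateParams, ComplexConfig
from .cav import CaVParams
from .exocytosis import GranuleParams
from .nanodomain import NanodomainParams, default_nanodomain_params
from .wholecell import WholeCellParams


class FullConfig(BaseModel):
    """Top-level configuration with one section per model component."""

    model_config = ConfigDict(extra="forbid")

    nanodomain: NanodomainParams = default_nanodomain_params()
    cav: CaVParams = CaVParams()
    bk: BKRateParams = BKRateParams()
    complex: ComplexConfig = ComplexConfig()
    granule: GranuleParams = GranuleParams()
    wholecell: WholeCellParams = WholeCellParams()
    seed: int = 0


def load_config(path: str | Path | None = None) -> FullConfig:
    """Load and validate a YAML or JSON config; defaults when path is None."""
    if path is None:
        return FullConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    return FullConfig.model_validate(data)


def dump_config(cfg: FullConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(cfg.model_dump(), indent=2))
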