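"""Pipeline configuration: the protocol constants, validated and serializable.

Defaults are the study protocol: abundance-level thresholds 1% / 0.1%,
alpha 0.05 everywhere, a 1000-network ensemble over random 90% taxon
subsets, 90% sign coherence for a reliable interaction, the +-0.1
topological-niche band, motif significance at z >= 2, and the interaction
strength grid top-500 to top-2000 plus the full network.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, Field, model_validator


class Thresholds(BaseModel):
    level_high: float = Field(1.0, gt=0)  # percent
    level_rare: float = Field(0.1, gt=0)  # percent
    alpha: float = Field(0.05, gt=0, lt=1)
    coherence: float = Field(0.9, gt=0.5, le=1.0)
    niche_band: float = Field(0.1, ge=0, le=1)
    motif_z: float = Field(2.0, ge=0)
    motif_min_count: int = Field(4, ge=0)

    @model_validator(mode="after")
    def _ordered(self) -> "Thresholds":
        if self.level_rare >= self.level_high:
            raise ValueError("level_rare must be below level_high")
        return self


class Ensemble(BaseModel):
    n_networks: int = Field(1000, ge=1)
    member_frac: float = Field(0.9, gt=0, le=1)
    ridge: float = Field(1e-3, ge=0)


class MotifSettings(BaseModel):
    sizes: tuple[int, ...] = (3, 4)
    n_random: int = Field(100, ge=2)

    @model_validator(mode="after")
    def _sizes(self) -> "MotifSettings":
        if not set(self.sizes) <= {3, 4}:
            raise ValueError("motif sizes must be 3 and/or 4")
        return self


class SyntheticSettings(BaseModel):
    """Mirror of :class:`micronet.synthetic.SyntheticConfig` for YAML use."""

    n_taxa: int = Field(113, ge=2)
    n_dates: int = Field(7, ge=4)
    process_noise_sd: float = Field(0.05, ge=0)
    pattern_noise_sd: float = Field(0.05, ge=0)
    diff_effect_sd: float = Field(3.0, ge=0)
    counts: bool = True
    pattern_group_sizes: tuple[int, int, int] = (9, 8, 8)
    n_diff_up: int = Field(20, ge=0)
    n_diff_dn: int = Field(13, ge=0)
    n_c_only: int = Field(5, ge=0)
    n_b_only: int = Field(7, ge=0)

    def to_synthetic_config(self):
        from .synthetic import SyntheticConfig

        return SyntheticConfig(
            n_taxa=self.n_taxa,
            n_dates=self.n_dates,
            process_noise_sd=self.process_noise_sd,
            pattern_noise_sd=self.pattern_noise_sd,
            diff_effect_sd=self.diff_effect_sd,
            counts=self.counts,
            pattern_group_sizes=self.pattern_group_sizes,
            n_diff_up=self.n_diff_up,
            n_diff_dn=self.n_diff_dn,
            n_c_only=self.n_c_only,
            n_b_only=self.n_b_only,
        )


class PipelineConfig(BaseModel):
    thresholds: Thresholds = Thresholds()
    ensemble: Ensemble = Ensemble()
    motifs: MotifSettings = MotifSettings()
    synthetic: SyntheticSettings = SyntheticSettings()
    strength_grid: tuple[int | Literal["all"], ...] = (500, 1000, 1500, 2000, "all")
    seed: int = 0
    fisher_mc: int = Field(100_000, ge=100)

    @model_validator(mode="after")
    def _grid(self) -> "PipelineConfig":
        for s in self.strength_grid:
            if s != "all" and (not isinstance(s, int) or s < 1):
                raise ValueError(f"bad strength level {s!r}")
        return self

    # -- serialization ----------------------------------------------------
    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(json.loads(self.model_dump_json()), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.model_validate(yaml.safe_load(text) or {})

    def hash(self) -> str:
        return hashlib.sha256(self.model_dump_json().encode()).hexdigest()[:12]
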