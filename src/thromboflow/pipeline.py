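"""End-to-end orchestration: simulate -> render -> segment -> quantify -> stats.

A single JSON configuration drives the whole pipeline; it is validated
strictly (unknown keys are rejected) and the seed recorded in every output
manifest, so a rerun with the same configuration reproduces every CSV
byte-identically.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError, \
    field_validator

from .cohort import Condition, generate_cohort, quantify_dataset, \
    segment_dataset
from .kinetics import DEFAULT_TIMEPOINTS
from .presets import PRESETS
from .render import RenderConfig
from .segment import SegmentationConfig
from .stats import assemble_report

log = logging.getLogger("thromboflow")


class ConditionSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    preset: str = "vehicle"
    switch_time: Optional[float] = None

    @field_validator("preset")
    @classmethod
    def _known_preset(cls, v):
        if v not in PRESETS:
            raise ValueError(f"unknown preset {v!r}; choose from {list(PRESETS)}")
        return v

    @field_validator("switch_time")
    @classmethod
    def _valid_switch(cls, v):
        if v is not None and v not in (0, 2):
            raise ValueError("switch_time must be 0, 2 or null")
        return v


class RenderSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    scale: Literal["quarter", "full"] = "quarter"
    noise_sigma: float = Field(4.0, ge=0)
    gradient_amplitude: float = Field(20.0, ge=0)

    def to_config(self, seed: int) -> RenderConfig:
        base = RenderConfig.quarter_scale if self.scale == "quarter" \
            else RenderConfig
        return base(noise_sigma=self.noise_sigma,
                    gradient_amplitude=self.gradient_amplitude, seed=seed)


class SegmentSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    fibrin_high_threshold: float = Field(120.0, ge=0, le=255)
    fft_highpass_cutoff: Optional[float] = Field(None, ge=0)
    qc_overlays: bool = False

    def to_config(self) -> SegmentationConfig:
        cfg = SegmentationConfig(fibrin_high_threshold=self.fibrin_high_threshold)
        if self.fft_highpass_cutoff is not None:
            for ch in ("bf", "dioc6", "af568"):
                cfg = cfg.with_channel(
                    ch, fft_highpass_cutoff=self.fft_highpass_cutoff)
        return cfg


class StatsSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    reference_preset: str = "vehicle"
    reference_switch: str = "none"
    alpha: float = Field(0.05, gt=0, lt=1)
    filtered: bool = True
    scale_scope: Literal["all", "surface"] = "all"


class PipelineConfig(BaseModel):
    """Validated configuration of a full pipeline run."""

    model_config = ConfigDict(extra="forbid")

    seed: int = Field(..., ge=0, lt=2 ** 31)
    n_donors: int = Field(3, ge=2)
    replicates: int = Field(2, ge=2, le=3)
    surfaces: list[Literal["collagen", "collagen_TF"]] = \
        ["collagen", "collagen_TF"]
    conditions: list[ConditionSpec] = [
        ConditionSpec(preset="vehicle"),
        ConditionSpec(preset="tirofiban", switch_time=2),
    ]
    timepoints: list[float] = list(DEFAULT_TIMEPOINTS)
    volumetric_flow_ul_min: float = Field(75.0, gt=0)
    render: RenderSpec = RenderSpec()
    segment: SegmentSpec = SegmentSpec()
    stats: StatsSpec = StatsSpec()
    log_level: str = "INFO"

    @field_validator("timepoints")
    @classmethod
    def _increasing(cls, v):
        if not v or any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("timepoints must be strictly increasing")
        return v

    @field_validator("conditions")
    @classmethod
    def _has_reference(cls, v):
        if not any(c.preset == "vehicle" and c.switch_time is None for c in v):
            v = [ConditionSpec(preset="vehicle")] + list(v)
        return v


def validate_config(path: "str | Path") -> PipelineConfig:
    """Load and schema-check a JSON pipeline configuration."""
    raw = json.loads(Path(path).read_text())
    try:
        return PipelineConfig.model_validate(raw)
    except ValidationError as err:
        locs = "; ".join(
            "/" + "/".join(str(x) for x in e["loc"]) + ": " + e["msg"]
            for e in err.errors())
        raise ValueError(f"invalid pipeline configuration {path}: {locs}") from None


def expand_conditions(cfg: PipelineConfig) -> list[Condition]:
    return [Condition(surface=s, preset=c.preset, switch_time=c.switch_time)
            for s in cfg.surfaces for c in cfg.conditions]


def run_all(cfg: PipelineConfig, out_dir: "str | Path",
            overwrite: bool = False) -> dict:
    """Run the full pipeline; returns a dict of stage output paths."""
    logging.basicConfig(level=cfg.log_level)
    out = Path(out_dir)
    images_dir = out / "images"
    masks_dir = out / "masks"
    stats_dir = out / "stats"

    conditions = expand_conditions(cfg)
    log.info("simulate+render: %d donors x %d replicates x %d conditions "
             "x %d timepoints", cfg.n_donors, cfg.replicates,
             len(conditions), len(cfg.timepoints))
    manifest = generate_cohort(
        images_dir, n_donors=cfg.n_donors, conditions=conditions,
        replicates=cfg.replicates, seed=cfg.seed,
        render_cfg=cfg.render.to_config(cfg.seed),
        timepoints=tuple(cfg.timepoints), overwrite=overwrite)
    log.info("rendered %d image sets", len(manifest))

    seg_manifest = segment_dataset(images_dir, masks_dir,
                                   cfg.segment.to_config(),
                                   qc=cfg.segment.qc_overlays)
    log.info("segmented %d image sets", len(seg_manifest))

    params_csv = out / "params.csv"
    frame = quantify_dataset(images_dir, masks_dir, params_csv)
    log.info("quantified %d parameter records", len(frame))

    report = assemble_report(
        frame, stats_dir,
        reference=(cfg.stats.reference_preset, cfg.stats.reference_switch),
        alpha=cfg.stats.alpha, filtered=cfg.stats.filtered,
        scale_scope=cfg.stats.scale_scope)
    log.info("stats: %d subtraction heatmaps, %d donors",
             len(report.heatmaps), report.scaled.n_donors)

    return {
        "images": images_dir, "masks": masks_dir, "params": params_csv,
        "stats": stats_dir, "report": report, "manifest": manifest,
    }
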