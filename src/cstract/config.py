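"""Run configuration, validation and manifests for the pipeline CLI.

A single structured YAML file configures every stage; one global seed
fans out into per-stage substreams keyed by stable stage names, so
adding a stage never perturbs another stage's randomness.  Re-running an
identical configuration reproduces bit-identical outputs, and every
output directory carries a manifest with the configuration hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import rng as crng
from .tracking import TrackingParams


@dataclass
class RunConfig:
    rng_seed: int = 0
    species_a: str = "human"
    species_b: str = "macaque"
    hemisphere: str = "l"
    # tracking
    step_mm: float | None = None          # None: species default
    curvature_limit_deg: float = 80.0
    max_steps: int = 2000
    fraction_threshold: float = 0.01
    seeds_per_voxel: int = 200
    # thresholds
    blueprint_threshold: float = 0.001    # 0.1% on collated path distributions
    similarity_threshold: float = 0.005   # 0.5% before Pearson correlation
    downsample: int = 2
    delta: float = 1e-6
    percentile: float = 7.0
    out_dir: str = "cstract_out"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        return crng.derive_key(self.rng_seed, "stage", stage) % (2**31)

    def tracking_params(self, species_step_mm: float, stage: str = "track") -> TrackingParams:
        return TrackingParams(
            rng_seed=self.stage_seed(stage),
            step_mm=self.step_mm if self.step_mm is not None else species_step_mm,
            curvature_limit_deg=self.curvature_limit_deg, max_steps=self.max_steps,
            fraction_threshold=self.fraction_threshold, seeds_per_voxel=self.seeds_per_voxel)


_DEFAULTS = RunConfig()


def validate_config(cfg: RunConfig) -> dict:
    """Range checks plus a report of every overridden default."""
    problems = []
    if not 0 < cfg.curvature_limit_deg < 180:
        problems.append("curvature_limit_deg must lie in (0, 180)")
    if cfg.step_mm is not None and cfg.step_mm <= 0:
        problems.append("step_mm must be positive")
    if cfg.max_steps < 1:
        problems.append("max_steps must be >= 1")
    for name in ("fraction_threshold", "blueprint_threshold", "similarity_threshold"):
        v = getattr(cfg, name)
        if not 0 <= v < 1:
            problems.append(f"{name} must lie in [0, 1)")
    if cfg.delta <= 0:
        problems.append("delta must be positive (the divergence is degenerate at 0)")
    if not 0 < cfg.percentile <= 100:
        problems.append("percentile must lie in (0, 100]")
    if cfg.downsample < 1:
        problems.append("downsample must be a positive integer factor")
    if cfg.seeds_per_voxel < 1:
        problems.append("seeds_per_voxel must be >= 1")
    overridden = {f.name: getattr(cfg, f.name) for f in dataclasses.fields(cfg)
                  if getattr(cfg, f.name) != getattr(_DEFAULTS, f.name)}
    return {"valid": not problems, "problems": problems, "overridden": overridden}


def load_config(path: str | Path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ValueError(f"unknown configuration keys: {unknown}")
    cfg = RunConfig(**data)
    report = validate_config(cfg)
    if not report["valid"]:
        raise ValueError("invalid configuration: " + "; ".join(report["problems"]))
    return cfg


def save_config(cfg: RunConfig, path: str | Path):
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def write_manifest(out_dir: str | Path, cfg: RunConfig, stages: dict):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "stages": stages,
        "written_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
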