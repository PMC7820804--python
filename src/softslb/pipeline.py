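"""Analysis configuration and stage dispatch.

An AnalysisConfig carries the acquisition parameters shared by all stages
(pixel size, frame interval, exposure), a seed, per-stage parameter blocks
and an output directory; run_pipeline validates it and dispatches to one
stage, logging the resolved parameters into every output file so results are
reproducible from the config alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd

from . import __version__, io, spt, synth

STAGES = ("spt", "frap", "calcium", "exclusion", "afm", "synth")


class ConfigError(ValueError):
    """Invalid or incomplete analysis configuration."""


@dataclass
class AnalysisConfig:
    pixel_size: float | None = None  # um/px
    frame_interval: float | None = None  # s
    exposure_time: float | None = None  # s
    seed: int = 0
    output_dir: str = "."
    stage_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("pixel_size", "frame_interval", "exposure_time"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ConfigError(f"{name} must be positive")

    @classmethod
    def from_json(cls, path) -> "AnalysisConfig":
        data = json.loads(Path(path).read_text())
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def require(self, *names: str) -> None:
        missing = [n for n in names if getattr(self, n) is None]
        if missing:
            raise ConfigError(f"config missing required parameters: {missing}")

    def resolved(self, stage: str) -> dict:
        out = {"stage": stage, "seed": self.seed, "version": __version__}
        for name in ("pixel_size", "frame_interval", "exposure_time"):
            if getattr(self, name) is not None:
                out[name] = getattr(self, name)
        out.update(self.stage_params.get(stage, {}))
        return out


def run_pipeline(config: AnalysisConfig, stage: str, inputs=None):
    """Dispatch one analysis stage; outputs land in config.output_dir."""
    if stage not in STAGES:
        raise ConfigError(f"unknown stage {stage!r}; choose from {STAGES}")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = config.resolved(stage)

    if stage == "synth":
        return _run_synth(config, outdir, params)
    if stage == "spt":
        config.require("pixel_size", "frame_interval")
        tracks = inputs
        curve = spt.compute_ensemble_msd(
            spt.filter_tracks(tracks), max_lag=params.get("max_lag", 10))
        fit = spt.fit_msd(curve, exposure_time=config.exposure_time or 0.0)
        df = pd.DataFrame([{
            "D_um2_per_s": fit.D, "sigma_loc_um": fit.sigma_loc,
            "offset_um2": fit.offset, "n_tracks": curve.n_tracks,
        }])
        io.write_table(df, outdir / "msd_fit.csv", params)
        return df
    raise ConfigError(
        f"stage {stage!r} has no batch driver; use the library API or CLI")


def _run_synth(config: AnalysisConfig, outdir: Path, params: dict):
    """Write a deterministic default synthetic track set (seeded)."""
    gt = synth.DiffusionGroundTruth()
    tracks = synth.simulate_tracks(gt, seed=config.seed)
    df = io.tracks_to_table(tracks)
    io.write_table(df, outdir / "tracks.csv", params)
    return df
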