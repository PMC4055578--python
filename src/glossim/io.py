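"""Run configuration, result writing and manifests.

A run is described by a small YAML/JSON mapping: where the vegetation
grid comes from (a raster file or a builder spec), the bait roster,
schedule and cohort-parameter overrides.  Unknown keys are rejected so
that typos cannot silently fall back to defaults; every default is the
model's standard value and the manifest echoes the full effective
configuration for reproducibility.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import landscape
from .cohort import DEFAULT_DAILY_STEPS, FEEDING_F, CohortParams, StepSchedule
from .kinematics import DEFAULT_H, DispersalParams
from .landscape import VegetationGrid


@dataclass
class RunConfig:
    """Validated configuration of a simulation run."""

    grid_file: str | None = None
    layout: str | None = None          # block | band | checkerboard
    width_m: float = 2000.0
    flank: str = "poor"
    serpentine: bool = False
    h: float = DEFAULT_H
    step_length_m: float = 10.0
    daily_steps: tuple[int, ...] = DEFAULT_DAILY_STEPS
    mobility_multiplier: float = 1.0
    f_by_day: tuple[float, ...] = FEEDING_F
    f_capture: float = 0.6
    wild_host_step_prob: float = 0.00125
    daily_mortality: float = 0.03
    baits: list[dict] = field(default_factory=list)
    output_dir: str = "."
    verbosity: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.h <= 1.0:
            raise ValueError(f"h = {self.h} outside [0, 1]")
        for name in ("wild_host_step_prob", "daily_mortality", "f_capture"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} = {v} outside [0, 1]")
        if any(not 0.0 <= f <= 1.0 for f in self.f_by_day):
            raise ValueError("f_by_day values must lie in [0, 1]")
        if self.step_length_m <= 0:
            raise ValueError("step_length_m must be positive")
        if self.grid_file and not Path(self.grid_file).exists():
            raise FileNotFoundError(self.grid_file)

    # -- realized objects --------------------------------------------------
    def build_grid(self) -> VegetationGrid:
        if self.grid_file:
            return landscape.read_ascii_grid(self.grid_file)
        width_cells = max(1, int(round(self.width_m / self.step_length_m)))
        if self.layout in (None, "block"):
            return landscape.make_block(min(width_cells, 200), self.flank)
        if self.layout == "band":
            return landscape.make_band(width_cells, flank=self.flank,
                                       serpentine=self.serpentine)
        if self.layout == "checkerboard":
            return landscape.make_checkerboard(width_cells)
        raise ValueError(f"unknown layout {self.layout!r}")

    def schedule(self) -> StepSchedule:
        return StepSchedule(tuple(self.daily_steps),
                            mobility_multiplier=self.mobility_multiplier)

    def cohort_params(self) -> CohortParams:
        return CohortParams(self.wild_host_step_prob, self.daily_mortality,
                            tuple(self.f_by_day))

    def dispersal(self) -> DispersalParams:
        return DispersalParams(self.h, self.step_length_m)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["daily_steps"] = list(self.daily_steps)
        d["f_by_day"] = list(self.f_by_day)
        return d


def load_config(path) -> RunConfig:
    """Read a YAML/JSON config file, rejecting unknown keys."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("daily_steps", "f_by_day"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


def grid_hash(grid: VegetationGrid) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(grid.entry).tobytes())
    h.update(str(grid.cell_size).encode())
    return h.hexdigest()[:16]


def write_results(tables: dict[str, pd.DataFrame], out_dir,
                  config: RunConfig | None = None,
                  grid: VegetationGrid | None = None) -> list[Path]:
    """Write result tables as CSV plus a JSON manifest.

    Rows and columns are emitted in a deterministic order so identical
    configurations produce byte-identical outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in sorted(tables.items()):
        path = out / f"{name}.csv"
        df.to_csv(path, index=False, float_format="%.10g")
        written.append(path)
    manifest = {"package": "glossim", "version": _version()}
    if config is not None:
        manifest["config"] = config.as_dict()
    if grid is not None:
        manifest["grid_hash"] = grid_hash(grid)
        manifest["grid_shape"] = list(grid.shape)
    path = out / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(path)
    return written


def _version() -> str:
    from importlib.metadata import PackageNotFoundError, version
    try:
        return version("glossim")
    except PackageNotFoundError:
        return "unknown"
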