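"""Baits (hosts and insecticide-treated targets) and their stimulus footprints.

A bait sits in one cell and stimulates flies over two zones:

* a *visual* zone -- the disc in which the bait can be seen, rasterized
  as the square block of whole cells with the same area.  Visual range
  scales with the cube root of body mass (linear size), anchored at
  6 m for a 50 kg animal.
* an *olfactory* zone -- the downwind odor plume, an isosceles triangle
  with apex at the bait and edges deviating 26 degrees from the wind
  axis.  Plume length scales with the square root of body mass,
  anchored at 90 m for a 470 kg ox; a large artificial target dosed
  with ox odor uses a fixed 60 m plume.

Small baits that cover less than one cell stimulate only a fraction of
the flies in their cell: 50% for a lizard seen but not smelled, 80%
with odor added, and 25% for the tiny (0.06 m^2) odorless target that
is visible from only two directions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .landscape import GOOD, VegetationGrid

#: Body masses (kg) of the four named hosts.
HOST_MASSES = {"lizard": 2.0, "warthog": 42.0, "kudu": 333.0, "elephant": 5196.0}
#: Targets take the visual range of a proxy host.
TARGET_PROXY = {"large_target": "kudu", "tiny_target": "lizard"}

WIND_VECTORS = {"E": (0, 1), "W": (0, -1), "S": (1, 0), "N": (-1, 0)}

VISUAL = "visual"
OLFACTORY = "olfactory"


@dataclass(frozen=True)
class BaitScalingParams:
    """Anchors of the allometric detection-range laws."""

    visual_ref_mass: float = 50.0        # kg
    visual_ref_range: float = 6.0        # m
    olfactory_ref_mass: float = 470.0    # kg
    olfactory_ref_range: float = 90.0    # m
    plume_half_angle_deg: float = 26.0
    large_target_odor_range: float = 60.0  # m

    def __post_init__(self) -> None:
        if min(self.visual_ref_range, self.olfactory_ref_range,
               self.large_target_odor_range) <= 0:
            raise ValueError("reference ranges must be positive")
        if not 0 < self.plume_half_angle_deg < 90:
            raise ValueError("plume half-angle must lie in (0, 90) degrees")


DEFAULT_SCALING = BaitScalingParams()


def visual_range(mass: float, scaling: BaitScalingParams = DEFAULT_SCALING) -> float:
    """Visual detection range in m: 6 * (mass / 50)**(1/3)."""
    if mass <= 0:
        raise ValueError("mass must be positive")
    return scaling.visual_ref_range * (mass / scaling.visual_ref_mass) ** (1 / 3)


def olfactory_range(mass: float, scaling: BaitScalingParams = DEFAULT_SCALING) -> float:
    """Odor-plume length in m: 90 * sqrt(mass / 470)."""
    if mass <= 0:
        raise ValueError("mass must be positive")
    return scaling.olfactory_ref_range * np.sqrt(mass / scaling.olfactory_ref_mass)


@dataclass
class BaitSpec:
    """One bait: kind, mass, cell position and stimulus configuration."""

    kind: str
    position: tuple[int, int]
    mass: float | None = None
    has_odor: bool = False
    wind: str = "E"
    response_mode: str = "day_schedule"  # or "fixed_f"

    def __post_init__(self) -> None:
        if self.mass is None:
            proxy = TARGET_PROXY.get(self.kind, self.kind)
            if proxy not in HOST_MASSES:
                raise ValueError(f"mass required for bait kind {self.kind!r}")
            self.mass = HOST_MASSES[proxy]
        if self.mass <= 0:
            raise ValueError("mass must be positive")
        if self.kind == "tiny_target" and self.has_odor:
            raise ValueError("the tiny target is always used without odor")
        if self.wind not in WIND_VECTORS:
            raise ValueError(f"wind must be one of {sorted(WIND_VECTORS)}")


def make_bait(kind: str, position: tuple[int, int], has_odor: bool = False,
              wind: str = "E", mass: float | None = None,
              response_mode: str = "day_schedule") -> BaitSpec:
    if kind in ("pig", "warthog_pig"):
        kind = "warthog"
    if kind not in HOST_MASSES and kind not in TARGET_PROXY and mass is None:
        raise ValueError(f"unknown bait kind {kind!r}; give a mass for "
                         "custom hosts")
    return BaitSpec(kind, position, mass, has_odor, wind, response_mode)


@dataclass
class StimulusFootprint:
    """Rasterized stimulus zone: cells with per-cell stimulation fractions."""

    rows: np.ndarray
    cols: np.ndarray
    fraction: np.ndarray
    zone: np.ndarray  # per-cell "visual" / "olfactory"

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=int)
        self.cols = np.asarray(self.cols, dtype=int)
        self.fraction = np.asarray(self.fraction, dtype=float)
        self.zone = np.asarray(self.zone)
        if self.fraction.size and not ((self.fraction > 0) & (self.fraction <= 1)).all():
            raise ValueError("stimulation fractions must lie in (0, 1]")

    def __len__(self) -> int:
        return self.rows.size

    @property
    def cells(self) -> set[tuple[int, int]]:
        return set(zip(self.rows.tolist(), self.cols.tolist()))

    def release_cells(self, grid: VegetationGrid) -> tuple[np.ndarray, np.ndarray]:
        """Good-habitat cells of the visual zone (inactive-pool release sites)."""
        vis = self.zone == VISUAL
        good = grid.entry[self.rows[vis], self.cols[vis]] == GOOD
        return self.rows[vis][good], self.cols[vis][good]


def _clip(rows, cols, fraction, zone, grid, warn=True):
    rows = np.asarray(rows, int)
    cols = np.asarray(cols, int)
    inside = (rows >= 0) & (rows < grid.n_rows) & (cols >= 0) & (cols < grid.n_cols)
    if warn and not inside.all():
        warnings.warn("stimulus footprint clipped at the map edge", stacklevel=3)
    return StimulusFootprint(rows[inside], cols[inside],
                             np.asarray(fraction, float)[inside],
                             np.asarray(zone)[inside])


def visual_block_width(mass: float, cell_size: float = 10.0,
                       scaling: BaitScalingParams = DEFAULT_SCALING) -> int:
    """Side (in cells) of the square block with the visual disc's area."""
    r = visual_range(mass, scaling)
    return max(1, round(np.sqrt(np.pi) * r / cell_size))


def visual_footprint(spec: BaitSpec, grid: VegetationGrid,
                     scaling: BaitScalingParams = DEFAULT_SCALING) -> StimulusFootprint:
    """Visual stimulus cells with their stimulation fractions.

    Hosts from warthog size upward cover whole cells (fraction 1.0) in
    an area-matched square block (1x1, 2x2, 5x5 for warthog, kudu,
    elephant).  The lizard and the tiny target stimulate a fraction of
    their single cell.  The large target uses the kudu block reduced to
    a 1x2 block along the wind axis, reflecting the two faces of a flat
    target.
    """
    r0, c0 = spec.position
    if not (0 <= r0 < grid.n_rows and 0 <= c0 < grid.n_cols):
        raise ValueError(f"bait position {spec.position} is off the map")
    if spec.kind == "lizard":
        frac = 0.8 if spec.has_odor else 0.5
        return _clip([r0], [c0], [frac], [VISUAL], grid)
    if spec.kind == "tiny_target":
        return _clip([r0], [c0], [0.25], [VISUAL], grid)
    if spec.kind == "large_target":
        dr, dc = WIND_VECTORS[spec.wind]
        rows = [r0, r0 + dr]
        cols = [c0, c0 + dc]
        return _clip(rows, cols, [1.0, 1.0], [VISUAL, VISUAL], grid)
    k = visual_block_width(spec.mass, grid.cell_size, scaling)
    start_r = r0 - (k - 1) // 2
    start_c = c0 - (k - 1) // 2
    rr, cc = np.meshgrid(np.arange(start_r, start_r + k),
                         np.arange(start_c, start_c + k), indexing="ij")
    n = rr.size
    return _clip(rr.ravel(), cc.ravel(), np.ones(n), np.full(n, VISUAL), grid)


def _plume_length(spec: BaitSpec, scaling: BaitScalingParams) -> float:
    if spec.kind == "large_target":
        return scaling.large_target_odor_range
    return olfactory_range(spec.mass, scaling)


def plume_footprint(spec: BaitSpec, grid: VegetationGrid,
                    scaling: BaitScalingParams = DEFAULT_SCALING) -> StimulusFootprint:
    """Cells of the downwind odor-plume triangle (fraction 1.0 each).

    A cell belongs to the plume iff its center lies strictly inside the
    triangle with apex at the bait cell center, axis along the wind and
    the stated half-angle; the apex cell itself is always included.
    """
    if not spec.has_odor:
        raise ValueError("bait has no odor; no plume to rasterize")
    length = _plume_length(spec, scaling)
    cell = grid.cell_size
    r0, c0 = spec.position
    if length <= 0:
        return StimulusFootprint(np.empty(0, int), np.empty(0, int),
                                 np.empty(0), np.empty(0))
    tan_half = np.tan(np.deg2rad(scaling.plume_half_angle_deg))
    dr, dc = WIND_VECTORS[spec.wind]
    # signed metric offsets of all cell centers from the bait cell center
    drow = (np.arange(grid.n_rows) - r0) * cell
    dcol = (np.arange(grid.n_cols) - c0) * cell
    dy, dx = np.meshgrid(drow, dcol, indexing="ij")
    along = dy * dr + dx * dc
    across = np.abs(dy * dc - dx * dr)
    inside = (along > 0) & (along < length) & (across < along * tan_half)
    inside[r0, c0] = True  # apex cell
    rows, cols = np.nonzero(inside)
    n = rows.size
    return StimulusFootprint(rows, cols, np.ones(n), np.full(n, OLFACTORY))


def stimulus_footprint(spec: BaitSpec, grid: VegetationGrid,
                       scaling: BaitScalingParams = DEFAULT_SCALING) -> StimulusFootprint:
    """Combined visual + olfactory footprint of a bait.

    Cells in both zones keep fraction 1.0 and are labelled visual (the
    visual zone is also where recovering flies are released).  The
    lizard is special-cased: its stimuli stay within its own cell, with
    the with-odor stimulation already folded into the 0.8 fraction.
    """
    vis = visual_footprint(spec, grid, scaling)
    if not spec.has_odor or spec.kind == "lizard":
        return vis
    plume = plume_footprint(spec, grid, scaling)
    vis_cells = vis.cells
    keep = np.array([(r, c) not in vis_cells
                     for r, c in zip(plume.rows, plume.cols)], dtype=bool)
    if keep.size == 0:
        return vis
    return StimulusFootprint(
        np.concatenate([vis.rows, plume.rows[keep]]),
        np.concatenate([vis.cols, plume.cols[keep]]),
        np.concatenate([vis.fraction, plume.fraction[keep]]),
        np.concatenate([vis.zone, plume.zone[keep]]),
    )
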