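"""Drivers for the in-silico habitat-geometry experiments.

Each driver wires the landscape, bait and cohort machinery into one of
the standard experiments: crossover catch comparisons (odor efficacy),
insecticide-target efficacy at varying density, feeding success on
natural hosts, starvation risk part-way through the hunger cycle, and
the nearest-bait geometry underlying all of them.

Catches are normalized as a percent of the initial abundance of tsetse
per square kilometre of good habitat, so that habitats of different
extent are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import landscape
from .baits import BaitSpec, make_bait, stimulus_footprint
from .cohort import (CAPTURE_RESPONSE, FEEDING_RESPONSE, CohortParams,
                     CohortSimulation, DeployedBait, StepSchedule,
                     run_cycle, starvation_probability)
from .landscape import VegetationGrid, geometry_summary, make_long_band


# ---------------------------------------------------------------------------
# placement

def _is_band_like(grid: VegetationGrid) -> bool:
    return grid.layout_kind in ("band", "serpentine") or min(grid.shape) <= 5


def _band_axis_cells(grid: VegetationGrid) -> tuple[int, np.ndarray]:
    """Center row of a horizontal band and the columns it spans."""
    rows, cols = np.nonzero(grid.good_mask)
    row = int(round(rows.mean()))
    span = np.unique(cols[rows == row])
    return row, span


def place_singly(grid: VegetationGrid, density_per_km2: float,
                 group_size: int = 1) -> list[tuple[int, int]]:
    """Even "singly" placement of baits at a density per km2 of habitat.

    Blocks get a square lattice; bands get equal spacing along the band
    axis.  With ``group_size > 1`` each placement becomes a group of
    that many baits in consecutive cells along the (band or column)
    axis, as in the grouped-host comparisons.
    """
    if density_per_km2 <= 0:
        raise ValueError("density must be positive")
    area = geometry_summary(grid).good_area_km2
    n = max(1, round(density_per_km2 * area / group_size))
    positions: list[tuple[int, int]] = []
    if _is_band_like(grid):
        row, span = _band_axis_cells(grid)
        length = span.size
        spacing = length / n
        for i in range(n):
            c = span[0] + int(round(spacing * (i + 0.5)))
            start = c - (group_size - 1) // 2
            positions.extend((row, start + g) for g in range(group_size))
    else:
        k = max(1, round(np.sqrt(n)))
        dr = grid.n_rows / k
        dc = grid.n_cols / (n / k)
        n_per_row = int(round(n / k))
        for i in range(k):
            r = int(dr * (i + 0.5))
            for j in range(n_per_row):
                c = int(dc * (j + 0.5))
                start = c - (group_size - 1) // 2
                positions.extend((r, start + g) for g in range(group_size))
    for r, c in positions:
        if not (0 <= r < grid.n_rows and 0 <= c < grid.n_cols
                and grid.entry[r, c] > 0):
            raise ValueError(f"placement {(r, c)} falls outside habitat")
    return positions


def long_band_for_density(width_cells: int, density_per_km2: float,
                          n_baits: int = 4,
                          cell_size: float = 10.0) -> VegetationGrid:
    """Long thin band sized so ``n_baits`` fit at the requested density.

    Low densities in narrow bands imply bait spacings of several km --
    longer than one 2-km map -- so the band is built as a long grid
    whose reflecting ends stand in for the continuing band.
    """
    width_m = width_cells * cell_size
    spacing_m = 1e6 / (density_per_km2 * width_m)
    length_cells = int(round(n_baits * spacing_m / cell_size))
    return make_long_band(length_cells, width_cells, cell_size)


def nearest_bait_distance(grid: VegetationGrid, density_per_km2: float) -> float:
    """Mean distance (m) from a good cell to the nearest evenly placed bait."""
    positions = place_singly(grid, density_per_km2)
    cs = grid.cell_size
    pts = (np.asarray(positions) + 0.5) * cs
    rows, cols = np.nonzero(grid.good_mask)
    cells = np.column_stack([(rows + 0.5) * cs, (cols + 0.5) * cs])
    dist, _ = cKDTree(pts).query(cells)
    return float(dist.mean())


# ---------------------------------------------------------------------------
# crossover catch experiments

@dataclass(frozen=True)
class CrossoverDesign:
    """Six-day two-site crossover with afternoon-only bait presence."""

    n_days: int = 6
    sites: tuple[tuple[int, int], tuple[int, int]] | None = None
    presence: str = "second_half"


@dataclass(frozen=True)
class CatchResult:
    """Catches (percent of initial abundance per km2 of good habitat)."""

    catch_a: float
    catch_b: float

    def efficacy_percent(self) -> float:
        """Percent by which bait A's catch exceeds bait B's."""
        return 100.0 * (self.catch_a - self.catch_b) / self.catch_b


def default_sites(grid: VegetationGrid) -> tuple[tuple[int, int], tuple[int, int]]:
    """Two sites on the habitat's medial axis, a quarter map apart each
    from center (1 km apart on the default map)."""
    rows, cols = np.nonzero(grid.good_mask)
    if rows.size == 1:
        cell = (int(rows[0]), int(cols[0]))
        return cell, cell
    row = int(round(rows.mean()))
    row_cols = np.unique(cols[rows == row])
    c1 = row_cols[row_cols.size // 4]
    c2 = row_cols[(3 * row_cols.size) // 4]
    return (row, int(c1)), (row, int(c2))


def crossover_catch(grid: VegetationGrid, bait_a: BaitSpec, bait_b: BaitSpec,
                    design: CrossoverDesign | None = None,
                    schedule: StepSchedule | None = None,
                    params: CohortParams | None = None) -> CatchResult:
    """Simulated electric-pen crossover catch of two baits.

    The baits operate simultaneously at two well-separated sites and
    swap sites daily; each is present only during the second half of
    each day's step periods and captures arriving flies with fixed
    f = 0.6.  With a single-cell habitat the two "sites" coincide and
    each bait is run in its own cycle.
    """
    design = design or CrossoverDesign()
    sites = design.sites or default_sites(grid)
    s1, s2 = sites
    area = geometry_summary(grid).good_area_km2

    def percent(caught: float, initial_total: float) -> float:
        return 100.0 * caught * area / initial_total

    if s1 == s2:  # degenerate habitat: run the baits separately
        catches = []
        for spec in (bait_a, bait_b):
            bait = DeployedBait(
                replace(spec, position=s1),
                [stimulus_footprint(replace(spec, position=s1), grid)],
                CAPTURE_RESPONSE)
            res = run_cycle(grid, [bait], schedule, params,
                            presence=design.presence, end_day=design.n_days)
            catches.append(percent(float(res.state.caught.sum()),
                                   res.state.initial_total))
        return CatchResult(*catches)

    def day_footprints(spec: BaitSpec, first_site) -> list:
        fps = []
        for day in range(design.n_days):
            site = first_site if day % 2 == 0 else (s2 if first_site == s1 else s1)
            fps.append(stimulus_footprint(replace(spec, position=site), grid))
        return fps

    baits = [DeployedBait(bait_a, day_footprints(bait_a, s1), CAPTURE_RESPONSE),
             DeployedBait(bait_b, day_footprints(bait_b, s2), CAPTURE_RESPONSE)]
    res = run_cycle(grid, baits, schedule, params,
                    presence=design.presence, end_day=design.n_days)
    init = res.state.initial_total
    return CatchResult(percent(float(res.state.caught[0]), init),
                       percent(float(res.state.caught[1]), init))


def odor_efficacy(grid: VegetationGrid, kind: str, wind: str = "E",
                  design: CrossoverDesign | None = None) -> tuple[float, float, float]:
    """(catch visual+odor, catch visual only, efficacy %) for one host.

    Compares the host (with odor) against an odorless model animal of
    the same size, the standard field measure of odor's contribution.
    """
    host = make_bait(kind, (0, 0), has_odor=True, wind=wind)
    model = make_bait(kind, (0, 0), has_odor=False, wind=wind)
    res = crossover_catch(grid, host, model, design)
    return res.catch_a, res.catch_b, res.efficacy_percent()


HABITATS_TABLE2 = ("large_block", "band_50m", "band_10m")


def _habitat_grid(name: str) -> VegetationGrid:
    if name == "large_block":
        return landscape.make_block(200, "poor")
    if name == "band_50m":
        return landscape.make_band(5, flank="nogo")
    if name == "band_10m":
        return landscape.make_band(1, flank="nogo")
    raise ValueError(f"unknown habitat {name!r}")


def catch_table(hosts=("lizard", "warthog", "kudu", "elephant"),
                habitats=HABITATS_TABLE2) -> pd.DataFrame:
    """Crossover catches and odor efficacy for each host x habitat."""
    records = []
    for habitat in habitats:
        grid = _habitat_grid(habitat)
        for kind in hosts:
            vo, v, eff = odor_efficacy(grid, kind)
            records.append({"habitat": habitat, "host": kind,
                            "catch_visual": v, "catch_visual_odor": vo,
                            "odor_efficacy_percent": eff})
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# target efficacy

def target_efficacy(grid: VegetationGrid, target_kind: str,
                    density_per_km2: float, has_odor: bool = False,
                    wind: str = "E",
                    schedule: StepSchedule | None = None,
                    params: CohortParams | None = None) -> float:
    """Percent of the population killed per hunger cycle by targets.

    Targets are placed singly and evenly at the given density and
    operate continuously; the close-range response follows the rising
    day schedule.  Wild hosts compete as usual.
    """
    if density_per_km2 == 0:
        return 0.0
    positions = place_singly(grid, density_per_km2)
    baits = [DeployedBait(make_bait(target_kind, pos, has_odor=has_odor,
                                    wind=wind),
                          [stimulus_footprint(
                              make_bait(target_kind, pos, has_odor=has_odor,
                                        wind=wind), grid)],
                          FEEDING_RESPONSE)
             for pos in positions]
    res = run_cycle(grid, baits, schedule, params, presence="always")
    return 100.0 * res.caught_total / res.state.initial_total


# ---------------------------------------------------------------------------
# feeding success

def feeding_success(grid: VegetationGrid, host_kind: str,
                    density_per_km2: float, group_size: int = 1,
                    horizon_days: int = 4,
                    schedule: StepSchedule | None = None) -> float:
    """Cumulative percent of the cohort fed on mapped hosts by a horizon.

    Flies feed only on the introduced stationary hosts (the wild-host
    encounter probability is zero); hosts operate through all
    host-searching steps with the rising probing response.
    """
    positions = place_singly(grid, density_per_km2, group_size)
    baits = [DeployedBait(make_bait(host_kind, pos),
                          [stimulus_footprint(make_bait(host_kind, pos), grid)],
                          FEEDING_RESPONSE)
             for pos in positions]
    params = CohortParams(wild_host_step_prob=0.0)
    res = run_cycle(grid, baits, schedule, params, presence="always",
                    end_day=horizon_days)
    return 100.0 * res.caught_total / res.state.initial_total


# ---------------------------------------------------------------------------
# starvation risk

def starvation_percent(grid: VegetationGrid, host_kind: str,
                       density_per_km2: float, day_completed: int,
                       mobility_multiplier: float = 1.0) -> float:
    """Percent probability that flies unfed after ``day_completed`` days
    starve, with mapped hosts only and the given mobility."""
    positions = place_singly(grid, density_per_km2)
    baits = [DeployedBait(make_bait(host_kind, pos),
                          [stimulus_footprint(make_bait(host_kind, pos), grid)],
                          FEEDING_RESPONSE)
             for pos in positions]
    schedule = StepSchedule(mobility_multiplier=mobility_multiplier)
    params = CohortParams(wild_host_step_prob=0.0)
    return 100.0 * starvation_probability(grid, baits, day_completed,
                                          schedule, params)


def starvation_table(conditions, multipliers=(1 / 3, 1.0, 3.0),
                     days=(2, 5)) -> pd.DataFrame:
    """Starvation probabilities over host/habitat/day/mobility conditions.

    ``conditions`` is an iterable of ``(label, grid, host_kind,
    density_per_km2)`` tuples.
    """
    records = []
    for label, grid, kind, density in conditions:
        for day in days:
            for mult in multipliers:
                pct = starvation_percent(grid, kind, density, day, mult)
                records.append({"condition": label, "host": kind,
                                "density_per_km2": density,
                                "days_completed": day,
                                "steps_per_cycle":
                                    StepSchedule(mobility_multiplier=mult).steps_per_cycle,
                                "starvation_percent": pct})
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# displacement vs habitat width (movement experiments)

def displacement_percent(grid: VegetationGrid, n_steps: int = 1000,
                         seed_cell: tuple[int, int] | None = None) -> float:
    """Displacement after ``n_steps`` as percent of the homogeneous value."""
    from .kinematics import displacement_after

    if seed_cell is None:
        good = np.nonzero(grid.good_mask)
        center = (grid.n_rows // 2, grid.n_cols // 2)
        i = np.argmin((good[0] - center[0]) ** 2 + (good[1] - center[1]) ** 2)
        seed_cell = (int(good[0][i]), int(good[1][i]))
    ref_grid = landscape.make_block(min(*grid.shape),
                                    shape=(min(*grid.shape),) * 2,
                                    cell_size=grid.cell_size)
    ref = displacement_after(ref_grid, n_steps).mean_displacement
    d = displacement_after(grid, n_steps, seed_cell=seed_cell).mean_displacement
    return 100.0 * d / ref
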