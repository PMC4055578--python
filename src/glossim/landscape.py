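"""Vegetation grids: habitat geometry for the movement model.

The habitat is a lattice of square cells (default 200x200 cells of 10 m,
i.e. a 2x2 km map).  Each cell carries an *entry probability* describing
its vegetation: 1.0 ("good"), 0.1 ("poor") or 0.0 ("no-go", e.g. an
impenetrable bush or open ground a riverine fly will not enter).  The
entry probabilities drive the cell-crossing rule in
:mod:`glossim.kinematics`.

Builders are provided for the canonical geometries used in habitat
experiments: square blocks, straight and serpentine bands, checkerboards
of good/poor blocks, and bush patterns punched into otherwise good
habitat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

GOOD = 1.0
POOR = 0.1
NOGO = 0.0
LEGAL_ENTRY = (GOOD, POOR, NOGO)

_FLANK = {"poor": POOR, "nogo": NOGO, "no-go": NOGO, "good": GOOD}

DEFAULT_SHAPE = (200, 200)
DEFAULT_CELL_SIZE = 10.0


class DisconnectedHabitatError(ValueError):
    """Raised when a bush pattern would leave no usable habitat."""


@dataclass
class VegetationGrid:
    """Per-cell entry probabilities on a rectangular lattice.

    Parameters
    ----------
    entry
        Array of shape ``(n_rows, n_cols)`` with entry probabilities,
        normally drawn from ``{1.0, 0.1, 0.0}``.
    cell_size
        Cell edge length in metres (default 10).
    layout_kind
        One of ``block, band, checkerboard, serpentine, custom`` --
        informational only.
    band_width_m
        Width of the band for band-like layouts, in metres.
    """

    entry: np.ndarray
    cell_size: float = DEFAULT_CELL_SIZE
    layout_kind: str = "custom"
    band_width_m: float | None = None

    def __post_init__(self) -> None:
        self.entry = np.asarray(self.entry, dtype=float)
        if self.entry.ndim != 2 or min(self.entry.shape) < 1:
            raise ValueError("entry grid must be 2-D with at least one cell")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def n_rows(self) -> int:
        return self.entry.shape[0]

    @property
    def n_cols(self) -> int:
        return self.entry.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.entry.shape

    @property
    def good_mask(self) -> np.ndarray:
        return self.entry == GOOD

    @property
    def habitable_mask(self) -> np.ndarray:
        return self.entry > 0.0

    def validate(self, strict: bool = True) -> None:
        """Check invariants; with ``strict`` also require legal entry values."""
        if strict and not np.isin(self.entry, LEGAL_ENTRY).all():
            bad = np.unique(self.entry[~np.isin(self.entry, LEGAL_ENTRY)])
            raise ValueError(f"illegal entry probabilities: {bad}")
        if (self.entry < 0).any() or (self.entry > 1).any():
            raise ValueError("entry probabilities must lie in [0, 1]")
        if not self.habitable_mask.any():
            raise ValueError("grid has no cell with entry probability > 0")

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Metric (y, x) coordinates of every cell center."""
        y = (np.arange(self.n_rows) + 0.5) * self.cell_size
        x = (np.arange(self.n_cols) + 0.5) * self.cell_size
        return y, x

    def copy(self) -> "VegetationGrid":
        return replace(self, entry=self.entry.copy())


@dataclass(frozen=True)
class GeometrySummary:
    good_area_km2: float
    band_width_m: float | None
    layout_kind: str
    n_good: int
    n_poor: int
    n_nogo: int


def geometry_summary(grid: VegetationGrid) -> GeometrySummary:
    n_good = int((grid.entry == GOOD).sum())
    n_poor = int((grid.entry == POOR).sum())
    n_nogo = int((grid.entry == NOGO).sum())
    area = n_good * grid.cell_size**2 / 1e6
    return GeometrySummary(area, grid.band_width_m, grid.layout_kind,
                           n_good, n_poor, n_nogo)


def good_area_km2(grid: VegetationGrid) -> float:
    return geometry_summary(grid).good_area_km2


def _flank_value(flank: str | float) -> float:
    if isinstance(flank, str):
        try:
            return _FLANK[flank.lower()]
        except KeyError:
            raise ValueError(f"unknown vegetation class {flank!r}") from None
    return float(flank)


def make_block(width_cells: int, vegetation_outside: str | float = "poor",
               shape: tuple[int, int] = DEFAULT_SHAPE,
               cell_size: float = DEFAULT_CELL_SIZE) -> VegetationGrid:
    """Square block of good habitat centered on the map.

    ``vegetation_outside`` fills the remainder ("poor" or "nogo").  A
    block as wide as the map is the homogeneous good habitat.
    """
    n_rows, n_cols = shape
    if not 1 <= width_cells <= min(n_rows, n_cols):
        raise ValueError(f"block width {width_cells} exceeds map {shape}")
    entry = np.full(shape, _flank_value(vegetation_outside))
    r0 = (n_rows - width_cells) // 2
    c0 = (n_cols - width_cells) // 2
    entry[r0:r0 + width_cells, c0:c0 + width_cells] = GOOD
    return VegetationGrid(entry, cell_size, "block")


def make_band(width_cells: int, orientation: str = "horizontal",
              flank: str | float = "nogo", serpentine: bool = False,
              shape: tuple[int, int] = DEFAULT_SHAPE,
              cell_size: float = DEFAULT_CELL_SIZE,
              bend_spacing: int = 195) -> VegetationGrid:
    """Band of good habitat crossing the map, flanked by poor/no-go.

    With ``serpentine=True`` the band takes a right-angle bend near each
    map edge (default every 195 cells, i.e. nearly 2 km) so that a band
    much longer than the map fits onto it.
    """
    n_rows, n_cols = shape
    along = n_cols if orientation == "horizontal" else n_rows
    across = n_rows if orientation == "horizontal" else n_cols
    if width_cells < 1:
        raise ValueError("band width must be >= 1 cell")
    if width_cells >= across:
        raise ValueError("band as wide as the map is a block; use make_block")
    if serpentine:
        grid = _make_serpentine(width_cells, flank, shape, cell_size,
                                bend_spacing)
    else:
        entry = np.full(shape, _flank_value(flank))
        c0 = (across - width_cells) // 2
        if orientation == "horizontal":
            entry[c0:c0 + width_cells, :] = GOOD
        else:
            entry[:, c0:c0 + width_cells] = GOOD
        grid = VegetationGrid(entry, cell_size, "band")
    grid.band_width_m = width_cells * cell_size
    return grid


def _make_serpentine(width: int, flank, shape, cell_size,
                     bend_spacing: int) -> VegetationGrid:
    """Snake layout: horizontal runs joined by short vertical connectors.

    Runs are ``bend_spacing`` cells long and separated by one flank row
    per band row, giving an effective band length of several map widths.
    """
    n_rows, n_cols = shape
    run_len = min(bend_spacing, n_cols)
    entry = np.full(shape, _flank_value(flank))
    pitch = 2 * width  # band rows + equal separation
    r = 0
    leg = 0
    while r + width <= n_rows:
        rows = slice(r, r + width)
        if leg % 2 == 0:
            entry[rows, :run_len] = GOOD
        else:
            entry[rows, n_cols - run_len:] = GOOD
        # vertical connector to the next run
        r_next = r + pitch
        if r_next + width <= n_rows:
            cols = (slice(run_len - width, run_len) if leg % 2 == 0
                    else slice(n_cols - run_len, n_cols - run_len + width))
            entry[r:r_next + width, cols] = GOOD
        r = r_next
        leg += 1
    return VegetationGrid(entry, cell_size, "serpentine")


def make_checkerboard(block_width_cells: int,
                      shape: tuple[int, int] = DEFAULT_SHAPE,
                      cell_size: float = DEFAULT_CELL_SIZE) -> VegetationGrid:
    """Alternating good/poor square blocks tiling the map."""
    n_rows, n_cols = shape
    if block_width_cells < 1:
        raise ValueError("block width must be >= 1")
    r_idx = np.arange(n_rows) // block_width_cells
    c_idx = np.arange(n_cols) // block_width_cells
    parity = (r_idx[:, None] + c_idx[None, :]) % 2
    entry = np.where(parity == 0, GOOD, POOR)
    return VegetationGrid(entry.astype(float), cell_size, "checkerboard")


def make_long_band(length_cells: int, width_cells: int = 1,
                   cell_size: float = DEFAULT_CELL_SIZE) -> VegetationGrid:
    """A long thin band as a ``width x length`` all-good grid.

    The reflecting map edges act exactly like the no-go flanks of an
    on-map band, so this is the efficient equivalent of a serpentine
    band several map-widths long (used for low host densities whose
    spacing exceeds one 2-km map).
    """
    entry = np.full((width_cells, length_cells), GOOD)
    grid = VegetationGrid(entry, cell_size, "band")
    grid.band_width_m = width_cells * cell_size
    return grid


# ---------------------------------------------------------------------------
# bushes

@dataclass(frozen=True)
class BushPatternSpec:
    """Parameterized generator of no-go "bush" cells inside good habitat.

    kind:
        ``spaced``    -- isolated single bushes on a regular lattice;
        ``staggered`` -- offset rows of bushes forcing tortuous paths;
        ``comb``      -- teeth growing from one side, creating dead-ends;
        ``maze``      -- dense alternating comb (teeth from both sides).
    spacing: lattice pitch in cells; tooth_length for comb/maze.
    """

    kind: str = "spaced"
    spacing: int = 4
    tooth_length: int = 3


def bush_cells(grid: VegetationGrid, pattern: BushPatternSpec) -> list[tuple[int, int]]:
    """Cells the pattern would turn into bushes, restricted to good habitat."""
    rows, cols = np.nonzero(grid.good_mask)
    if rows.size == 0:
        return []
    r0, r1 = rows.min(), rows.max()
    c0, c1 = cols.min(), cols.max()
    s = pattern.spacing
    cells: list[tuple[int, int]] = []
    if pattern.kind == "spaced":
        for r in range(r0 + 1, r1 + 1, s):
            for c in range(c0 + 1, c1 + 1, s):
                cells.append((r, c))
    elif pattern.kind == "staggered":
        for k, c in enumerate(range(c0 + 1, c1 + 1, s)):
            offset = (k % 2) * (s // 2)
            for r in range(r0 + offset, r1 + 1, s):
                cells.append((r, c))
    elif pattern.kind in ("comb", "maze"):
        length = min(pattern.tooth_length, r1 - r0)
        for k, c in enumerate(range(c0 + 1, c1 + 1, s)):
            if pattern.kind == "comb" or k % 2 == 0:
                cells.extend((r0 + i, c) for i in range(length))
            else:
                cells.extend((r1 - i, c) for i in range(length))
    else:
        raise ValueError(f"unknown bush pattern kind {pattern.kind!r}")
    good = grid.good_mask
    return [(r, c) for r, c in cells
            if 0 <= r < grid.n_rows and 0 <= c < grid.n_cols and good[r, c]]


def add_bushes(grid: VegetationGrid,
               pattern: BushPatternSpec | list[tuple[int, int]]) -> VegetationGrid:
    """Set pattern cells to no-go; good habitat must remain usable.

    Multiple disconnected good components are allowed (with a warning);
    a pattern wiping out all good habitat raises
    :class:`DisconnectedHabitatError`.
    """
    cells = (bush_cells(grid, pattern) if isinstance(pattern, BushPatternSpec)
             else list(pattern))
    out = grid.copy()
    for r, c in cells:
        if not grid.good_mask[r, c]:
            raise ValueError(f"bush cell {(r, c)} is not inside good habitat")
        out.entry[r, c] = NOGO
    n_components = count_components(out)
    if out.habitable_mask.sum() == 0 or (cells and not out.good_mask.any()):
        raise DisconnectedHabitatError("bush pattern removed all good habitat")
    if n_components > 1:
        warnings.warn(f"good habitat split into {n_components} components; "
                      "seed flies per component", stacklevel=2)
    return out


def count_components(grid: VegetationGrid) -> int:
    """Number of 4-connected components of good habitat."""
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    _, n = ndimage.label(grid.good_mask, structure=structure)
    return n


# ---------------------------------------------------------------------------
# plain-text raster I/O (ESRI ASCII style) and CSV

def write_ascii_grid(grid: VegetationGrid, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write("xllcorner 0.0\n")
        fh.write("yllcorner 0.0\n")
        fh.write(f"cellsize {grid.cell_size}\n")
        fh.write("NODATA_value -9999\n")
        for row in grid.entry:
            fh.write(" ".join(format(v, "g") for v in row) + "\n")


def read_ascii_grid(path) -> VegetationGrid:
    header: dict[str, float] = {}
    data_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and not parts[0].lstrip("-+").replace(".", "").isdigit():
                header[parts[0].lower()] = float(parts[1])
            else:
                data_lines.append(line)
    entry = np.loadtxt(data_lines, ndmin=2)
    ncols = int(header.get("ncols", entry.shape[1]))
    nrows = int(header.get("nrows", entry.shape[0]))
    if entry.shape != (nrows, ncols):
        raise ValueError(f"grid body {entry.shape} does not match header "
                         f"({nrows}, {ncols})")
    return VegetationGrid(entry, header.get("cellsize", DEFAULT_CELL_SIZE))


def write_csv_grid(grid: VegetationGrid, path) -> None:
    np.savetxt(path, grid.entry, delimiter=",", fmt="%g")


def read_csv_grid(path, cell_size: float = DEFAULT_CELL_SIZE) -> VegetationGrid:
    return VegetationGrid(np.loadtxt(path, delimiter=",", ndmin=2), cell_size)
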