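"""Rectangular cellular resource landscape.

The world is a grid of patches, each holding a scalar resource stock
``R_k`` and an occupancy count ``J_k`` (number of agents standing on the
patch).  Patches are coupled only through the foragers that move between
them; resource dynamics are purely local, following a discrete logistic
regrowth map with a small reservoir term that reseeds emptied patches.

Cells are indexed row-major, 0-based.  Neighbourhoods are Moore
neighbourhoods (the 8 surrounding cells).  The grid is toroidal by
default, which makes every neighbourhood exactly 8 cells; a bounded mode
is kept for sensitivity checks, where corner cells have 3 neighbours and
edge cells 5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

__all__ = [
    "GridSpec",
    "ResourceParams",
    "Landscape",
    "moore_neighbors",
    "neighborhood_mean",
    "neighborhood_means",
    "init_resources",
    "regrow",
]

# Row-major order over the 3x3 block minus the centre; this fixed order
# defines the neighbour slots l = 1..8 used by the movement rule.
_MOORE_OFFSETS: tuple[tuple[int, int], ...] = (
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
)


@dataclass(frozen=True)
class GridSpec:
    """Dimensions and topology of the cellular array.

    The default 20 x 20 = 400 patches matches the density arithmetic of
    the baseline study design (10 agents on 400 patches = 0.025 per
    patch).
    """

    n_rows: int = 20
    n_cols: int = 20
    toroidal: bool = True

    def __post_init__(self) -> None:
        if self.n_rows < 3 or self.n_cols < 3:
            raise ValueError(
                "grid must be at least 3x3 so Moore neighbourhoods are "
                f"well defined, got {self.n_rows}x{self.n_cols}"
            )

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def cell_index(self, row: int, col: int) -> int:
        return row * self.n_cols + col

    def cell_coords(self, k: int) -> tuple[int, int]:
        return divmod(k, self.n_cols)


@dataclass(frozen=True)
class ResourceParams:
    """Per-patch resource dynamics and initialisation parameters.

    r : intrinsic growth rate per tick.
    s : saturation level; regrowth vanishes at R = s.
    g : reservoir level; lets an emptied patch (R = 0) recover.
    r_min, r_max : bounds of the uniform initial-resource draw applied
        to every patch at the start of each generation.  The narrow
        baseline range [2.99, 3.00] makes the landscape near-homogeneous
        while leaving just enough noise to randomise early movement.
    """

    r: float = 0.1
    s: float = 20.0
    g: float = 0.1
    r_min: float = 2.99
    r_max: float = 3.00

    def __post_init__(self) -> None:
        if self.r < 0:
            raise ValueError(f"growth rate r must be >= 0, got {self.r}")
        if self.s <= 0:
            raise ValueError(f"saturation s must be > 0, got {self.s}")
        if self.g < 0:
            raise ValueError(f"reservoir g must be >= 0, got {self.g}")
        if not 0 <= self.r_min <= self.r_max:
            raise ValueError(
                f"need 0 <= r_min <= r_max, got [{self.r_min}, {self.r_max}]"
            )


@dataclass
class Landscape:
    """Grid state: per-cell resources ``R`` and occupancy counts ``J``."""

    grid: GridSpec
    R: np.ndarray
    J: np.ndarray

    def copy(self) -> "Landscape":
        return Landscape(self.grid, self.R.copy(), self.J.copy())

    def to_frame(self):
        """Snapshot as a DataFrame (cell_row, cell_col, R, J)."""
        import pandas as pd

        rows, cols = np.divmod(np.arange(self.grid.n_cells), self.grid.n_cols)
        return pd.DataFrame(
            {"cell_row": rows, "cell_col": cols, "R": self.R, "J": self.J}
        )


@lru_cache(maxsize=None)
def _neighbor_table(grid: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    """(n_cells, 8) neighbour indices (-1 where out of bounds) and counts."""
    nr, nc = grid.n_rows, grid.n_cols
    rows, cols = np.divmod(np.arange(nr * nc), nc)
    table = np.empty((nr * nc, 8), dtype=np.int64)
    for slot, (dr, dc) in enumerate(_MOORE_OFFSETS):
        rr = rows + dr
        cc = cols + dc
        if grid.toroidal:
            table[:, slot] = (rr % nr) * nc + (cc % nc)
        else:
            inside = (rr >= 0) & (rr < nr) & (cc >= 0) & (cc < nc)
            table[:, slot] = np.where(inside, rr * nc + cc, -1)
    counts = (table >= 0).sum(axis=1)
    return table, counts


def moore_neighbors(k: int, grid: GridSpec) -> list[int]:
    """Moore neighbourhood of cell ``k`` in deterministic row-major order.

    Toroidal grids always return 8 distinct cells; bounded grids return
    only the in-bounds cells (3 at corners, 5 at edges).  ``k`` itself is
    never included.
    """
    if not 0 <= k < grid.n_cells:
        raise IndexError(f"cell index {k} out of range for {grid.n_cells} cells")
    table, _ = _neighbor_table(grid)
    return [int(j) for j in table[k] if j >= 0]


def neighborhood_mean(values: np.ndarray, k: int, grid: GridSpec) -> float:
    """Mean of ``values`` over the Moore neighbourhood of cell ``k``.

    The divisor is the actual neighbour count (8 on a torus, fewer at
    bounded edges), keeping neighbourhood means comparable across cells.
    """
    values = np.asarray(values)
    if values.shape[0] != grid.n_cells:
        raise ValueError("values must have one entry per cell")
    nbrs = moore_neighbors(k, grid)
    return float(np.mean(values[nbrs]))


def neighborhood_means(values: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Vector of Moore-neighbourhood means for every cell at once."""
    table, counts = _neighbor_table(grid)
    values = np.asarray(values, dtype=float)
    safe = np.where(table >= 0, table, 0)
    picked = values[safe]
    picked[table < 0] = 0.0
    return picked.sum(axis=1) / counts


def init_resources(
    grid: GridSpec, params: ResourceParams, rng: np.random.Generator
) -> Landscape:
    """Fresh landscape for the start of a generation.

    Every cell's resource is drawn independently and uniformly on
    [r_min, r_max]; all occupancy counts start at zero.
    """
    R = rng.uniform(params.r_min, params.r_max, size=grid.n_cells)
    J = np.zeros(grid.n_cells, dtype=np.int64)
    return Landscape(grid, R, J)


def regrow(R_star, params: ResourceParams):
    """One tick of post-extraction resource regrowth.

    R(t+1) = R* + r (1 - R*/s) (R* + g)

    where ``R*`` is the stock left after extraction.  With the baseline
    parameters this map is strictly increasing on [0, s], fixes s, and
    maps [0, s] into (0, s], so resources stay positive and bounded once
    the run starts.  Accepts scalars or arrays.
    """
    R_star = np.asarray(R_star, dtype=float)
    if np.any(R_star < 0):
        raise ValueError("post-extraction resource is negative; extraction bug upstream")
    out = R_star + params.r * (1.0 - R_star / params.s) * (R_star + params.g)
    if out.ndim == 0:
        return float(out)
    return out
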