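"""Annual cellular-automaton dispersal constraint on future range maps.

Each year a suitable cell becomes occupied if its center lies within the
annual dispersal distance (Euclidean, cell center to cell center) of an
occupied cell.  Suitability is held piecewise-constant within each period
(e.g. 30-year climate intervals); at a period transition, occupied cells
that are no longer suitable are vacated and can only be recolonized by
dispersal.  The automaton is fully deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .enm import BinaryMap, _disc_structure

__all__ = ["DispersalRun", "run_automaton"]


@dataclass
class DispersalRun:
    rate_m_per_year: float
    initial: np.ndarray
    constrained: dict            # period -> BinaryMap (occupied at period end)
    colonization_year: np.ndarray  # year the cell first became occupied; -1 never

    def area_km2(self, period: str) -> float:
        return self.constrained[period].area_km2


def run_automaton(binary_series: list[BinaryMap], initial: np.ndarray,
                  rate_m_per_year: float, years_per_period: int = 30) -> DispersalRun:
    """Run the annual colonization automaton across an ordered period series.

    ``binary_series`` holds one suitability BinaryMap per period in
    chronological order (the first is the current period, whose map the
    ``initial`` occupancy must already respect); ``initial`` is the boolean
    starting occupancy.  Returns per-period constrained maps and the first
    colonization year per cell (year 0 = start).
    """
    if not binary_series:
        raise ValueError("empty period series")
    grid = binary_series[0].grid
    for b in binary_series:
        if b.values.shape != grid.shape:
            raise ValueError("period maps must share one grid")
    cell = grid.cellsize
    if rate_m_per_year < cell:
        warnings.warn("dispersal rate below cell size: no spread, occupied "
                      "suitable cells only persist")
        struct = np.ones((1, 1), bool)  # identity: no spread
    else:
        # a disc larger than the grid diagonal behaves identically to one
        # exactly covering it, so cap the structuring element there
        max_cells = float(np.hypot(*grid.shape)) + 1
        struct = _disc_structure(min(rate_m_per_year / cell, max_cells))
    occupied = np.asarray(initial, bool) & binary_series[0].values.astype(bool)
    colonized = np.where(occupied, 0, -1)
    year = 0
    constrained: dict = {}
    for i, bmap in enumerate(binary_series):
        suit = bmap.values.astype(bool)
        # period transition: vacate cells that lost suitability
        occupied &= suit
        if i == 0:
            constrained[bmap.period] = BinaryMap(
                occupied.astype(np.int8), grid, bmap.period, bmap.scenario,
                bmap.threshold_method, bmap.buffered)
            continue
        for _ in range(years_per_period):
            year += 1
            if not occupied.any():
                break
            reach = ndimage.binary_dilation(occupied, structure=struct)
            new = reach & suit & ~occupied
            occupied |= new
            colonized[new & (colonized < 0)] = year
        constrained[bmap.period] = BinaryMap(
            occupied.astype(np.int8), grid, bmap.period, bmap.scenario,
            bmap.threshold_method, bmap.buffered)
    return DispersalRun(rate_m_per_year, np.asarray(initial, bool),
                        constrained, colonized)
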