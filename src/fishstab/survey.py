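"""Design-based trawl-survey biomass indices.

A stratified random survey within depth strata yields per-haul catch
densities (catch mass / swept area).  The design-based index expands the
stratum mean densities by stratum area and sums; this is a transparent
stand-in for model-based spatiotemporal index standardization, producing
the same downstream ``BiomassIndex`` records.

``grid_aggregate`` integrates an arbitrary density surface over a
prediction grid of equal-area cells (default 6.25 km^2), the same
area-weighting used to turn model predictions into indices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger("fishstab")

#: Depth strata (m) of a ChesMMAP-style design.
DEPTH_STRATA = {1: (3.0, 9.1), 2: (9.1, 15.2), 3: (15.2, np.inf)}

#: Prediction-grid cell area, km^2.
DEFAULT_CELL_AREA = 6.25

#: Columns of a haul table.
HAUL_COLUMNS = ("station", "x", "y", "stratum", "year", "month", "species",
                "catch_kg", "swept_km2")


@dataclass(frozen=True)
class BiomassIndex:
    """Area-expanded biomass index (kg) for one region-species-year-month."""

    region: str
    species: str
    year: int
    month: int
    index: float
    se: float | None = None
    flags: tuple[str, ...] = ()


def stratified_index(
    hauls: pd.DataFrame,
    stratum_areas: Mapping[int, float],
    region: str = "",
    species: str = "",
    year: int = 0,
    month: int = 0,
) -> BiomassIndex:
    """Design-based stratified estimate for one region-species-month.

    index = sum_s area_s * mean(catch/swept within s).  The SE follows
    the stratified-sampling variance sum_s area_s^2 * s_s^2 / n_s with
    the (n_s - 1) sample-variance denominator.  Strata with a single
    haul contribute no variance (flag ``var-deficient:<s>``); strata
    with positive area but no hauls contribute zero with a coverage flag.
    """
    if any(a <= 0 for a in stratum_areas.values()):
        raise ValidationError("stratum areas must be positive")
    if (hauls["swept_km2"] <= 0).any():
        raise ValidationError("swept areas must be positive")
    if (hauls["catch_kg"] < 0).any():
        raise ValidationError("catch masses must be non-negative")

    total = 0.0
    var = 0.0
    flags: list[str] = []
    for s, area in sorted(stratum_areas.items()):
        sub = hauls.loc[hauls["stratum"] == s]
        n_s = len(sub)
        if n_s == 0:
            flags.append(f"empty-stratum:{s}")
            logger.warning("stratum %s has positive area but no hauls", s)
            continue
        dens = (sub["catch_kg"] / sub["swept_km2"]).to_numpy(dtype=float)
        total += area * dens.mean()
        if n_s >= 2:
            var += area ** 2 * dens.var(ddof=1) / n_s
        else:
            flags.append(f"var-deficient:{s}")
    return BiomassIndex(region=region, species=species, year=year, month=month,
                        index=float(total), se=float(np.sqrt(var)),
                        flags=tuple(flags))


def make_grid(
    bounds: tuple[float, float, float, float],
    cell_area: float = DEFAULT_CELL_AREA,
) -> np.ndarray:
    """Centroids of square cells of ``cell_area`` tiling a planar bounding box.

    Returns an (m, 2) array of (x, y) in km.  Cells are laid from the
    lower-left corner; partial cells at the upper/right edges are
    dropped, so the covered area is an integer multiple of the cell area.
    """
    x0, y0, x1, y1 = bounds
    side = float(np.sqrt(cell_area))
    xs = np.arange(x0 + side / 2, x1, side)
    xs = xs[xs + side / 2 <= x1 + 1e-9]
    ys = np.arange(y0 + side / 2, y1, side)
    ys = ys[ys + side / 2 <= y1 + 1e-9]
    gx, gy = np.meshgrid(xs, ys)
    return np.column_stack([gx.ravel(), gy.ravel()])


def grid_aggregate(
    surface: Callable[[np.ndarray], np.ndarray],
    cells: np.ndarray,
    cell_area: float = DEFAULT_CELL_AREA,
) -> float:
    """Area-weighted total of a density surface over grid-cell centroids.

    ``surface`` maps an (m, 2) centroid array to densities in kg/km^2;
    the index is ``sum density * cell_area`` (kg).
    """
    cells = np.asarray(cells, dtype=float)
    dens = np.asarray(surface(cells), dtype=float)
    if dens.shape[0] != cells.shape[0]:
        raise ValidationError("surface must return one density per centroid")
    return float(dens.sum() * cell_area)


def index_table(indices: Sequence[BiomassIndex]) -> pd.DataFrame:
    """Flatten BiomassIndex records to the long biomass-index table."""
    return pd.DataFrame([
        {"region": b.region, "year": b.year, "month": b.month,
         "species": b.species, "quantity_kind": "biomass_kg",
         "value": b.index, "se": b.se}
        for b in indices
    ])
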