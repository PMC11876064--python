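"""Dasymetric population mapping and noise-contour rasterization.

Census-block populations are redistributed onto the 30-m cells whose centres
fall inside each block, restricted to non-transportation impervious
(developed) land cover, so that rural blocks do not smear their residents
uniformly over forest and water.  Population mass is conserved exactly: every
block's population ends up on some cell, fractional persons are kept
end-to-end, and rounding happens only when reports are formatted.

Noise-exposure contour polygons (1-dB increments) are rasterized to the same
grid by cell-centre containment, with centres on a shared boundary assigned
to the higher contour (never understating exposure).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry

from .curves import ThresholdSet
from .grids import GridSpec, Raster, require_aligned

logger = logging.getLogger(__name__)

NOISE_METRICS = ("Ldn", "Lnight", "Leq24")


@dataclass(frozen=True)
class CensusBlock:
    block_id: str
    geometry: BaseGeometry
    population: float

    def __post_init__(self) -> None:
        if not self.geometry.is_valid:
            raise ValueError(f"block {self.block_id!r}: invalid geometry")
        if not np.isfinite(self.population) or self.population < 0:
            raise ValueError(f"block {self.block_id!r}: bad population")


@dataclass(frozen=True)
class Region:
    region_id: str
    geometry: BaseGeometry
    kind: str = "county"  # "county" regions are mutually exclusive; "tribal"
                          # regions may overlap counties and are summarised
                          # independently

    def __post_init__(self) -> None:
        if not self.geometry.is_valid:
            raise ValueError(f"region {self.region_id!r}: invalid geometry")


class PopulationRaster(Raster):
    """30-m raster of fractional person counts."""


class NoiseSurface(Raster):
    """30-m raster of one cumulative noise metric (dB)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.metric not in NOISE_METRICS:
            raise ValueError(f"noise surface metric must be one of {NOISE_METRICS}")


# ---------------------------------------------------------------------------
# geometry-on-grid helpers
# ---------------------------------------------------------------------------

def cells_in_geometry(spec: GridSpec, geom: BaseGeometry) -> np.ndarray:
    """Boolean (nrows, ncols) array: cell centre inside/on ``geom``.

    Boundary-touching centres count as inside (``intersects`` semantics).
    """
    X, Y = spec.cell_centers()
    minx, miny, maxx, maxy = geom.bounds
    cand = (X >= minx) & (X <= maxx) & (Y >= miny) & (Y <= maxy)
    out = np.zeros(spec.shape, dtype=bool)
    if cand.any():
        shapely.prepare(geom)
        idx = np.nonzero(cand)
        out[idx] = shapely.intersects_xy(geom, X[idx], Y[idx])
    return out


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def impervious_mask(
    landcover: Raster,
    included_classes: set[int],
    excluded_transport_classes: set[int] = frozenset(),
) -> np.ndarray:
    """Developed, non-transportation cells of a categorical land-cover grid."""
    classes = landcover.values.astype(np.int64)
    inc = np.isin(classes, sorted(included_classes))
    exc = np.isin(classes, sorted(excluded_transport_classes))
    return inc & ~exc & landcover.valid


def distribute_population(
    blocks: list[CensusBlock],
    mask: np.ndarray,
    spec: GridSpec,
) -> PopulationRaster:
    """Dasymetrically distribute block populations over masked cells.

    Each cell is assigned to the block containing its centre (first block in
    ``block_id`` order wins a boundary tie).  A block's population is split
    equally among its masked-true cells; blocks with no masked cell fall back
    to a uniform split over all their cells (logged); blocks containing no
    cell centre at all place their whole population in the cell nearest their
    representative point, so population mass is always conserved.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != spec.shape:
        raise ValueError("mask shape does not match grid spec")
    values = np.zeros(spec.shape, dtype=np.float64)
    assigned = np.zeros(spec.shape, dtype=bool)
    for block in sorted(blocks, key=lambda b: b.block_id):
        if block.geometry.area == 0:
            raise ValueError(f"block {block.block_id!r} has zero area")
        cells = cells_in_geometry(spec, block.geometry) & ~assigned
        assigned |= cells
        target = cells & mask
        if not target.any():
            if cells.any():
                logger.info(
                    "block %s has no impervious cells; uniform fallback over "
                    "%d cells", block.block_id, int(cells.sum()),
                )
                target = cells
            else:
                pt = block.geometry.representative_point()
                rc = spec.index_of(pt.x, pt.y)
                if rc is None:
                    raise ValueError(
                        f"block {block.block_id!r} lies outside the grid"
                    )
                logger.info(
                    "block %s contains no cell centre; population placed in "
                    "cell %s", block.block_id, rc,
                )
                target = np.zeros(spec.shape, dtype=bool)
                target[rc] = True
        values[target] += block.population / target.sum()
    return PopulationRaster(values=values, spec=spec)


def rasterize_contours(
    contours: list[tuple[float, BaseGeometry]],
    spec: GridSpec,
    metric: str = "Ldn",
) -> NoiseSurface:
    """Rasterize nested 1-dB contour polygons to a noise surface.

    Each cell takes the level of the highest-level contour containing its
    centre (lower-bound-inclusive binning); centres on a shared boundary go
    to the higher contour.  Cells outside all contours are nodata.
    """
    values = np.zeros(spec.shape, dtype=np.float64)
    mask = np.ones(spec.shape, dtype=bool)
    for level, geom in sorted(contours, key=lambda lg: lg[0]):
        inside = cells_in_geometry(spec, geom)
        values[inside] = level
        mask[inside] = False
    return NoiseSurface(values=values, spec=spec, mask=mask, metric=metric)


def population_by_level(
    pop: PopulationRaster,
    surface: NoiseSurface,
    bin_width: float = 5.0,
) -> pd.DataFrame:
    """Population per ``[b, b + bin_width)`` dB exposure bin.

    Only cells with a valid noise level are binned; the total over bins equals
    the population over unmasked surface cells regardless of bin width.
    """
    require_aligned(pop, surface)
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    valid = surface.valid
    if not valid.any():
        return pd.DataFrame(columns=["bin_lo_db", "bin_hi_db", "persons"])
    levels = surface.values[valid]
    persons = pop.values[valid]
    lo = np.floor(levels.min() / bin_width) * bin_width
    hi = np.floor(levels.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    which = np.digitize(levels, edges) - 1  # lower-bound inclusive
    sums = np.bincount(which, weights=persons, minlength=len(edges) - 1)
    return pd.DataFrame(
        {"bin_lo_db": edges[:-1], "bin_hi_db": edges[1:], "persons": sums}
    )


def region_masks(
    spec: GridSpec, regions: list[Region]
) -> dict[str, np.ndarray]:
    """Cell-centre membership mask per region (overlaps allowed)."""
    return {r.region_id: cells_in_geometry(spec, r.geometry) for r in regions}


def region_summary(
    pop: PopulationRaster,
    surfaces: dict[str, NoiseSurface],
    regions: list[Region],
    thresholds: ThresholdSet | None = None,
) -> pd.DataFrame:
    """Per-region population at or above each health-risk threshold.

    ``surfaces`` maps metric name (``Ldn``, ``Lnight``, ``Leq24``) to its
    surface; thresholds whose metric is absent yield NaN columns.  Tribal
    regions overlapping counties are summarised independently (no
    de-duplication); the ``Total`` row is computed over the whole raster,
    which equals the sum over the mutually exclusive county regions.
    """
    thresholds = thresholds or ThresholdSet()
    for s in surfaces.values():
        require_aligned(pop, s)
    outcome_defs = [
        ("exposed", "Ldn", thresholds.adverse_ldn),
        ("sleep_risk", "Lnight", thresholds.sleep_lnight),
        ("hearing_risk", "Leq24", thresholds.hearing_leq24),
        ("landuse_incompatible", "Ldn", thresholds.landuse_ldn),
    ]
    masks = region_masks(pop.spec, regions)
    masks["Total"] = np.ones(pop.spec.shape, dtype=bool)
    rows = []
    for region in [*regions, Region("Total", shapely.box(0, 0, 1, 1), "total")]:
        rmask = masks[region.region_id]
        if region.region_id != "Total" and not rmask.any():
            logger.warning(
                "region %s is outside the raster extent", region.region_id
            )
        total_pop = float(pop.values[rmask].sum())
        row = {
            "region_id": region.region_id,
            "kind": region.kind,
            "population": total_pop,
        }
        for name, metric, thr in outcome_defs:
            surf = surfaces.get(metric)
            if surf is None:
                row[name] = np.nan
                row[f"{name}_pct"] = np.nan
                continue
            above = rmask & surf.valid & (surf.values >= thr)
            persons = float(pop.values[above].sum())
            row[name] = persons
            row[f"{name}_pct"] = 100.0 * persons / total_pop if total_pop else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
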