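"""Minimal georeferenced raster container and plain-text raster I/O.

All rasters in this package live on north-up 30-m grids in a projected CRS
(metres).  A :class:`GridSpec` is the usual affine north-up georeference
(top-left corner, square cell); values are row-major numpy arrays with row 0
at the top.  Rasters round-trip through the ESRI ASCII grid format (plain
text) with a small YAML sidecar carrying the metric tag and CRS name.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

NODATA = -9999.0


@dataclass(frozen=True)
class GridSpec:
    """North-up grid georeference: top-left corner, square cells."""

    x0: float            # west edge of the top-left cell
    y0: float            # north edge of the top-left cell
    cell: float          # cell size in metres
    nrows: int
    ncols: int
    crs: str = "local-metres"

    def __post_init__(self) -> None:
        if self.cell <= 0 or self.nrows <= 0 or self.ncols <= 0:
            raise ValueError("cell size and shape must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) coordinate arrays of every cell center, shape (nrows, ncols)."""
        xs = self.x0 + (np.arange(self.ncols) + 0.5) * self.cell
        ys = self.y0 - (np.arange(self.nrows) + 0.5) * self.cell
        return np.meshgrid(xs, ys)

    def index_of(self, x: float, y: float) -> tuple[int, int] | None:
        """(row, col) of the cell containing point (x, y), or None if outside."""
        col = int(np.floor((x - self.x0) / self.cell))
        row = int(np.floor((self.y0 - y) / self.cell))
        if 0 <= row < self.nrows and 0 <= col < self.ncols:
            return (row, col)
        return None

    def compatible_with(self, other: "GridSpec") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.x0, other.x0)
            and np.isclose(self.y0, other.y0)
            and np.isclose(self.cell, other.cell)
            and self.crs == other.crs
        )


def require_aligned(a: "Raster", b: "Raster") -> None:
    if not a.spec.compatible_with(b.spec):
        raise ValueError(
            "rasters are not aligned (transform/shape/CRS mismatch); "
            "reproject or resample explicitly before combining"
        )


@dataclass(frozen=True)
class Raster:
    """A gridded field with an optional nodata mask (True = missing)."""

    values: np.ndarray
    spec: GridSpec
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    metric: str | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64)
        if vals.shape != self.spec.shape:
            raise ValueError("values shape does not match grid spec")
        mask = (
            np.zeros(vals.shape, dtype=bool)
            if self.mask is None
            else np.asarray(self.mask, dtype=bool)
        )
        if mask.shape != vals.shape:
            raise ValueError("mask shape does not match values")
        if not np.all(np.isfinite(vals[~mask])):
            raise ValueError("unmasked raster values must be finite")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "mask", mask)

    @property
    def valid(self) -> np.ndarray:
        return ~self.mask


def write_ascii_grid(raster: Raster, path: str | Path) -> None:
    """Write an ESRI ASCII grid plus a ``<path>.meta.yaml`` sidecar."""
    path = Path(path)
    spec = raster.spec
    vals = np.where(raster.mask, NODATA, raster.values)
    header = (
        f"ncols {spec.ncols}\n"
        f"nrows {spec.nrows}\n"
        f"xllcorner {float(spec.x0)!r}\n"
        f"yllcorner {float(spec.y0 - spec.nrows * spec.cell)!r}\n"
        f"cellsize {float(spec.cell)!r}\n"
        f"NODATA_value {float(NODATA)!r}\n"
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header)
        for row in vals:
            # repr of a Python float is shortest-exact: lossless round-trip
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")
    meta = {"crs": spec.crs, "metric": raster.metric}
    path.with_suffix(path.suffix + ".meta.yaml").write_text(
        yaml.safe_dump(meta, sort_keys=True), encoding="utf-8"
    )


def read_ascii_grid(path: str | Path) -> Raster:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        head = {}
        for _ in range(6):
            key, val = fh.readline().split()
            head[key.lower()] = float(val)
        vals = np.loadtxt(fh, dtype=np.float64, ndmin=2)
    nrows, ncols = int(head["nrows"]), int(head["ncols"])
    if vals.shape != (nrows, ncols):
        raise ValueError(f"{path}: data shape {vals.shape} != header ({nrows},{ncols})")
    meta_path = path.with_suffix(path.suffix + ".meta.yaml")
    meta = (
        yaml.safe_load(meta_path.read_text(encoding="utf-8"))
        if meta_path.exists()
        else {}
    )
    nodata = head.get("nodata_value", NODATA)
    mask = vals == nodata
    spec = GridSpec(
        x0=head["xllcorner"],
        y0=head["yllcorner"] + nrows * head["cellsize"],
        cell=head["cellsize"],
        nrows=nrows,
        ncols=ncols,
        crs=meta.get("crs", "local-metres"),
    )
    return Raster(
        values=np.where(mask, 0.0, vals),
        spec=spec,
        mask=mask,
        metric=meta.get("metric"),
    )
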