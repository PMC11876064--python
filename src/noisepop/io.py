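"""File formats, run configuration and the end-to-end pipeline driver.

Formats are all plain text: SPL and event tables are CSV, geometries are
GeoJSON, rasters are ESRI ASCII grids (see :mod:`noisepop.grids`), and the
run configuration and curve registry are YAML.  Readers fail loudly with the
offending row or feature named; writers round-trip values to 1e-9.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import mapping, shape

from .events import AcousticEvent, DetectionConfig
from .curves import ThresholdSet
from .population import CensusBlock, Region
from .series import SplSeries, SpectrumSeries


# ---------------------------------------------------------------------------
# SPL CSV
# ---------------------------------------------------------------------------

def _iso_to_epoch(value: str, row: int) -> tuple[int, int]:
    """Epoch second and UTC offset (s) of an ISO-8601 timestamp."""
    try:
        dt = datetime.fromisoformat(value)
    except ValueError as exc:
        raise ValueError(f"row {row}: bad timestamp {value!r}: {exc}") from None
    if dt.tzinfo is None:
        dt = dt.replace(tzinfo=timezone.utc)
    offset = int(dt.utcoffset().total_seconds())
    return int(dt.timestamp()), offset


def _epoch_to_iso(ts: int, utc_offset_s: int) -> str:
    tz = timezone(timedelta(seconds=utc_offset_s))
    return datetime.fromtimestamp(ts, tz=tz).isoformat()


def read_spl_csv(
    path: str | Path, location_id: str | None = None
) -> dict[str, SplSeries]:
    """Read an SPL CSV into per-channel series.

    Returns a mapping with key ``"laeq"`` and, when the columns are present,
    ``"lafmax"`` and ``"lcpeak"``.  Timestamps must be strictly increasing;
    the first offending row is named otherwise.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if "timestamp_iso8601" not in df.columns or "laeq_1s" not in df.columns:
        raise ValueError(f"{path}: need columns timestamp_iso8601, laeq_1s")
    parsed = [
        _iso_to_epoch(v, i + 2) for i, v in enumerate(df["timestamp_iso8601"])
    ]
    ts = np.array([p[0] for p in parsed], dtype=np.int64)
    bad = np.nonzero(np.diff(ts) <= 0)[0]
    if bad.size:
        raise ValueError(
            f"{path}: non-increasing timestamp at row {int(bad[0]) + 3}"
        )
    offset = parsed[0][1] if parsed else 0
    loc = location_id or path.stem
    channels = {
        "laeq": ("laeq_1s", "A", "eq_1s"),
        "lafmax": ("lafmax_1s", "A", "fast_max"),
        "lcpeak": ("lcpeak_1s", "C", "peak"),
    }
    out = {}
    for key, (col, fw, tw) in channels.items():
        if col in df.columns:
            out[key] = SplSeries(
                location_id=loc,
                timestamps=ts,
                levels=df[col].to_numpy(dtype=np.float64),
                freq_weighting=fw,
                time_weighting=tw,
                utc_offset_s=offset,
            )
    return out


def write_spl_csv(
    path: str | Path,
    laeq: SplSeries,
    lafmax: SplSeries | None = None,
    lcpeak: SplSeries | None = None,
) -> None:
    data = {
        "timestamp_iso8601": [
            _epoch_to_iso(int(t), laeq.utc_offset_s) for t in laeq.timestamps
        ],
        "laeq_1s": laeq.levels,
    }
    for name, chan in (("lafmax_1s", lafmax), ("lcpeak_1s", lcpeak)):
        if chan is not None:
            if not np.array_equal(chan.timestamps, laeq.timestamps):
                raise ValueError(f"{name} channel timestamps differ from laeq")
            data[name] = chan.levels
    pd.DataFrame(data).to_csv(
        path, index=False, float_format="%.9g", lineterminator="\n"
    )


def read_spectrum_csv(path: str | Path, location_id: str | None = None) -> SpectrumSeries:
    """Spectrum CSV: ``timestamp_iso8601`` plus ``lzeq_<Hz>`` band columns."""
    path = Path(path)
    df = pd.read_csv(path)
    band_cols = [c for c in df.columns if c.startswith("lzeq_")]
    if not band_cols:
        raise ValueError(f"{path}: no lzeq_<Hz> band columns")
    centers = sorted((float(c.split("_", 1)[1]), c) for c in band_cols)
    ts = np.array(
        [_iso_to_epoch(v, i + 2)[0] for i, v in enumerate(df["timestamp_iso8601"])],
        dtype=np.int64,
    )
    return SpectrumSeries(
        location_id=location_id or path.stem,
        timestamps=ts,
        band_centers=np.array([c for c, _ in centers]),
        levels=df[[name for _, name in centers]].to_numpy(dtype=np.float64),
    )


def write_events_csv(
    path: str | Path,
    events: list[AcousticEvent],
    location_id: str,
    utc_offset_s: int = 0,
) -> None:
    rows = [
        {
            "location_id": location_id,
            "start_iso": _epoch_to_iso(e.start, utc_offset_s),
            "end_iso": _epoch_to_iso(e.end, utc_offset_s),
            "duration_s": e.duration_s,
            "le_db": e.le,
            "lmax_db": e.lmax,
            "lfmax_db": "" if e.lfmax is None else e.lfmax,
            "lcpeak_db": "" if e.lcpeak is None else e.lcpeak,
            "onset_rate_db_s": e.onset_rate,
            "threshold_db": e.threshold_at_peak,
        }
        for e in events
    ]
    pd.DataFrame(
        rows,
        columns=[
            "location_id", "start_iso", "end_iso", "duration_s", "le_db",
            "lmax_db", "lfmax_db", "lcpeak_db", "onset_rate_db_s", "threshold_db",
        ],
    ).to_csv(path, index=False, float_format="%.6f", lineterminator="\n")


# ---------------------------------------------------------------------------
# GeoJSON
# ---------------------------------------------------------------------------

def _read_geojson(path: str | Path) -> list[dict]:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    return doc["features"]


def _feature_error(path, i, msg):
    raise ValueError(f"{path}: feature {i}: {msg}")


def read_blocks_geojson(path: str | Path) -> list[CensusBlock]:
    blocks = []
    for i, feat in enumerate(_read_geojson(path)):
        props = feat.get("properties") or {}
        if "block_id" not in props or "population" not in props:
            _feature_error(path, i, "needs block_id and population properties")
        blocks.append(
            CensusBlock(
                block_id=str(props["block_id"]),
                geometry=shape(feat["geometry"]),
                population=float(props["population"]),
            )
        )
    return blocks


def read_regions_geojson(path: str | Path) -> list[Region]:
    regions = []
    for i, feat in enumerate(_read_geojson(path)):
        props = feat.get("properties") or {}
        if "region_id" not in props:
            _feature_error(path, i, "needs a region_id property")
        regions.append(
            Region(
                region_id=str(props["region_id"]),
                geometry=shape(feat["geometry"]),
                kind=str(props.get("kind", "county")),
            )
        )
    return regions


def read_schools_geojson(path: str | Path) -> list[tuple[str, float, float]]:
    schools = []
    for i, feat in enumerate(_read_geojson(path)):
        props = feat.get("properties") or {}
        geom = shape(feat["geometry"])
        if geom.geom_type != "Point":
            _feature_error(path, i, f"expected Point, got {geom.geom_type}")
        schools.append(
            (str(props.get("school_id", f"S{i:02d}")), geom.x, geom.y)
        )
    return schools


def write_geojson(path: str | Path, features: list[tuple[dict, object]]) -> None:
    """Write (properties, shapely geometry) pairs as a FeatureCollection."""
    doc = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "properties": props, "geometry": mapping(geom)}
            for props, geom in features
        ],
    }
    Path(path).write_text(
        json.dumps(doc, sort_keys=True, separators=(",", ":")), encoding="utf-8"
    )


def write_blocks_geojson(path: str | Path, blocks: list[CensusBlock]) -> None:
    write_geojson(
        path,
        [
            ({"block_id": b.block_id, "population": b.population}, b.geometry)
            for b in blocks
        ],
    )


def write_regions_geojson(path: str | Path, regions: list[Region]) -> None:
    write_geojson(
        path,
        [({"region_id": r.region_id, "kind": r.kind}, r.geometry) for r in regions],
    )


def write_schools_geojson(
    path: str | Path, schools: list[tuple[str, float, float]]
) -> None:
    from shapely.geometry import Point

    write_geojson(
        path, [({"school_id": sid}, Point(x, y)) for sid, x, y in schools]
    )


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

_KNOWN_KEYS = {
    "seed", "out_dir", "curves_path", "crs", "thresholds", "detection",
    "synth", "scenario_k",
}
_THRESHOLD_KEYS = {
    "adverse_ldn", "sleep_lnight", "hearing_leq24", "landuse_ldn",
    "school_ldn", "school_near_band_db",
}
_SYNTH_KEYS = {
    "nrows", "ncols", "cell", "n_blocks", "total_population", "ops_per_day",
    "ref_sel_db",
}
_DETECTION_KEYS = {
    "smoothing_window_s", "termination_gap_s", "margin_db",
    "baseline_ambient_db", "l95_window_min", "subdivision_prominence_db",
    "threshold_mode", "smoothing_alignment",
}


@dataclass(frozen=True)
class RunConfig:
    """Validated end-to-end run configuration (unknown keys rejected)."""

    seed: int
    out_dir: str
    curves_path: str | None = None
    crs: str = "local-metres"
    thresholds: ThresholdSet = field(default_factory=ThresholdSet)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    synth: dict = field(default_factory=dict)
    scenario_k: tuple[float, ...] = ()


def _check_keys(section: str, given: dict, allowed: set[str]) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ValueError(f"config section {section!r}: unknown keys {sorted(unknown)}")


def load_run_config(path: str | Path) -> RunConfig:
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: config must be a mapping")
    _check_keys("<root>", doc, _KNOWN_KEYS)
    if "seed" not in doc or "out_dir" not in doc:
        raise ValueError(f"{path}: config requires 'seed' and 'out_dir'")
    thr = doc.get("thresholds", {})
    _check_keys("thresholds", thr, _THRESHOLD_KEYS)
    det = doc.get("detection", {})
    _check_keys("detection", det, _DETECTION_KEYS)
    synth = doc.get("synth", {})
    _check_keys("synth", synth, _SYNTH_KEYS)
    return RunConfig(
        seed=int(doc["seed"]),
        out_dir=str(doc["out_dir"]),
        curves_path=doc.get("curves_path"),
        crs=str(doc.get("crs", "local-metres")),
        thresholds=ThresholdSet(**thr),
        detection=DetectionConfig(**det),
        synth=dict(synth),
        scenario_k=tuple(float(k) for k in doc.get("scenario_k", ())),
    )


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Synthetic end-to-end run: world generation through report rendering.

    Stages run in workflow order (generate inputs, distribute population,
    intersect with noise surfaces, estimate outcomes, sweep scenarios); a
    failure aborts with the stage named.  Outputs are byte-reproducible from
    config + seed.
    """
    from .curves import load_curve_registry
    from .grids import write_ascii_grid
    from .pipeline import build_report
    from .population import distribute_population, impervious_mask
    from .synth import LC_DEVELOPED, LC_TRANSPORT, gen_world

    out_dir = Path(config.out_dir)
    stage = "synthetic world generation"
    try:
        world = gen_world(seed=config.seed, **config.synth)
        stage = "curve registry load"
        curves = load_curve_registry(config.curves_path)
        stage = "dasymetric population distribution"
        mask = impervious_mask(
            world.census.landcover, {LC_DEVELOPED}, {LC_TRANSPORT}
        )
        pop = distribute_population(world.census.blocks, mask, world.spec)
        stage = "impact estimation and reporting"
        paths = build_report(
            out_dir,
            pop,
            world.surfaces,
            world.census.regions,
            curves,
            schools=world.census.schools,
            thresholds=config.thresholds,
            scenario_k=list(config.scenario_k) or None,
            manifest_extra={"seed": config.seed, "crs": config.crs},
        )
        stage = "raster and vector export"
        write_ascii_grid(pop, out_dir / "population.asc")
        for metric, surf in world.surfaces.items():
            write_ascii_grid(surf, out_dir / f"{metric.lower()}.asc")
        write_blocks_geojson(out_dir / "blocks.geojson", world.census.blocks)
        write_regions_geojson(out_dir / "regions.geojson", world.census.regions)
        write_schools_geojson(out_dir / "schools.geojson", world.census.schools)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed during {stage}: {exc}") from exc
    return paths
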