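"""Health-outcome estimation, school impacts and operations-scaling scenarios.

Outcome counts are pure exposure accounting: for each 30-m cell the
exposure-response curve converts the cell's noise level into a percent of
residents affected, the cell's dasymetric population is multiplied by that
percent, and the products are summed per region.  Cells below a curve's
domain contribute zero; cells above it are capped at the domain-top response.

The operations-scaling sweep shifts every noise surface by ``10*log10(k)``
dB, the exact consequence of multiplying every event count by ``k`` under
energy-additive metrics.  This is a demonstrative surrogate for re-running a
full propagation model with a scaled schedule: it preserves the spatial
pattern of the baseline regime while scaling its total energy.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .curves import ERCurve, ThresholdSet, learning_delay, school_year_adjustment
from .grids import require_aligned
from .population import (
    NoiseSurface,
    PopulationRaster,
    Region,
    population_by_level,
    region_masks,
    region_summary,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OutcomeEstimate:
    outcome: str
    region_id: str
    persons: float
    percent_of_region: float
    curve_name: str | None = None


@dataclass(frozen=True)
class SchoolImpact:
    school_id: str
    x: float
    y: float
    ldn: float | None
    adjusted_ldn: float | None
    delay_months: tuple[int, int]
    above_threshold: bool
    near_threshold: bool


@dataclass(frozen=True)
class ScenarioResult:
    scale_factor: float
    db_shift: float
    outcomes: list[OutcomeEstimate]


_METRIC_FOR_OUTCOME = {"annoyance": "Ldn", "sleep_disturbance": "Lnight"}


def _per_region(
    cell_persons: np.ndarray,
    pop: PopulationRaster,
    regions: list[Region],
    outcome: str,
    curve_name: str | None,
) -> list[OutcomeEstimate]:
    masks = region_masks(pop.spec, regions)
    masks["Total"] = np.ones(pop.spec.shape, dtype=bool)
    out = []
    for region_id, rmask in masks.items():
        persons = float(cell_persons[rmask].sum())
        region_pop = float(pop.values[rmask].sum())
        out.append(
            OutcomeEstimate(
                outcome=outcome,
                region_id=region_id,
                persons=persons,
                percent_of_region=100.0 * persons / region_pop if region_pop else 0.0,
                curve_name=curve_name,
            )
        )
    return out


def estimate_outcome(
    pop: PopulationRaster,
    surface: NoiseSurface,
    curve: ERCurve,
    regions: list[Region],
) -> list[OutcomeEstimate]:
    """Persons affected per region under one exposure-response curve."""
    require_aligned(pop, surface)
    expected = _METRIC_FOR_OUTCOME.get(curve.outcome, curve.metric)
    if surface.metric != expected:
        raise ValueError(
            f"curve {curve.name!r} needs a {expected} surface, got {surface.metric}"
        )
    frac = np.zeros(pop.spec.shape)
    v = surface.valid
    frac[v] = curve.response(surface.values[v]) / 100.0
    outcome = (
        "highly_annoyed" if curve.outcome == "annoyance" else "highly_sleep_disturbed"
    )
    return _per_region(frac * pop.values, pop, regions, outcome, curve.name)


def exposed_population(
    pop: PopulationRaster,
    surface: NoiseSurface,
    threshold_db: float,
    regions: list[Region],
    outcome: str = "exposed",
) -> list[OutcomeEstimate]:
    """Population on cells at or above ``threshold_db``, per region."""
    require_aligned(pop, surface)
    above = surface.valid & (surface.values >= threshold_db)
    return _per_region(
        np.where(above, pop.values, 0.0), pop, regions, outcome, None
    )


def hearing_risk(
    pop: PopulationRaster,
    leq24_surface: NoiseSurface,
    regions: list[Region],
    threshold_db: float = 70.0,
) -> list[OutcomeEstimate]:
    """Population exposed above the long-term hearing-impairment level.

    Same accounting as :func:`exposed_population` on the Leq24 surface; acute
    monitoring-location assessment is handled by
    :func:`noisepop.metrics.noise_dose`.
    """
    if leq24_surface.metric != "Leq24":
        raise ValueError("hearing risk requires the Leq24 surface")
    return exposed_population(
        pop, leq24_surface, threshold_db, regions, outcome="hearing_risk"
    )


def school_impacts(
    schools: list[tuple[str, float, float]],
    ldn_surface: NoiseSurface,
    thresholds: ThresholdSet | None = None,
    adjust: bool = False,
    school_days: float = 180,
    flying_days: float = 365,
) -> list[SchoolImpact]:
    """Noise exposure and learning-delay risk at school point locations.

    Exposure is the value of the cell containing each point (no
    interpolation; the surfaces are 1-dB step data).  With ``adjust=True``
    the annual level is converted to a school-year equivalent before the
    delay rule is applied.  Schools outside the raster, or on nodata cells,
    get a warning and ``None`` exposure.
    """
    thresholds = thresholds or ThresholdSet()
    out = []
    for school_id, x, y in schools:
        rc = ldn_surface.spec.index_of(x, y)
        if rc is None or ldn_surface.mask[rc]:
            logger.warning("school %s has no noise-surface coverage", school_id)
            out.append(
                SchoolImpact(school_id, x, y, None, None, (0, 0), False, False)
            )
            continue
        level = float(ldn_surface.values[rc])
        adjusted = (
            school_year_adjustment(level, school_days, flying_days)
            if adjust
            else level
        )
        thr = thresholds.school_ldn
        out.append(
            SchoolImpact(
                school_id=school_id,
                x=x,
                y=y,
                ldn=level,
                adjusted_ldn=adjusted,
                delay_months=learning_delay(adjusted),
                above_threshold=adjusted >= thr,
                near_threshold=thr - thresholds.school_near_band_db
                < adjusted
                < thr,
            )
        )
    return out


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

def scale_surface(surface: NoiseSurface, k: float) -> NoiseSurface:
    """Shift a surface by ``10*log10(k)`` dB (k = operations scale factor)."""
    if k <= 0:
        raise ValueError("scale factor must be positive")
    shift = 10.0 * np.log10(k)
    return replace(surface, values=surface.values + shift)


def scenario_sweep(
    pop: PopulationRaster,
    surfaces: dict[str, NoiseSurface],
    regions: list[Region],
    curves: list[ERCurve],
    k_values: list[float],
    thresholds: ThresholdSet | None = None,
) -> list[ScenarioResult]:
    """Re-run all outcome estimators for each operations scale factor.

    ``k = 1`` reproduces the baseline bit-exactly (the dB shift is 0.0).
    """
    thresholds = thresholds or ThresholdSet()
    results = []
    for k in k_values:
        scaled = {m: scale_surface(s, k) for m, s in surfaces.items()}
        outcomes: list[OutcomeEstimate] = []
        if "Ldn" in scaled:
            outcomes += exposed_population(
                pop, scaled["Ldn"], thresholds.adverse_ldn, regions
            )
            outcomes += exposed_population(
                pop,
                scaled["Ldn"],
                thresholds.landuse_ldn,
                regions,
                outcome="landuse_incompatible",
            )
        if "Leq24" in scaled:
            outcomes += hearing_risk(
                pop, scaled["Leq24"], regions, thresholds.hearing_leq24
            )
        for curve in curves:
            metric = _METRIC_FOR_OUTCOME.get(curve.outcome)
            if metric in scaled:
                outcomes += estimate_outcome(pop, scaled[metric], curve, regions)
        results.append(
            ScenarioResult(
                scale_factor=k,
                db_shift=float(10.0 * np.log10(k)),
                outcomes=outcomes,
            )
        )
    return results


# ---------------------------------------------------------------------------
# report rendering
# ---------------------------------------------------------------------------

def outcomes_frame(outcomes: list[OutcomeEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "outcome": o.outcome,
                "curve": o.curve_name or "",
                "region_id": o.region_id,
                "persons": o.persons,
                "percent_of_region": o.percent_of_region,
            }
            for o in outcomes
        ]
    )


def schools_frame(impacts: list[SchoolImpact]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "school_id": s.school_id,
                "x": s.x,
                "y": s.y,
                "ldn_db": np.nan if s.ldn is None else s.ldn,
                "adjusted_ldn_db": np.nan if s.adjusted_ldn is None else s.adjusted_ldn,
                "delay_months_lo": s.delay_months[0],
                "delay_months_hi": s.delay_months[1],
                "above_threshold": s.above_threshold,
                "near_threshold": s.near_threshold,
            }
            for s in impacts
        ]
    )


def build_report(
    out_dir: str | Path,
    pop: PopulationRaster,
    surfaces: dict[str, NoiseSurface],
    regions: list[Region],
    curves: list[ERCurve],
    schools: list[tuple[str, float, float]] | None = None,
    thresholds: ThresholdSet | None = None,
    scenario_k: list[float] | None = None,
    manifest_extra: dict | None = None,
) -> dict[str, Path]:
    """Render the full deterministic output set.

    Writes the exposure summary, per-curve outcome table, exposure histogram,
    scenario table, school table and a run manifest.  Persons are rounded to
    integers only here, at formatting time.  Reruns with identical inputs are
    byte-identical (the manifest records a content hash, not a timestamp).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    thresholds = thresholds or ThresholdSet()
    paths: dict[str, Path] = {}

    def _write(name: str, df: pd.DataFrame, round_cols: tuple[str, ...] = ()) -> None:
        df = df.copy()
        for col in round_cols:
            if col in df:
                df[col] = df[col].round().astype("Int64")
        path = out_dir / name
        df.to_csv(path, index=False, float_format="%.6g", lineterminator="\n")
        paths[name] = path

    table1 = region_summary(pop, surfaces, regions, thresholds)
    _write(
        "table1_exposure.csv",
        table1,
        round_cols=(
            "population", "exposed", "sleep_risk", "hearing_risk",
            "landuse_incompatible",
        ),
    )

    outcomes: list[OutcomeEstimate] = []
    for curve in curves:
        metric = _METRIC_FOR_OUTCOME.get(curve.outcome)
        if metric in surfaces:
            outcomes += estimate_outcome(pop, surfaces[metric], curve, regions)
    _write("table2_outcomes.csv", outcomes_frame(outcomes), round_cols=("persons",))

    if "Ldn" in surfaces:
        _write("fig6_histogram.csv", population_by_level(pop, surfaces["Ldn"]))

    if scenario_k:
        sweep = scenario_sweep(pop, surfaces, regions, curves, scenario_k, thresholds)
        rows = []
        for res in sweep:
            df = outcomes_frame(res.outcomes)
            df.insert(0, "scale_factor", res.scale_factor)
            df.insert(1, "db_shift", res.db_shift)
            rows.append(df)
        _write("fig7_scenarios.csv", pd.concat(rows, ignore_index=True))

    if schools is not None and "Ldn" in surfaces:
        _write("schools.csv", schools_frame(
            school_impacts(schools, surfaces["Ldn"], thresholds)
        ))

    digest = hashlib.sha256()
    for name in sorted(paths):
        digest.update(paths[name].read_bytes())
    manifest = {
        "thresholds": {
            "adverse_ldn": thresholds.adverse_ldn,
            "sleep_lnight": thresholds.sleep_lnight,
            "hearing_leq24": thresholds.hearing_leq24,
            "landuse_ldn": thresholds.landuse_ldn,
            "school_ldn": thresholds.school_ldn,
        },
        "curves": [c.name for c in curves],
        "scenario_k": scenario_k or [],
        "outputs_sha256": digest.hexdigest(),
    }
    if manifest_extra:
        manifest.update(manifest_extra)
    mpath = out_dir / "manifest.yaml"
    mpath.write_text(yaml.safe_dump(manifest, sort_keys=True), encoding="utf-8")
    paths["manifest.yaml"] = mpath
    return paths
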