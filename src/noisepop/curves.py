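"""Exposure-response curves, health-risk thresholds and the learning-delay rule.

The registry ships seven published curves (five for the percent of a
population highly annoyed as a function of Ldn, two for the percent highly
sleep disturbed as a function of Lnight).  Every curve is validated at load
time: responses must stay within [0, 100] and be nondecreasing over the
declared domain (checked on a 0.1 dB grid).  Outside the domain the paper-
standard capping rule applies: zero below the domain, the domain-top response
above it.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

logger = logging.getLogger(__name__)

_FAMILIES = ("logistic", "polynomial", "polynomial_shifted")
_REQUIRED_KEYS = {"name", "metric", "family", "coefficients", "domain", "source"}


class RegistryError(ValueError):
    """A curve registry failed schema or validity checks."""


@dataclass(frozen=True)
class ERCurve:
    """A named exposure-response function mapping dB to percent affected."""

    name: str
    metric: str                 # metric the pipeline feeds in: Ldn or Lnight
    family: str
    coefficients: tuple[float, ...]
    domain: tuple[float, float]
    source: str = ""
    outcome: str = "annoyance"
    native_metric: str | None = None  # metric the source defined, if different

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise RegistryError(f"curve {self.name!r}: unknown family {self.family!r}")
        lo, hi = self.domain
        if not lo < hi:
            raise RegistryError(f"curve {self.name!r}: empty domain {self.domain}")

    def _raw(self, level: np.ndarray) -> np.ndarray:
        c = np.asarray(self.coefficients)
        if self.family == "logistic":
            a, b = c
            return 100.0 / (1.0 + np.exp(a - b * level))
        if self.family == "polynomial":
            return np.polynomial.polynomial.polyval(level, c)
        # polynomial_shifted: [shift, c1, c2, ...] with no constant term
        x = level - c[0]
        return np.polynomial.polynomial.polyval(x, np.concatenate([[0.0], c[1:]]))

    def response(self, level) -> np.ndarray | float:
        """Percent affected at ``level`` dB, with the cap/zero rule applied."""
        arr = np.asarray(level, dtype=np.float64)
        lo, hi = self.domain
        out = self._raw(np.clip(arr, lo, hi))
        out = np.where(arr < lo, 0.0, out)
        return float(out) if np.isscalar(level) else out

    def validate(self, grid_step: float = 0.1) -> None:
        """Raise :class:`RegistryError` unless bounded in [0,100], nondecreasing."""
        lo, hi = self.domain
        grid = np.arange(lo, hi + grid_step / 2, grid_step)
        resp = self._raw(grid)
        if np.any(resp < -1e-9) or np.any(resp > 100.0 + 1e-9):
            raise RegistryError(
                f"curve {self.name!r}: response leaves [0, 100] on its domain"
            )
        if np.any(np.diff(resp) < -1e-9):
            raise RegistryError(
                f"curve {self.name!r}: response is not nondecreasing on its "
                "domain; re-check the transcribed coefficients"
            )


def response_percent(curve: ERCurve, level: float) -> float:
    """Functional form of :meth:`ERCurve.response` for a scalar level."""
    return float(curve.response(float(level)))


def _parse_entry(entry: dict) -> ERCurve:
    missing = _REQUIRED_KEYS - entry.keys()
    if missing:
        raise RegistryError(
            f"registry entry {entry.get('name', '<unnamed>')!r} missing {sorted(missing)}"
        )
    curve = ERCurve(
        name=str(entry["name"]),
        metric=str(entry["metric"]),
        family=str(entry["family"]),
        coefficients=tuple(float(c) for c in entry["coefficients"]),
        domain=(float(entry["domain"][0]), float(entry["domain"][1])),
        source=str(entry["source"]).strip(),
        outcome=str(entry.get("outcome", "annoyance")),
        native_metric=entry.get("native_metric"),
    )
    curve.validate()
    if curve.native_metric and curve.native_metric != curve.metric:
        logger.info(
            "curve %s is natively %s but will be evaluated on %s "
            "(no evening penalty available)",
            curve.name, curve.native_metric, curve.metric,
        )
    return curve


def load_curve_registry(path: str | Path | None = None) -> list[ERCurve]:
    """Load and validate a YAML curve registry.

    With no path, the registry shipped with the package (FICON, ISO, WHO,
    NES, Yokoshima annoyance; WHO and Smith sleep) is loaded.
    """
    if path is None:
        text = (
            importlib.resources.files("noisepop.data")
            .joinpath("curves.yaml")
            .read_text(encoding="utf-8")
        )
    else:
        text = Path(path).read_text(encoding="utf-8")
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "curves" not in doc:
        raise RegistryError("registry must be a mapping with a 'curves' list")
    curves = [_parse_entry(e) for e in doc["curves"]]
    names = [c.name for c in curves]
    if len(set(names)) != len(names):
        raise RegistryError("duplicate curve names in registry")
    return curves


def get_curve(curves: list[ERCurve], name: str) -> ERCurve:
    for c in curves:
        if c.name == name:
            return c
    raise KeyError(f"no curve named {name!r} in registry")


@dataclass(frozen=True)
class ThresholdSet:
    """Health-risk and land-use dB thresholds (overridable by config)."""

    adverse_ldn: float = 45.0     # WHO adverse-effect threshold (Ldn)
    sleep_lnight: float = 40.0    # WHO sleep-effect threshold (Lnight)
    hearing_leq24: float = 70.0   # long-term hearing-impairment risk (Leq24)
    landuse_ldn: float = 65.0     # residential land-use incompatibility (Ldn)
    school_ldn: float = 55.0      # childhood learning-delay threshold (Ldn)
    school_near_band_db: float = 5.0  # "within 5 dB of threshold" flag band


# ---------------------------------------------------------------------------
# childhood learning
# ---------------------------------------------------------------------------

def learning_delay(level_db: float) -> tuple[int, int]:
    """Reading-age delay range (months) at a school exposed to ``level_db`` Ldn.

    One month at 55 dB, plus 1-2 further months per completed 5 dB increment
    beyond 55 (so 60-63 dB maps to 2-3 months).  Below 55 dB: no delay.
    """
    if not np.isfinite(level_db):
        raise ValueError("level must be finite")
    if level_db < 55.0:
        return (0, 0)
    n = int((level_db - 55.0) // 5.0)
    return (1 + n, 1 + 2 * n)


def school_year_adjustment(
    annual_ldn: float,
    school_days: float = 180,
    flying_days: float = 365,
    mode: str = "concentrate",
) -> float:
    """Convert an average-annual-day Ldn to a school-year equivalent level.

    The annual exposure energy assumes ``flying_days`` of operations; the
    default ``concentrate`` mode attributes it to ``school_days`` of school
    exposure, raising the level by ``10*log10(flying_days/school_days)``
    (+3.07 dB for 180/365).  ``dilute`` applies the opposite sign and
    ``none`` returns the input unchanged; the choice is surfaced in reports.
    """
    if school_days <= 0 or flying_days <= 0:
        raise ValueError("day counts must be positive")
    if school_days > 365:
        raise ValueError("school_days cannot exceed 365")
    shift = 10.0 * np.log10(flying_days / school_days)
    if mode == "concentrate":
        return float(annual_ldn + shift)
    if mode == "dilute":
        return float(annual_ldn - shift)
    if mode == "none":
        return float(annual_ldn)
    raise ValueError(f"unknown school-year adjustment mode {mode!r}")
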