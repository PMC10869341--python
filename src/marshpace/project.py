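"""Sea-level-rise projection curves and threshold-crossing years.

Projected decadal rates of geocentric sea-level (GSL) rise per emissions
scenario are averaged over coastal locations, observed surface-elevation
deficits are converted into rise-rate thresholds (observed rate minus the
deficit at a chosen cross-site percentile), and each scenario curve is
scanned for the first decade whose projected rate reaches each threshold.
When the projected rate exceeds the threshold derived from the p-th
percentile deficit, the corresponding fraction of monitoring sites is in
elevation deficit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

PROJECTION_YEARS = tuple(range(2025, 2151, 10))


@dataclass
class ProjectionCurve:
    """Decadal rise-rate curve for one scenario (central rate and 1σ band)."""

    scenario: str
    years: np.ndarray  # strictly increasing, 10-year steps
    rate: np.ndarray  # mm/yr
    sigma: np.ndarray  # mm/yr, >= 0
    confidence: str = "medium"  # medium | low
    location_id: str | None = None

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.rate = np.asarray(self.rate, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if len(self.years) == 0:
            raise ValueError("empty projection curve")
        steps = np.diff(self.years)
        if len(steps) and not np.all(steps == 10):
            raise ValueError("projection years must increase in 10-year steps")
        if self.rate.shape != self.years.shape or self.sigma.shape != self.years.shape:
            raise ValueError("years, rate and sigma must align")
        if np.any(self.sigma < 0):
            raise ValueError("sigma band must be non-negative")

    def band(self, which: str) -> np.ndarray:
        if which == "central":
            return self.rate
        if which == "upper1sigma":
            return self.rate + self.sigma
        raise ValueError(f"unknown band {which!r}")


@dataclass
class ThresholdSet:
    """Rise-rate thresholds implied by observed deficit percentiles."""

    observed_rate: float  # mm/yr
    thresholds: dict[float, float]  # deficit percentile prob -> threshold mm/yr


def average_locations(curves: list[ProjectionCurve]) -> ProjectionCurve:
    """Unweighted mean rate and sigma over locations sharing one decade grid."""
    if not curves:
        raise ValueError("no curves to average")
    years = curves[0].years
    for c in curves[1:]:
        if not np.array_equal(c.years, years):
            raise ValueError("location curves are not on a common decade grid")
    return ProjectionCurve(
        scenario=curves[0].scenario,
        years=years.copy(),
        rate=np.mean([c.rate for c in curves], axis=0),
        sigma=np.mean([c.sigma for c in curves], axis=0),
        confidence=curves[0].confidence,
    )


def thresholds_from_deficits(
    observed_rate: float, deficit_percentiles: dict[float, float]
) -> ThresholdSet:
    """Convert deficit percentiles into rise-rate thresholds (mm/yr).

    ``threshold_p = observed_rate - deficit_p``: if sea level were rising at
    ``threshold_p`` instead of the observed rate, the fraction ``p`` of
    sites would sit at or below a zero deficit.
    """
    thresholds = {
        p: observed_rate - d for p, d in sorted(deficit_percentiles.items())
    }
    return ThresholdSet(observed_rate=observed_rate, thresholds=thresholds)


def crossing_year(
    curve: ProjectionCurve, threshold: float, band: str = "central"
) -> int | None:
    """First decade whose projected rate reaches ``threshold`` (mm/yr).

    Reported at the curve's native decadal resolution, no interpolation;
    None when the threshold is never reached by the final decade.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    rates = curve.band(band)
    hit = np.nonzero(rates >= threshold)[0]
    return int(curve.years[hit[0]]) if len(hit) else None


def crossing_year_interpolated(
    curve: ProjectionCurve, threshold: float, band: str = "central"
) -> float | None:
    """Linearly interpolated crossing year (off by default in reports)."""
    rates = curve.band(band)
    hit = np.nonzero(rates >= threshold)[0]
    if not len(hit):
        return None
    i = hit[0]
    if i == 0 or rates[i] == rates[i - 1]:
        return float(curve.years[i])
    frac = (threshold - rates[i - 1]) / (rates[i] - rates[i - 1])
    return float(curve.years[i - 1] + frac * (curve.years[i] - curve.years[i - 1]))


def scenario_report(
    curves: list[ProjectionCurve],
    thresholds: ThresholdSet,
    bands: tuple[str, ...] = ("central",),
) -> pd.DataFrame:
    """Crossing year for every (scenario, threshold percentile, band) combination.

    The ``fraction_in_deficit`` column states the share of monitoring sites
    in elevation deficit once the threshold is exceeded.
    """
    if not curves or not thresholds.thresholds:
        raise ValueError("need at least one curve and one threshold")
    rows = []
    for curve in curves:
        for band in bands:
            for prob, thr in thresholds.thresholds.items():
                rows.append(
                    {
                        "scenario": curve.scenario,
                        "confidence": curve.confidence,
                        "band": band,
                        "deficit_percentile": prob,
                        "threshold_mm_yr": thr,
                        "fraction_in_deficit": 1.0 - prob,
                        "crossing_year": crossing_year(curve, thr, band),
                    }
                )
    return pd.DataFrame(rows)
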