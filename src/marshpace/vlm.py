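"""Differential vertical-land-motion (VLM) correction.

A water-level gauge anchored 4–5 m down and an RSET rod driven ~20 m down
subside at different rates whenever compaction occurs between their anchoring
depths.  If both instruments penetrate the compaction-free Pleistocene
basement the differential motion is zero and no correction is applied; if
either floats in Holocene strata, the gauge sinks relative to the rod and
the measured water-level rise overstates what the wetland surface actually
experiences.

The magnitude of that differential motion is uncertain, so it is modelled as
a normal distribution pinned by its 5th and 95th percentiles (1 and 4 mm/yr
by default), assumed constant through the study period.  Corrections are
drawn from this distribution and subtracted draw-by-draw from the water-level
trend ensemble; monthly water-surface elevations are shifted linearly about
the geodetic survey epoch (2014), which raises pre-survey values and lowers
post-survey values by the accumulated motion.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .series import MM_PER_M, LevelSeries
from .stations import StationRecord
from .trends import TrendEnsemble

log = logging.getLogger(__name__)

DEFAULT_P5_MM_YR = 1.0
DEFAULT_P95_MM_YR = 4.0
SURVEY_EPOCH = 2014.0


@dataclass
class VLMCorrectionModel:
    """Normal differential-VLM rate distribution pinned at two percentiles."""

    p5: float  # mm/yr
    p95: float  # mm/yr
    mean: float  # mm/yr
    sd: float  # mm/yr


def requires_correction(station: StationRecord) -> bool:
    """Whether a site needs a differential VLM correction.

    No correction only when *both* instruments reach the Pleistocene
    basement, i.e. both anchoring depths are at least the local
    Holocene–Pleistocene interface depth; if either instrument floats in
    Holocene strata, the correction applies.
    """
    if math.isnan(station.hp_depth):
        raise ValueError(
            f"{station.site_id}: Holocene-Pleistocene interface depth unresolved "
            "(nearest-neighbour fill required upstream)"
        )
    both_anchored = (
        station.rset_depth >= station.hp_depth
        and station.gauge_depth >= station.hp_depth
    )
    return not both_anchored


def fill_hp_depth_nearest(stations: list[StationRecord]) -> list[StationRecord]:
    """Fill missing interface depths from the nearest site with a known one."""
    known = [s for s in stations if not math.isnan(s.hp_depth)]
    if not known:
        raise ValueError("no station has a known Holocene-Pleistocene depth")
    for s in stations:
        if math.isnan(s.hp_depth):
            nearest = min(
                known, key=lambda k: (k.lon - s.lon) ** 2 + (k.lat - s.lat) ** 2
            )
            s.hp_depth = nearest.hp_depth
    return stations


def build_model(
    p5: float = DEFAULT_P5_MM_YR, p95: float = DEFAULT_P95_MM_YR
) -> VLMCorrectionModel:
    """Normal model whose 5th/95th percentiles sit at ``p5``/``p95`` mm/yr.

    By symmetry the mean is the midpoint; the standard deviation is the
    half-spread divided by the standard-normal 95th-percentile deviate.
    """
    if not (np.isfinite(p5) and np.isfinite(p95)):
        raise ValueError("percentile pins must be finite")
    if not p5 < p95:
        raise ValueError(f"need p5 < p95, got {p5} >= {p95}")
    z95 = stats.norm.ppf(0.95)
    mean = 0.5 * (p5 + p95)
    sd = (p95 - p5) / (2.0 * z95)
    return VLMCorrectionModel(p5=p5, p95=p95, mean=mean, sd=sd)


def draw_corrections(
    model: VLMCorrectionModel,
    n_draws: int = 10_000,
    rng: np.random.Generator | int | None = None,
    applicable: bool = True,
) -> np.ndarray:
    """Seeded draws of the correction rate (mm/yr).

    Sites exempt from correction (both instruments in the basement) get
    all-zero draws, so the downstream arithmetic is uniform; the exemption
    is logged.
    """
    if not applicable:
        log.info("site exempt from differential VLM correction; zero draws")
        return np.zeros(n_draws)
    rng = np.random.default_rng(rng)
    return model.mean + model.sd * rng.standard_normal(n_draws)


def correct_trend_ensemble(
    rwl: TrendEnsemble, corrections: np.ndarray
) -> TrendEnsemble:
    """Subtract correction draws from the water-level trend ensemble (cRWL).

    Draw i of the corrected ensemble is draw i of the raw ensemble minus
    correction i; the point rate is reduced by the mean applied correction.
    Negative corrections from the normal tail are retained (the distribution
    is not truncated).
    """
    if rwl.draws is None:
        raise ValueError("trend ensemble has no draws")
    corrections = np.asarray(corrections, dtype=float)
    if corrections.shape != rwl.draws.shape:
        raise ValueError(
            f"draw-count mismatch: {rwl.draws.shape} vs {corrections.shape}"
        )
    return TrendEnsemble(
        site_id=rwl.site_id,
        rate=rwl.rate - float(corrections.mean()),
        intercept=rwl.intercept,
        residual_sd=rwl.residual_sd,
        n_obs=rwl.n_obs,
        p_value=rwl.p_value,
        draws=rwl.draws - corrections,
        residuals=rwl.residuals,
        times=rwl.times,
    )


def correct_elevations(
    series: LevelSeries, vlm_rate_mm_yr: float, survey_epoch: float = SURVEY_EPOCH
) -> LevelSeries:
    """Remove accumulated differential VLM from monthly elevations.

    ``corrected(t) = raw(t) - rate * (t - survey_epoch)`` in decimal years:
    elevations after the survey epoch are lowered by the motion accumulated
    since the survey, elevations before it are raised — one formula covers
    both directions, and the survey epoch itself is a fixed point.
    """
    t = series.times_decimal()
    shift_m = (vlm_rate_mm_yr / MM_PER_M) * (t - survey_epoch)
    return series.with_values(series.values - shift_m)
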