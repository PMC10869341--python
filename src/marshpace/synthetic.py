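"""Synthetic coastal monitoring network with known ground truth.

Emulates the data structure of a CRMS-style wetland monitoring network:
daily water-level series (linear trend + annual seasonal sinusoid + a shared
"ocean" signal common to all sites + monthly AR(1) red noise, with random
daily gaps and occasional whole-month outages), biannual wetland
surface-elevation series (linear trend + white measurement noise), per-site
instrument metadata, a monthly reference geocentric sea-level series that
carries the same shared ocean signal, and decadal projection curves.

Differential vertical land motion is injected as an extra linear term in the
water-level series only — gauges float in compacting Holocene strata while
RSET rods are anchored deep — at sites where at least one instrument misses
the Pleistocene basement, with the true rate drawn from the same 1–4 mm/yr
band the correction model uses.  The generator records every true parameter
and the response category the classification rules assign to the noise-free
system, so parameter- and category-recovery are testable end to end.

All elevations are in metres; all rates in mm/yr.  Identical config and seed
give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import vlm
from .classify import TIDE_CONDITIONS, classify_site
from .seeding import generator
from .series import MM_PER_M, LevelSeries, decimal_years
from .stations import StationRecord
from .project import PROJECTION_YEARS, ProjectionCurve
from .trends import AR1Model, simulate_surrogates

__all__ = [
    "SyntheticConfig",
    "SiteTruth",
    "generate_network",
    "generate_reference_gsl",
    "generate_projection_curves",
    "write_fixtures",
    "DEFAULT_SCENARIOS",
]


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic monitoring network.

    Ranges are (low, high) pairs sampled uniformly per site; a point value is
    expressed as a degenerate pair.  Defaults emulate the conditions of a
    rapidly subsiding, microtidal deltaic coast during a ~13-year window of
    fast sea-level rise: water-level trends spread widely around ~16 mm/yr,
    wetland surface gains around ~7 mm/yr, red-noise monthly residuals, and
    a shared ocean signal strong enough that deseasonalized site series
    correlate with the reference sea-level series at roughly 0.7.
    """

    n_sites: int = 100
    start: str = "2009-01"
    end: str = "2021-12"
    #: water-level trend excluding differential VLM (mm/yr)
    rwl_trend_range: tuple[float, float] = (5.0, 28.0)
    sec_trend_range: tuple[float, float] = (0.0, 14.0)
    #: true differential VLM band for sites needing correction (mm/yr)
    vlm_rate_range: tuple[float, float] = (1.0, 4.0)
    seasonal_amplitude: float = 80.0  # mm
    ar1_phi_range: tuple[float, float] = (0.2, 0.7)
    innovation_sd: float = 30.0  # mm, monthly AR(1) innovations
    shared_signal_weight: float = 0.7
    ocean_signal_sd: float = 55.0  # mm, marginal sd of the shared signal
    ocean_phi: float = 0.5
    gsl_trend: float = 10.7  # mm/yr, reference series trend
    gauge_depth_range: tuple[float, float] = (4.0, 5.0)
    rset_depth_default: float = 20.0
    hp_depth_range: tuple[float, float] = (0.5, 25.0)
    tidal_amplitude_range: tuple[float, float] = (0.1, 0.6)
    organic_fraction_range: tuple[float, float] = (0.05, 0.95)
    water_level_2014_range: tuple[float, float] = (-0.05, 0.25)  # m
    wetland_elev_2014_range: tuple[float, float] = (-0.15, 0.35)  # m
    sec_noise_sd: float = 8.0  # mm, white noise on biannual pin readings
    missingness_rate: float = 0.10  # daily records dropped at random
    month_dropout_rate: float = 0.03  # whole months lost (outages)
    survey_year: int = 2014
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "rwl_trend_range", "sec_trend_range", "vlm_rate_range",
            "ar1_phi_range", "gauge_depth_range", "hp_depth_range",
            "tidal_amplitude_range", "organic_fraction_range",
            "water_level_2014_range", "wetland_elev_2014_range",
        ):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name}: low > high ({lo} > {hi})")
        lo, hi = self.ar1_phi_range
        if not (-1 < lo and hi < 1):
            raise ValueError("ar1_phi_range must lie strictly inside (-1, 1)")
        if not abs(self.ocean_phi) < 1:
            raise ValueError("ocean_phi must lie strictly inside (-1, 1)")
        for name in ("missingness_rate", "month_dropout_rate"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if not 0 <= self.shared_signal_weight <= 1:
            raise ValueError("shared_signal_weight must be in [0, 1]")
        if self.n_sites < 0:
            raise ValueError("n_sites must be >= 0")
        if len(self.months()) < 24:
            raise ValueError(
                "date range shorter than 24 months — too short to deseasonalize"
            )

    def months(self) -> pd.DatetimeIndex:
        return pd.date_range(
            pd.Timestamp(self.start), pd.Timestamp(self.end), freq="MS"
        )

    def days(self) -> pd.DatetimeIndex:
        months = self.months()
        last = months[-1] + pd.offsets.MonthEnd(0)
        return pd.date_range(months[0], last, freq="D")


@dataclass
class SiteTruth:
    """True generating parameters and noise-free classification of one site."""

    site_id: str
    rwl_trend: float  # mm/yr, includes differential VLM
    crwl_trend: float  # mm/yr, differential VLM removed
    sec_trend: float  # mm/yr
    vlm_rate: float  # mm/yr (0 for exempt sites)
    phi: float
    vlm_applicable: bool
    p_rate: float
    p_flood: dict[str, float] = field(default_factory=dict)
    category: dict[str, str] = field(default_factory=dict)


def _uniform(rng: np.random.Generator, pair: tuple[float, float]) -> float:
    lo, hi = pair
    return float(lo) if lo == hi else float(rng.uniform(lo, hi))


def _ar1_path(
    phi: float, innovation_sd_mm: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """One stationary AR(1) path in metres."""
    if innovation_sd_mm == 0.0:
        # keep the stream advancing so toggling noise off does not reshuffle
        rng.standard_normal(n)
        return np.zeros(n)
    path = simulate_surrogates(
        AR1Model(phi=phi, innovation_sd=innovation_sd_mm), n, 1, rng
    )[0]
    return path / MM_PER_M


def _ocean_signal(config: SyntheticConfig) -> np.ndarray:
    """Shared monthly ocean signal (m), keyed only to the master seed."""
    months = config.months()
    rng = generator(config.seed, "ocean")
    innov = config.ocean_signal_sd * math.sqrt(1.0 - config.ocean_phi**2)
    return _ar1_path(config.ocean_phi, innov, len(months), rng)


def _sec_dates(config: SyntheticConfig) -> pd.DatetimeIndex:
    """Biannual measurement dates: the 15th of every sixth month."""
    months = config.months()
    return pd.DatetimeIndex(months[::6]) + pd.Timedelta(days=14)


def _true_flooding(
    config: SyntheticConfig,
    w2014: float,
    crwl: float,
    s2014: float,
    sec: float,
    amplitude: float,
    seasonal_phase: float,
) -> dict[str, float]:
    """Noise-free flooding probabilities and categories per tide condition.

    Evaluates the deterministic skeleton of the site (trend lines plus the
    seasonal cycle, stochastic terms excluded) at the SEC measurement
    occasions, after exact removal of the differential VLM.
    """
    dates = _sec_dates(config)
    t = decimal_years(dates, "daily")
    epoch = float(config.survey_year)
    water = (
        w2014
        + (crwl / MM_PER_M) * (t - epoch)
        + (config.seasonal_amplitude / MM_PER_M)
        * np.sin(2.0 * np.pi * (t - seasonal_phase))
    )
    wetland = s2014 + (sec / MM_PER_M) * (t - epoch)
    offsets = {"low": -amplitude / 2.0, "mean": 0.0, "high": amplitude / 2.0}
    p_flood = {
        cond: float(np.mean(wetland < water + off)) for cond, off in offsets.items()
    }
    return p_flood


def generate_network(
    config: SyntheticConfig,
) -> tuple[
    list[StationRecord],
    dict[str, LevelSeries],
    dict[str, LevelSeries],
    dict[str, SiteTruth],
]:
    """Generate stations, daily water series, biannual SEC series, and truth.

    Returns ``(stations, water_series, sec_series, truths)``, all keyed by
    site id.  Regeneration with the same config and seed is bit-identical.
    """
    months = config.months()
    days = config.days()
    t_day = decimal_years(days, "daily")
    t_sec = decimal_years(_sec_dates(config), "daily")
    month_of_day = (days.year.to_numpy() - months[0].year) * 12 + (
        days.month.to_numpy() - months[0].month
    )
    ocean = _ocean_signal(config)
    epoch = float(config.survey_year)

    stations: list[StationRecord] = []
    water: dict[str, LevelSeries] = {}
    secs: dict[str, LevelSeries] = {}
    truths: dict[str, SiteTruth] = {}

    for i in range(config.n_sites):
        site_id = f"SYN{i:04d}"
        rng = generator(config.seed, "site", site_id)
        station = StationRecord(
            site_id=site_id,
            lon=float(rng.uniform(-94.0, -88.8)),
            lat=float(rng.uniform(28.8, 30.6)),
            rset_depth=config.rset_depth_default,
            gauge_depth=_uniform(rng, config.gauge_depth_range),
            hp_depth=_uniform(rng, config.hp_depth_range),
            survey_year=config.survey_year,
            tidal_amplitude=_uniform(rng, config.tidal_amplitude_range),
            organic_fraction=_uniform(rng, config.organic_fraction_range),
        )
        applicable = vlm.requires_correction(station)

        crwl_trend = _uniform(rng, config.rwl_trend_range)
        vlm_rate = _uniform(rng, config.vlm_rate_range) if applicable else 0.0
        sec_trend = _uniform(rng, config.sec_trend_range)
        phi = _uniform(rng, config.ar1_phi_range)
        phase = float(rng.uniform(0.0, 1.0))
        w2014 = _uniform(rng, config.water_level_2014_range)
        s2014 = _uniform(rng, config.wetland_elev_2014_range)

        noise_m = _ar1_path(phi, config.innovation_sd, len(months), rng)
        monthly_stoch = config.shared_signal_weight * ocean + noise_m

        values = (
            w2014
            + ((crwl_trend + vlm_rate) / MM_PER_M) * (t_day - epoch)
            + (config.seasonal_amplitude / MM_PER_M)
            * np.sin(2.0 * np.pi * (t_day - phase))
            + monthly_stoch[month_of_day]
        )
        values = pd.Series(values, index=days)
        if config.missingness_rate > 0:
            drop = rng.random(len(days)) < config.missingness_rate
            values[drop] = np.nan
        else:
            rng.random(len(days))
        if config.month_dropout_rate > 0:
            gone = rng.random(len(months)) < config.month_dropout_rate
            values[gone[month_of_day]] = np.nan
        else:
            rng.random(len(months))

        sec_noise = rng.standard_normal(len(t_sec)) * (
            config.sec_noise_sd / MM_PER_M
        )
        sec_values = pd.Series(
            s2014 + (sec_trend / MM_PER_M) * (t_sec - epoch) + sec_noise,
            index=_sec_dates(config),
        )

        p_rate = 1.0 if crwl_trend > sec_trend else 0.0
        p_flood = _true_flooding(
            config, w2014, crwl_trend, s2014, sec_trend,
            station.tidal_amplitude, phase,
        )
        truth = SiteTruth(
            site_id=site_id,
            rwl_trend=crwl_trend + vlm_rate,
            crwl_trend=crwl_trend,
            sec_trend=sec_trend,
            vlm_rate=vlm_rate,
            phi=phi,
            vlm_applicable=applicable,
            p_rate=p_rate,
            p_flood=p_flood,
            category={c: classify_site(p_rate, p_flood[c]) for c in TIDE_CONDITIONS},
        )

        stations.append(station)
        water[site_id] = LevelSeries(site_id, "daily", values)
        secs[site_id] = LevelSeries(site_id, "biannual", sec_values)
        truths[site_id] = truth

    return stations, water, secs, truths


def generate_reference_gsl(config: SyntheticConfig) -> LevelSeries:
    """Monthly reference geocentric sea-level series (m).

    Plays the role of a pooled altimetry / corrected tide-gauge record: a
    linear trend (``gsl_trend`` mm/yr) plus the same shared ocean signal that
    is injected into every site's water-level series.  Deterministic under
    the config seed.
    """
    months = config.months()
    t = decimal_years(months, "monthly")
    values = (config.gsl_trend / MM_PER_M) * (
        t - float(config.survey_year)
    ) + _ocean_signal(config)
    return LevelSeries("REFERENCE", "monthly", pd.Series(values, index=months))


#: Decadal rise-rate anchor points per emissions scenario (mm/yr), shaped to
#: emulate published coastal projections: near-stable rates under strong
#: mitigation, a mid-century acceleration through ~7 mm/yr around 2070 under
#: the middle-of-the-road pathway, and a steep climb under high emissions.
DEFAULT_SCENARIOS: dict[str, dict] = {
    "SSP1-2.6": {
        "anchor_years": (2025, 2060, 2100, 2150),
        "anchor_rates": (4.5, 5.5, 5.5, 5.0),
        "sigma": 1.5,
        "confidence": "medium",
    },
    "SSP2-4.5": {
        "anchor_years": (2025, 2050, 2070, 2100, 2150),
        "anchor_rates": (4.8, 6.2, 7.3, 9.0, 10.5),
        "sigma": 2.0,
        "confidence": "medium",
    },
    "SSP3-7.0": {
        "anchor_years": (2025, 2060, 2100, 2150),
        "anchor_rates": (5.0, 7.8, 11.0, 16.0),
        "sigma": 2.5,
        "confidence": "medium",
    },
}


def generate_projection_curves(
    scenario_params: dict[str, dict] | None = None,
    n_locations: int = 16,
    location_spread: float = 0.5,
    seed: int = 0,
) -> list[ProjectionCurve]:
    """Per-location decadal projection curves, 2025–2150.

    Each scenario's anchor points are linearly interpolated onto the decade
    grid; ``n_locations`` perturbed variants are produced whose offsets sum
    to zero at every decade, so their unweighted average reproduces the base
    curve exactly.  Negative sigma bands are rejected.
    """
    scenario_params = scenario_params or DEFAULT_SCENARIOS
    years = np.asarray(PROJECTION_YEARS)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x70726F6A]))
    curves: list[ProjectionCurve] = []
    for scenario, params in scenario_params.items():
        rate = np.interp(years, params["anchor_years"], params["anchor_rates"])
        if "anchor_sigmas" in params:
            sigma = np.interp(years, params["anchor_years"], params["anchor_sigmas"])
        else:
            sigma = np.full_like(rate, float(params.get("sigma", 0.0)))
        if np.any(sigma < 0):
            raise ValueError(f"{scenario}: sigma band must be non-negative")
        delta = rng.normal(0.0, location_spread, size=(n_locations, len(years)))
        delta -= delta.mean(axis=0, keepdims=True)  # exact zero-sum offsets
        for j in range(n_locations):
            curves.append(
                ProjectionCurve(
                    scenario=scenario,
                    years=years,
                    rate=rate + delta[j],
                    sigma=sigma,
                    confidence=params.get("confidence", "medium"),
                    location_id=f"L{j:02d}",
                )
            )
    return curves


def noise_free(config: SyntheticConfig) -> SyntheticConfig:
    """A copy of the config with every stochastic amplitude set to zero.

    The differential VLM band collapses to its centre so that a pipeline run
    in central-rate correction mode removes the injected motion exactly.
    """
    centre = 0.5 * (config.vlm_rate_range[0] + config.vlm_rate_range[1])
    return replace(
        config,
        innovation_sd=0.0,
        seasonal_amplitude=0.0,
        shared_signal_weight=0.0,
        ocean_signal_sd=0.0,
        sec_noise_sd=0.0,
        missingness_rate=0.0,
        month_dropout_rate=0.0,
        vlm_rate_range=(centre, centre),
    )


def write_fixtures(
    stations: list[StationRecord],
    water: dict[str, LevelSeries],
    secs: dict[str, LevelSeries],
    truths: dict[str, SiteTruth],
    directory,
    overwrite: bool = False,
    curves: list[ProjectionCurve] | None = None,
    reference: LevelSeries | None = None,
) -> list:
    """Write the network to CSV/JSON fixtures (see :mod:`marshpace.io`)."""
    from . import io

    return io.write_network(
        stations, water, secs, truths, directory,
        overwrite=overwrite, curves=curves, reference=reference,
    )
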