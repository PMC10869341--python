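"""Plain-text readers and writers for the network fixture formats.

Station table: CSV with one row per site.  Series: one CSV per site and
variable with ISO-8601 timestamps and elevations in metres (missing values
left blank).  Ground truth: JSON.  Projections: long-format CSV with one row
per (scenario, location, decade).  Everything round-trips losslessly through
these functions.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .series import LevelSeries
from .stations import StationRecord
from .project import ProjectionCurve
from .synthetic import SiteTruth

STATION_COLUMNS = [
    "site_id", "lon", "lat", "rset_depth_m", "gauge_depth_m", "hp_depth_m",
    "survey_year", "tidal_amplitude_m", "organic_fraction",
]


def write_station_table(stations: list[StationRecord], path) -> None:
    rows = [
        {
            "site_id": s.site_id,
            "lon": s.lon,
            "lat": s.lat,
            "rset_depth_m": s.rset_depth,
            "gauge_depth_m": s.gauge_depth,
            "hp_depth_m": s.hp_depth,
            "survey_year": s.survey_year,
            "tidal_amplitude_m": s.tidal_amplitude,
            "organic_fraction": s.organic_fraction,
        }
        for s in stations
    ]
    pd.DataFrame(rows, columns=STATION_COLUMNS).to_csv(path, index=False, float_format="%.17g")


def read_station_table(path) -> list[StationRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [
        StationRecord(
            site_id=str(r.site_id),
            lon=float(r.lon),
            lat=float(r.lat),
            rset_depth=float(r.rset_depth_m),
            gauge_depth=float(r.gauge_depth_m),
            hp_depth=float(r.hp_depth_m),
            survey_year=int(r.survey_year),
            tidal_amplitude=float(r.tidal_amplitude_m),
            organic_fraction=float(r.organic_fraction),
        )
        for r in df.itertuples()
    ]


def write_series(series: LevelSeries, path) -> None:
    df = pd.DataFrame(
        {"timestamp": series.values.index, "elevation_m": series.values.to_numpy()}
    )
    if series.completeness is not None:
        df["completeness"] = series.completeness.to_numpy()
    df.to_csv(path, index=False, date_format="%Y-%m-%dT%H:%M:%S", float_format="%.17g")


def read_series(path, site_id: str, cadence: str) -> LevelSeries:
    df = pd.read_csv(path, parse_dates=["timestamp"], float_precision="round_trip")
    values = pd.Series(
        df["elevation_m"].to_numpy(dtype=float),
        index=pd.DatetimeIndex(df["timestamp"]),
    )
    completeness = None
    if "completeness" in df.columns:
        completeness = pd.Series(
            df["completeness"].to_numpy(dtype=float), index=values.index
        )
    return LevelSeries(site_id, cadence, values, completeness)


def write_ground_truth(truths: dict[str, SiteTruth], path) -> None:
    payload = {sid: dataclasses.asdict(t) for sid, t in truths.items()}
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_ground_truth(path) -> dict[str, SiteTruth]:
    payload = json.loads(Path(path).read_text())
    return {sid: SiteTruth(**fields) for sid, fields in payload.items()}


def write_projections(curves: list[ProjectionCurve], path) -> None:
    rows = []
    for c in curves:
        for y, r, s in zip(c.years, c.rate, c.sigma):
            rows.append(
                {
                    "scenario": c.scenario,
                    "location_id": c.location_id or "",
                    "confidence": c.confidence,
                    "year": int(y),
                    "rate_mm_yr": float(r),
                    "sigma_mm_yr": float(s),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_projections(path) -> list[ProjectionCurve]:
    df = pd.read_csv(path, float_precision="round_trip")
    curves = []
    for (scenario, loc), grp in df.groupby(["scenario", "location_id"], dropna=False):
        grp = grp.sort_values("year")
        curves.append(
            ProjectionCurve(
                scenario=str(scenario),
                years=grp["year"].to_numpy(),
                rate=grp["rate_mm_yr"].to_numpy(),
                sigma=grp["sigma_mm_yr"].to_numpy(),
                confidence=str(grp["confidence"].iloc[0]),
                location_id=None if pd.isna(loc) or loc == "" else str(loc),
            )
        )
    return curves


def write_network(
    stations, water, secs, truths, directory, overwrite=False,
    curves=None, reference=None,
) -> list[Path]:
    """Write a full network fixture set; refuses to clobber without overwrite."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    station_path = directory / "stations.csv"
    if station_path.exists() and not overwrite:
        raise FileExistsError(
            f"fixture set already present at {directory} (pass overwrite=True)"
        )
    written: list[Path] = [station_path]
    write_station_table(stations, station_path)
    series_dir = directory / "series"
    series_dir.mkdir(exist_ok=True)
    for sid, ls in water.items():
        p = series_dir / f"rwl_{sid}.csv"
        write_series(ls, p)
        written.append(p)
    for sid, ls in secs.items():
        p = series_dir / f"sec_{sid}.csv"
        write_series(ls, p)
        written.append(p)
    truth_path = directory / "ground_truth.json"
    write_ground_truth(truths, truth_path)
    written.append(truth_path)
    if reference is not None:
        p = directory / "reference_gsl.csv"
        write_series(reference, p)
        written.append(p)
    if curves is not None:
        p = directory / "projections.csv"
        write_projections(curves, p)
        written.append(p)
    return written


def read_network(directory):
    """Read back a fixture set written by :func:`write_network`."""
    directory = Path(directory)
    stations = read_station_table(directory / "stations.csv")
    water, secs = {}, {}
    for s in stations:
        water[s.site_id] = read_series(
            directory / "series" / f"rwl_{s.site_id}.csv", s.site_id, "daily"
        )
        secs[s.site_id] = read_series(
            directory / "series" / f"sec_{s.site_id}.csv", s.site_id, "biannual"
        )
    truth_path = directory / "ground_truth.json"
    truths = read_ground_truth(truth_path) if truth_path.exists() else {}
    return stations, water, secs, truths
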