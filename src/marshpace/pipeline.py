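"""End-to-end orchestration: simulate → prep → trends → VLM → classify → project.

A single :class:`RunConfig` drives the whole analysis with seeded
reproducibility.  Each stage is exposed as a function over in-memory objects
(the CLI wires them to files); :func:`run` composes them and writes every
stage output plus a manifest (config hash, seed, per-stage record counts)
into an output directory when one is given.  Identical config and seed give
byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as cls
from . import prep, project, trends, vlm
from .seeding import generator
from .series import MM_PER_M, LevelSeries
from .stations import StationRecord
from .synthetic import (
    DEFAULT_SCENARIOS,
    SyntheticConfig,
    generate_network,
    generate_projection_curves,
    generate_reference_gsl,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one full analysis run."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    ensemble_size: int = 10_000
    seed: int = 0
    tide_conditions: tuple[str, ...] = ("low", "mean", "high")
    month_threshold: float = prep.MONTH_COMPLETENESS_THRESHOLD
    site_threshold: float = prep.SITE_COMPLETENESS_THRESHOLD
    vlm_p5: float = vlm.DEFAULT_P5_MM_YR
    vlm_p95: float = vlm.DEFAULT_P95_MM_YR
    #: "draws": per-draw corrections subtracted from the trend ensemble;
    #: "central": every draw shifted by the distribution mean (degenerate)
    vlm_mode: str = "draws"
    #: "occasions": flooding over SEC measurement occasions only;
    #: "mc": additionally integrate the VLM-correction elevation uncertainty
    flood_mode: str = "occasions"
    observed_gsl_rate: float | None = None  # mm/yr; default: reference OLS rate
    deficit_probs: tuple[float, ...] = (0.25, 0.50)
    scenarios: dict | None = None
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.ensemble_size < 100:
            raise ValueError("ensemble_size must be >= 100")
        if self.vlm_mode not in ("draws", "central"):
            raise ValueError(f"unknown vlm_mode {self.vlm_mode!r}")
        if self.flood_mode not in ("occasions", "mc"):
            raise ValueError(f"unknown flood_mode {self.flood_mode!r}")
        for c in self.tide_conditions:
            if c not in cls.TIDE_CONDITIONS:
                raise ValueError(f"unknown tide condition {c!r}")


@dataclass
class RunResult:
    """Everything a run produced, stage by stage."""

    config: RunConfig
    stations: dict[str, StationRecord]
    truths: dict
    prep_reports: list[prep.PrepReport]
    rwl_ensembles: dict[str, trends.TrendEnsemble]
    sec_ensembles: dict[str, trends.TrendEnsemble]
    crwl_ensembles: dict[str, trends.TrendEnsemble]
    vlm_report: pd.DataFrame
    classification: pd.DataFrame
    deficit_summary: cls.DeficitSummary
    rate_correlation: dict
    safe_summary: dict[str, dict]
    observed_gsl_rate: float
    thresholds: project.ThresholdSet
    projection_report: pd.DataFrame
    manifest: dict


# ----------------------------------------------------------------- stages
def stage_prep(
    water: dict[str, LevelSeries],
    window: tuple[str, str],
    month_threshold: float,
    site_threshold: float,
) -> tuple[dict[str, LevelSeries], dict[str, LevelSeries], list[prep.PrepReport]]:
    """Monthly QC for every site; returns deseasonalized and raw-monthly maps."""
    deseason: dict[str, LevelSeries] = {}
    raw_monthly: dict[str, LevelSeries] = {}
    reports: list[prep.PrepReport] = []
    for sid, daily in water.items():
        d, r, rep = prep.prepare_monthly(
            daily, window, month_threshold, site_threshold
        )
        reports.append(rep)
        if d is not None:
            deseason[sid] = d
            raw_monthly[sid] = r
    return deseason, raw_monthly, reports


def stage_trends(
    deseason: dict[str, LevelSeries],
    secs: dict[str, LevelSeries],
    ensemble_size: int,
    seed: int,
) -> tuple[dict[str, trends.TrendEnsemble], dict[str, trends.TrendEnsemble]]:
    """Per-site trend ensembles: red noise for water levels, white for SEC."""
    rwl_ens: dict[str, trends.TrendEnsemble] = {}
    sec_ens: dict[str, trends.TrendEnsemble] = {}
    for sid, series in deseason.items():
        ens = trends.ols_trend(series)
        model = trends.fit_ar1(ens.residuals * MM_PER_M)
        rng = generator(seed, "rwl-surrogates", sid)
        surr = trends.simulate_surrogates(model, ens.times.size, ensemble_size, rng)
        ens.p_value = trends.trend_p_value(ens, surr)
        rwl_ens[sid] = trends.trend_ensemble(ens, model, surrogates=surr)
    for sid in deseason:
        series = secs[sid]
        ens = trends.ols_trend(series)
        rng = generator(seed, "sec-surrogates", sid)
        surr = trends.white_noise_surrogates(
            ens.residual_sd, ens.times.size, ensemble_size, rng
        )
        ens.p_value = trends.trend_p_value(ens, surr)
        sec_ens[sid] = trends.trend_ensemble(
            ens, trends.AR1Model(0.0, ens.residual_sd), surrogates=surr
        )
    return rwl_ens, sec_ens


def stage_vlm(
    stations: dict[str, StationRecord],
    rwl_ens: dict[str, trends.TrendEnsemble],
    raw_monthly: dict[str, LevelSeries],
    config: RunConfig,
) -> tuple[
    dict[str, trends.TrendEnsemble],
    dict[str, LevelSeries],
    dict[str, np.ndarray],
    pd.DataFrame,
]:
    """Apply the differential-VLM correction to ensembles and elevations."""
    model = vlm.build_model(config.vlm_p5, config.vlm_p95)
    crwl_ens: dict[str, trends.TrendEnsemble] = {}
    corrected_monthly: dict[str, LevelSeries] = {}
    corrections: dict[str, np.ndarray] = {}
    rows = []
    for sid, ens in rwl_ens.items():
        station = stations[sid]
        applicable = vlm.requires_correction(station)
        rng = generator(config.seed, "vlm", sid)
        if config.vlm_mode == "central" and applicable:
            draws = np.full(config.ensemble_size, model.mean)
        else:
            draws = vlm.draw_corrections(
                model, config.ensemble_size, rng, applicable
            )
        corrections[sid] = draws
        crwl_ens[sid] = vlm.correct_trend_ensemble(ens, draws)
        central = model.mean if applicable else 0.0
        corrected_monthly[sid] = vlm.correct_elevations(
            raw_monthly[sid], central, float(station.survey_year)
        )
        rows.append(
            {
                "site_id": sid,
                "applicable": applicable,
                "rset_depth_m": station.rset_depth,
                "gauge_depth_m": station.gauge_depth,
                "hp_depth_m": station.hp_depth,
                "correction_mean": central,
                "correction_sd": model.sd if applicable else 0.0,
            }
        )
    return crwl_ens, corrected_monthly, corrections, pd.DataFrame(rows)


def stage_classify(
    stations: dict[str, StationRecord],
    crwl_ens: dict[str, trends.TrendEnsemble],
    sec_ens: dict[str, trends.TrendEnsemble],
    secs: dict[str, LevelSeries],
    raw_monthly: dict[str, LevelSeries],
    corrected_monthly: dict[str, LevelSeries],
    corrections: dict[str, np.ndarray],
    config: RunConfig,
) -> tuple[pd.DataFrame, cls.DeficitSummary, dict, dict[str, dict]]:
    """Per-site probabilities, categories, deficits and cross-site summaries."""
    rows = []
    medians = {}
    for sid in crwl_ens:
        station = stations[sid]
        p_rate = cls.p_rate_exceed(crwl_ens[sid], sec_ens[sid])
        wetland = secs[sid].observed()
        row = {
            "site_id": sid,
            "p_rate": p_rate,
            "crwl_rate_mm_yr": crwl_ens[sid].rate,
            "sec_rate_mm_yr": sec_ens[sid].rate,
            "organic_fraction": station.organic_fraction,
        }
        for cond in config.tide_conditions:
            if config.flood_mode == "mc":
                tides_raw = cls.tide_triplet(
                    raw_monthly[sid], station.tidal_amplitude
                )
                p_flood = cls.flooding_probability_mc(
                    wetland, tides_raw, cond, corrections[sid],
                    float(station.survey_year),
                )
            else:
                tides = cls.tide_triplet(
                    corrected_monthly[sid], station.tidal_amplitude
                )
                p_flood = cls.flooding_probability(wetland, tides, cond)
            row[f"p_flood_{cond}"] = p_flood
            row[f"category_{cond}"] = cls.classify_site(p_rate, p_flood)
        deficits = cls.deficit_draws(crwl_ens[sid], sec_ens[sid])
        medians[sid] = float(np.median(deficits))
        row["deficit_median_mm_yr"] = medians[sid]
        rows.append(row)
    table = pd.DataFrame(rows).set_index("site_id", drop=False)
    summary = cls.cross_site_percentiles(
        pd.Series(medians), probs=config.deficit_probs
    )
    try:
        corr = cls.rate_correlation(
            table.rename(
                columns={"crwl_rate_mm_yr": "crwl_rate", "sec_rate_mm_yr": "sec_rate"}
            ),
            rng=generator(config.seed, "rate-correlation"),
        )
    except ValueError as exc:  # too few sites for a trimmed correlation
        log.info("rate correlation skipped: %s", exc)
        corr = {"skipped": str(exc)}
    safe = {}
    for cond in config.tide_conditions:
        classifications = [
            cls.ResponseClassification(
                site_id=r["site_id"],
                p_rate=r["p_rate"],
                p_flood=r[f"p_flood_{cond}"],
                tide_condition=cond,
                category=r[f"category_{cond}"],
            )
            for r in rows
        ]
        safe[cond] = cls.safe_site_summary(
            classifications,
            table["crwl_rate_mm_yr"],
            table["sec_rate_mm_yr"],
        )
    return table, summary, corr, safe


def stage_project(
    config: RunConfig,
    deficit_summary: cls.DeficitSummary,
    observed_rate: float,
) -> tuple[project.ThresholdSet, pd.DataFrame]:
    """Thresholds from observed deficits and scenario crossing years."""
    curves = generate_projection_curves(
        config.scenarios or DEFAULT_SCENARIOS, seed=config.seed
    )
    by_scenario: dict[str, list[project.ProjectionCurve]] = {}
    for c in curves:
        by_scenario.setdefault(c.scenario, []).append(c)
    averaged = [project.average_locations(v) for v in by_scenario.values()]
    thresholds = project.thresholds_from_deficits(
        observed_rate, deficit_summary.percentiles
    )
    report = project.scenario_report(averaged, thresholds)
    return thresholds, report


# ---------------------------------------------------------------- compose
def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run(config: RunConfig) -> RunResult:
    """Execute every stage on a synthetic network and collect the outputs."""
    syn = config.synthetic
    stations_list, water, secs, truths = generate_network(syn)
    stations = {s.site_id: s for s in stations_list}
    reference = generate_reference_gsl(syn)

    window = (syn.start, syn.end)
    deseason, raw_monthly, reports = stage_prep(
        water, window, config.month_threshold, config.site_threshold
    )
    log.info("prep: %d of %d sites pass the completeness screen",
             len(deseason), len(water))
    for sid in list(deseason):
        if not prep.sec_site_passes(secs[sid], window, config.site_threshold):
            log.info("prep: %s dropped by the SEC completeness screen", sid)
            del deseason[sid], raw_monthly[sid]

    rwl_ens, sec_ens = stage_trends(
        deseason, secs, config.ensemble_size, config.seed
    )
    crwl_ens, corrected_monthly, corrections, vlm_report = stage_vlm(
        stations, rwl_ens, raw_monthly, config
    )
    classification, deficit_summary, corr, safe = stage_classify(
        stations, crwl_ens, sec_ens, secs, raw_monthly, corrected_monthly,
        corrections, config,
    )

    if config.observed_gsl_rate is not None:
        observed_rate = config.observed_gsl_rate
    else:
        observed_rate = trends.ols_trend(reference).rate
    thresholds, projection_report = stage_project(
        config, deficit_summary, observed_rate
    )

    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "ensemble_size": config.ensemble_size,
        "n_sites_generated": len(stations),
        "n_sites_passing": len(deseason),
        "n_sites_classified": len(classification),
        "observed_gsl_rate_mm_yr": observed_rate,
    }
    result = RunResult(
        config=config,
        stations=stations,
        truths=truths,
        prep_reports=reports,
        rwl_ensembles=rwl_ens,
        sec_ensembles=sec_ens,
        crwl_ensembles=crwl_ens,
        vlm_report=vlm_report,
        classification=classification,
        deficit_summary=deficit_summary,
        rate_correlation=corr,
        safe_summary=safe,
        observed_gsl_rate=observed_rate,
        thresholds=thresholds,
        projection_report=projection_report,
        manifest=manifest,
    )
    if config.out_dir is not None:
        write_outputs(result, config.out_dir)
    return result


def write_outputs(result: RunResult, out_dir) -> None:
    """Write every stage table plus the manifest to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.classification.to_csv(out / "classification.csv", index=False)
    result.vlm_report.to_csv(out / "vlm_report.csv", index=False)
    result.projection_report.to_csv(out / "projection_report.csv", index=False)
    trend_rows = []
    for sid, ens in result.rwl_ensembles.items():
        trend_rows.append(
            {
                "site_id": sid,
                "variable": "rwl",
                "rate_mm_yr": ens.rate,
                "ensemble_sd_mm_yr": ens.ensemble_sd,
                "p_value": ens.p_value,
                "n_obs": ens.n_obs,
            }
        )
    for sid, ens in result.sec_ensembles.items():
        trend_rows.append(
            {
                "site_id": sid,
                "variable": "sec",
                "rate_mm_yr": ens.rate,
                "ensemble_sd_mm_yr": ens.ensemble_sd,
                "p_value": ens.p_value,
                "n_obs": ens.n_obs,
            }
        )
    pd.DataFrame(trend_rows).to_csv(out / "trends.csv", index=False)
    (out / "prep_report.json").write_text(
        json.dumps([r.to_dict() for r in result.prep_reports], indent=1)
    )
    summary = {
        "manifest": result.manifest,
        "safe_summary": result.safe_summary,
        "rate_correlation": result.rate_correlation,
        "deficit_percentiles_mm_yr": {
            str(k): v for k, v in result.deficit_summary.percentiles.items()
        },
        "observed_gsl_rate_mm_yr": result.observed_gsl_rate,
        "thresholds_mm_yr": {
            str(k): v for k, v in result.thresholds.thresholds.items()
        },
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=1))


def report_text(result: RunResult) -> str:
    """Human-readable run summary: shares, deficits, crossing years."""
    lines = [
        f"sites generated {result.manifest['n_sites_generated']}, "
        f"passing QC {result.manifest['n_sites_passing']}, "
        f"classified {result.manifest['n_sites_classified']}",
        f"observed reference rise rate: "
        f"{result.observed_gsl_rate:.1f} mm/yr",
        "",
    ]
    for cond, summary in result.safe_summary.items():
        lines.append(f"[{cond} tide] category shares (%):")
        for cat, share in summary["category_shares"].items():
            lines.append(f"  {cat:34s} {100 * share:5.1f}")
        lines.append(
            f"  safe {100 * summary['safe_share']:.1f}%"
            f" | give-up {100 * summary['give_up_share']:.1f}%"
        )
    lines.append("")
    lines.append("surface-elevation deficit percentiles (mm/yr):")
    for p, v in result.deficit_summary.percentiles.items():
        lines.append(f"  {100 * p:.0f}th: {v:.1f}")
    lines.append("")
    lines.append("projection threshold crossings:")
    for _, row in result.projection_report.iterrows():
        year = row["crossing_year"]
        year_s = "never (by 2150)" if pd.isna(year) else f"{int(year)}"
        lines.append(
            f"  {row['scenario']:10s} threshold {row['threshold_mm_yr']:5.1f} mm/yr"
            f" ({100 * row['fraction_in_deficit']:.0f}% of sites in deficit)"
            f" -> {year_s}"
        )
    return "\n".join(lines)
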