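"""Wetland response classification and surface-elevation deficit statistics.

Two probabilities decide a site's fate.  The first, ``p_rate``, is the
probability that the corrected water-level (cRWL) rise rate exceeds the
wetland surface-elevation-change (SEC) rate, estimated by pairing the two
Monte Carlo trend ensembles draw-by-draw.  The second, ``p_flood``, is the
fraction of SEC measurement occasions on which the wetland surface sat below
the chosen tide level (monthly mean water level, or mean minus/plus half the
annual tidal amplitude for low/high tide) in the same calendar month.

The (p_rate, p_flood) plane is partitioned into seven categories borrowed
from coral-reef terminology: three give-up flavours (elevation deficit, with
flooding deciding whether drowning is complete, in progress, or merely
projected), two keep-up flavours (rates statistically indistinguishable),
catch-up (gaining on the water while flooded) and speed-up (gaining while
subaerial).  Sites outside the three give-up categories are "safe".

The boundary conventions — ``>= 0.66``, ``< 0.33``, ``>= 0.90``, ``<= 0.10``,
``> 0.50`` — are chosen so the seven rules tile the unit square exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .series import LevelSeries
from .trends import TrendEnsemble

GIVE_UP_COMPLETE = "give-up (drowning complete)"
GIVE_UP_IN_PROGRESS = "give-up (drowning in progress)"
GIVE_UP_PROJECTED = "give-up (drowning projected)"
KEEP_UP_DYNAMIC = "keep-up (dynamic equilibrium)"
KEEP_UP_STABLE = "keep-up (stable equilibrium)"
CATCH_UP = "catch-up"
SPEED_UP = "speed-up"

CATEGORIES = (
    GIVE_UP_COMPLETE,
    GIVE_UP_IN_PROGRESS,
    GIVE_UP_PROJECTED,
    KEEP_UP_DYNAMIC,
    KEEP_UP_STABLE,
    CATCH_UP,
    SPEED_UP,
)
SAFE_CATEGORIES = frozenset(
    {KEEP_UP_DYNAMIC, KEEP_UP_STABLE, CATCH_UP, SPEED_UP}
)
TIDE_CONDITIONS = ("low", "mean", "high")


@dataclass
class ResponseClassification:
    """Per-site classification outcome under one tide condition."""

    site_id: str
    p_rate: float
    p_flood: float
    tide_condition: str
    category: str


def tide_triplet(mean_tide: LevelSeries, tidal_amplitude: float) -> pd.DataFrame:
    """Monthly low/mean/high tide levels from corrected mean water levels.

    Low and high tide bracket the monthly mean by half the annual tidal
    amplitude; the spread of the triplet equals the amplitude every month.
    Returns a DataFrame with columns ``low``, ``mean``, ``high`` (metres).
    """
    if tidal_amplitude < 0:
        raise ValueError("tidal amplitude must be >= 0")
    half = tidal_amplitude / 2.0
    m = mean_tide.values
    return pd.DataFrame({"low": m - half, "mean": m, "high": m + half})


def p_rate_exceed(crwl: TrendEnsemble, sec: TrendEnsemble) -> float:
    """Probability that the cRWL rate exceeds the SEC rate.

    The fraction of index-paired draws with a strictly larger cRWL rate.
    For degenerate identical ensembles every comparison ties and the result
    is 0, not 0.5 — ties are not split.
    """
    if crwl.draws is None or sec.draws is None:
        raise ValueError("both ensembles need draws")
    if crwl.draws.shape != sec.draws.shape:
        raise ValueError("draw-count mismatch between cRWL and SEC ensembles")
    return float(np.mean(crwl.draws > sec.draws))


def flooding_probability(
    wetland_elev: pd.Series, tides: pd.DataFrame, tide_condition: str
) -> float:
    """Fraction of SEC measurement occasions with the wetland below tide level.

    ``wetland_elev`` holds the surveyed wetland surface elevation at each SEC
    measurement date; each occasion is compared against the selected tide
    level of the same calendar month.  Occasions with no matching tide month
    are dropped; at least one overlap is required.
    """
    if tide_condition not in TIDE_CONDITIONS:
        raise ValueError(f"unknown tide condition {tide_condition!r}")
    tide = tides[tide_condition]
    tide_by_month = pd.Series(
        tide.to_numpy(), index=tide.index.to_period("M")
    )
    months = wetland_elev.index.to_period("M")
    matched = tide_by_month.reindex(months)
    valid = matched.notna().to_numpy() & wetland_elev.notna().to_numpy()
    if not valid.any():
        raise ValueError("no SEC measurement month overlaps the tide series")
    flooded = wetland_elev.to_numpy()[valid] < matched.to_numpy()[valid]
    return float(np.mean(flooded))


def flooding_probability_mc(
    wetland_elev: pd.Series,
    tides_raw: pd.DataFrame,
    tide_condition: str,
    corrections_mm_yr: np.ndarray,
    survey_epoch: float = 2014.0,
) -> float:
    """Flooding probability integrating the VLM-correction ensemble.

    As :func:`flooding_probability`, but the tide levels come from the
    *uncorrected* monthly water elevations and each correction draw removes
    its own accumulated motion, so the elevation uncertainty of the
    correction propagates into the flooding estimate.  The result is the
    mean flooded fraction over (draw, occasion) pairs.
    """
    from .series import MM_PER_M, decimal_years

    if tide_condition not in TIDE_CONDITIONS:
        raise ValueError(f"unknown tide condition {tide_condition!r}")
    tide = tides_raw[tide_condition]
    tide_by_month = pd.Series(tide.to_numpy(), index=tide.index.to_period("M"))
    months = wetland_elev.index.to_period("M")
    matched = tide_by_month.reindex(months)
    valid = matched.notna().to_numpy() & wetland_elev.notna().to_numpy()
    if not valid.any():
        raise ValueError("no SEC measurement month overlaps the tide series")
    t = decimal_years(wetland_elev.index, "daily")[valid]
    raw_tide = matched.to_numpy()[valid]
    wet = wetland_elev.to_numpy()[valid]
    c = np.asarray(corrections_mm_yr, dtype=float)[:, None] / MM_PER_M
    tide_draws = raw_tide[None, :] - c * (t - survey_epoch)[None, :]
    return float(np.mean(wet[None, :] < tide_draws))


def classify_site(p_rate: float, p_flood: float) -> str:
    """Map the two probabilities to one of the seven response categories.

    Total on [0,1]^2: the give-up branch takes ``p_rate >= 0.66`` (drowning
    complete when ``p_flood >= 0.90``, projected when ``p_flood <= 0.10``,
    in progress otherwise); the keep-up branch takes ``0.33 <= p_rate <
    0.66`` (dynamic when ``p_flood > 0.10``, stable otherwise); below 0.33
    the site is catch-up when ``p_flood > 0.50`` and speed-up otherwise.
    """
    for name, p in (("p_rate", p_rate), ("p_flood", p_flood)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} outside [0, 1]: {p}")
    if p_rate >= 0.66:
        if p_flood >= 0.90:
            return GIVE_UP_COMPLETE
        if p_flood <= 0.10:
            return GIVE_UP_PROJECTED
        return GIVE_UP_IN_PROGRESS
    if p_rate >= 0.33:
        return KEEP_UP_DYNAMIC if p_flood > 0.10 else KEEP_UP_STABLE
    return CATCH_UP if p_flood > 0.50 else SPEED_UP


def deficit_draws(crwl: TrendEnsemble, sec: TrendEnsemble) -> np.ndarray:
    """Surface-elevation deficit draws, cRWL minus SEC rate (mm/yr).

    Positive draws mean the wetland is losing elevation relative to the
    water surface; negative draws are a surplus.
    """
    if crwl.draws is None or sec.draws is None:
        raise ValueError("both ensembles need draws")
    if crwl.draws.shape != sec.draws.shape:
        raise ValueError("draw-count mismatch")
    return crwl.draws - sec.draws


@dataclass
class DeficitSummary:
    """Cross-site percentiles of per-site central (median-of-draws) deficits."""

    per_site_median: pd.Series  # mm/yr, indexed by site_id
    percentiles: dict[float, float]  # prob -> mm/yr


def cross_site_percentiles(
    per_site_central: pd.Series, probs: tuple[float, ...] = (0.25, 0.50)
) -> DeficitSummary:
    """Empirical percentiles over sites of the central deficit (mm/yr)."""
    if len(per_site_central) < 4:
        raise ValueError("need >= 4 sites for cross-site percentiles")
    values = per_site_central.to_numpy(dtype=float)
    pct = {p: float(np.quantile(values, p)) for p in sorted(probs)}
    return DeficitSummary(per_site_median=per_site_central, percentiles=pct)


def rate_correlation(
    rates: pd.DataFrame,
    trim: tuple[float, float] = (0.025, 0.975),
    organic_threshold: float = 0.30,
    n_perm: int = 10_000,
    rng: np.random.Generator | int | None = None,
) -> dict:
    """Cross-site correlation of cRWL and SEC rates, outliers trimmed.

    Sites whose cRWL rate falls outside the [2.5th, 97.5th] cross-site
    percentile interval are excluded, then the Pearson correlation is
    computed on all remaining sites and on the organic-rich subset
    (``organic_fraction > organic_threshold``).  Significance is a seeded
    permutation test (add-one corrected), appropriate for cross-sectional
    pairs with no serial structure.

    ``rates`` needs columns ``crwl_rate``, ``sec_rate`` and (for the subset)
    ``organic_fraction``.
    """
    lo, hi = np.quantile(rates["crwl_rate"].to_numpy(), trim)
    kept = rates[(rates["crwl_rate"] >= lo) & (rates["crwl_rate"] <= hi)]
    if len(kept) < 10:
        raise ValueError("fewer than 10 sites remain after trimming")
    rng = np.random.default_rng(rng)

    def corr_and_p(df: pd.DataFrame) -> tuple[float, float]:
        x = df["crwl_rate"].to_numpy(dtype=float)
        y = df["sec_rate"].to_numpy(dtype=float)
        r = float(np.corrcoef(x, y)[0, 1])
        xc = (x - x.mean()) / x.std()
        yc = (y - y.mean()) / y.std()
        perms = np.array(
            [abs(np.mean(xc * rng.permutation(yc))) for _ in range(n_perm)]
        )
        k = int(np.sum(perms >= abs(np.mean(xc * yc))))
        return r, (k + 1) / (n_perm + 1)

    r_all, p_all = corr_and_p(kept)
    out = {
        "n_all": len(kept),
        "n_trimmed": len(rates) - len(kept),
        "r_all": r_all,
        "p_all": p_all,
    }
    if "organic_fraction" in kept:
        organic = kept[kept["organic_fraction"] > organic_threshold]
        if len(organic) >= 10:
            r_org, p_org = corr_and_p(organic)
            out.update({"n_organic": len(organic), "r_organic": r_org,
                        "p_organic": p_org})
    return out


def safe_site_summary(
    classifications: list[ResponseClassification],
    crwl_rates: pd.Series,
    sec_rates: pd.Series,
) -> dict:
    """Category shares plus median rates for safe sites versus all sites.

    "Safe" is the complement of the three give-up categories: both keep-up
    flavours, catch-up and speed-up.
    """
    if not classifications:
        raise ValueError("no classifications")
    cats = pd.Series([c.category for c in classifications])
    shares = (cats.value_counts() / len(cats)).reindex(CATEGORIES, fill_value=0.0)
    safe_ids = [c.site_id for c in classifications if c.category in SAFE_CATEGORIES]
    summary = {
        "n_sites": len(classifications),
        "category_shares": shares.to_dict(),
        "safe_share": float(sum(shares[c] for c in SAFE_CATEGORIES)),
        "give_up_share": float(
            sum(shares[c] for c in CATEGORIES if c not in SAFE_CATEGORIES)
        ),
        "median_crwl_all": float(crwl_rates.median()),
        "median_sec_all": float(sec_rates.median()),
    }
    if safe_ids:
        summary["median_crwl_safe"] = float(crwl_rates.loc[safe_ids].median())
        summary["median_sec_safe"] = float(sec_rates.loc[safe_ids].median())
    return summary
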