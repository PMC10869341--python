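"""Quality control and preprocessing of raw level series.

The preprocessing chain for gauge records is: average hourly readings to
daily means, average daily means to monthly means while tracking how many
days of each calendar month were actually observed, blank out months whose
daily completeness is not strictly above 70%, drop whole sites whose monthly
completeness over the study window falls below 70%, and finally remove the
seasonal cycle by subtracting a monthly climatology computed on detrended
data.  Wetland-surface (RSET pin) series are biannual and only pass through
the site-level completeness screen.

Boundary conventions: a month is kept only when its completeness *exceeds*
the threshold (strict ``>``); a site is kept when its monthly completeness is
*at least* the threshold (``>=``) — sites *below* the cut-off are excluded.
Both conventions are deliberate and tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .series import LevelSeries, ols_line

MONTH_COMPLETENESS_THRESHOLD = 0.70
SITE_COMPLETENESS_THRESHOLD = 0.70

_FINER: dict[str, tuple[str, ...]] = {
    "daily": ("hourly",),
    "monthly": ("hourly", "daily"),
}


@dataclass
class MonthlyClimatology:
    """Twelve calendar-month offsets (metres), approximately mean-centred."""

    offsets: np.ndarray  # index 0 = January

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=float)
        if self.offsets.shape != (12,):
            raise ValueError("climatology needs exactly 12 offsets")


def aggregate(series: LevelSeries, target_cadence: str) -> LevelSeries:
    """Average a finer-cadence series into daily or monthly bins.

    Per-bin completeness is the number of source records present divided by
    the number expected for that calendar period (24 hours per day; the true
    day count of each month, leap years included).  Bins with no source data
    are NaN with completeness 0.  The output covers every period between the
    first and last observation, so gaps appear explicitly.
    """
    if target_cadence not in _FINER:
        raise ValueError(f"cannot aggregate to cadence {target_cadence!r}")
    if series.cadence not in _FINER[target_cadence]:
        raise ValueError(
            f"cannot aggregate {series.cadence!r} series to {target_cadence!r}"
        )
    obs = series.observed()
    if obs.empty:
        raise ValueError(f"{series.site_id}: no observations to aggregate")
    freq = "D" if target_cadence == "daily" else "MS"
    grouped = obs.groupby(obs.index.to_period("D" if freq == "D" else "M"))
    mean = grouped.mean()
    count = grouped.size()
    full = pd.period_range(mean.index[0], mean.index[-1], freq=mean.index.freq)
    mean = mean.reindex(full)
    count = count.reindex(full, fill_value=0)
    if target_cadence == "daily":
        expected = 24.0 if series.cadence == "hourly" else 1.0
    else:
        expected = full.days_in_month.astype(float)
        if series.cadence == "hourly":
            expected = expected * 24.0
    completeness = pd.Series(count.to_numpy() / expected, index=full.to_timestamp())
    values = pd.Series(mean.to_numpy(dtype=float), index=full.to_timestamp())
    return LevelSeries(series.site_id, target_cadence, values, completeness)


def apply_month_completeness(
    series: LevelSeries, threshold: float = MONTH_COMPLETENESS_THRESHOLD
) -> LevelSeries:
    """Blank months whose daily completeness does not exceed ``threshold``.

    Strictly greater-than: a month at exactly the threshold is dropped.
    """
    if series.cadence != "monthly" or series.completeness is None:
        raise ValueError("month completeness filter needs a monthly series with completeness")
    keep = series.completeness > threshold
    values = series.values.where(keep)
    completeness = series.completeness.where(keep, 0.0)
    return LevelSeries(series.site_id, "monthly", values, completeness)


def site_passes(
    series: LevelSeries,
    threshold: float = SITE_COMPLETENESS_THRESHOLD,
    window: tuple[str, str] | None = None,
) -> bool:
    """Whether a monthly series clears the site-level completeness screen.

    The fraction of non-missing months over the study window must be at
    least ``threshold`` (sites below it are excluded).  ``window`` is an
    inclusive (start, end) month pair; by default the series' own span.
    """
    if series.cadence != "monthly":
        raise ValueError("site filter operates on monthly series")
    values = series.values
    if window is not None:
        full = pd.date_range(
            pd.Timestamp(window[0]), pd.Timestamp(window[1]), freq="MS"
        )
        values = values.reindex(full)
    if len(values) == 0:
        raise ValueError(f"{series.site_id}: empty study window")
    return bool(values.notna().sum() / len(values) >= threshold)


def detrend(series: LevelSeries) -> LevelSeries:
    """Residuals of the OLS line through the observed values."""
    obs = series.observed()
    if len(obs) < 3:
        raise ValueError(f"{series.site_id}: need >= 3 points to detrend")
    t = np.asarray(
        series.times_decimal()[series.values.notna().to_numpy()], dtype=float
    )
    _, _, resid = ols_line(t, obs.to_numpy())
    out = series.values.copy()
    out[out.notna()] = resid
    return series.with_values(out)


def deseasonalize(series: LevelSeries) -> tuple[LevelSeries, MonthlyClimatology]:
    """Remove the mean seasonal cycle from a monthly series.

    A copy of the series is OLS-detrended, the detrended values are averaged
    per calendar month, and the resulting 12-value climatology (mean-centred)
    is subtracted from the *raw* series — so the long-term trend survives,
    only the repeating seasonal pattern is removed.

    Requires at least 24 months with every calendar month observed at least
    twice, otherwise the monthly means are not meaningful averages.
    """
    if series.cadence != "monthly":
        raise ValueError("deseasonalization operates on monthly series")
    if series.n_present < 24:
        raise ValueError(
            f"{series.site_id}: need >= 24 observed months, have {series.n_present}"
        )
    detrended = detrend(series)
    obs = detrended.observed()
    by_month = obs.groupby(obs.index.month)
    counts = by_month.size().reindex(range(1, 13), fill_value=0)
    missing = counts[counts < 2]
    if len(missing):
        names = ", ".join(
            pd.Timestamp(2000, m, 1).strftime("%B") for m in missing.index
        )
        raise ValueError(
            f"{series.site_id}: calendar month(s) observed fewer than twice: {names}"
        )
    offsets = by_month.mean().reindex(range(1, 13)).to_numpy()
    offsets = offsets - offsets.mean()  # keep the series mean untouched
    clim = MonthlyClimatology(offsets)
    corrected = series.values - offsets[series.values.index.month - 1]
    return series.with_values(corrected), clim


def sec_site_passes(
    series: LevelSeries,
    window: tuple[str, str],
    threshold: float = SITE_COMPLETENESS_THRESHOLD,
) -> bool:
    """Completeness screen for biannual surface-elevation series.

    A site passes when the number of observed measurement occasions is at
    least ``threshold`` times the number of biannual slots in the window.
    """
    months = pd.date_range(pd.Timestamp(window[0]), pd.Timestamp(window[1]), freq="MS")
    expected = len(months[::6])
    if expected == 0:
        raise ValueError("empty study window")
    return bool(series.n_present / expected >= threshold)


@dataclass
class PrepReport:
    """Per-site QC outcome: months kept/dropped and the pass/fail verdict."""

    site_id: str
    months_total: int
    months_kept: int
    months_dropped: int
    passed: bool

    def to_dict(self) -> dict:
        return {
            "site_id": self.site_id,
            "months_total": self.months_total,
            "months_kept": self.months_kept,
            "months_dropped": self.months_dropped,
            "passed": self.passed,
        }


def prepare_monthly(
    daily: LevelSeries,
    window: tuple[str, str] | None = None,
    month_threshold: float = MONTH_COMPLETENESS_THRESHOLD,
    site_threshold: float = SITE_COMPLETENESS_THRESHOLD,
) -> tuple[LevelSeries | None, LevelSeries | None, PrepReport]:
    """Run the full monthly QC chain on a daily gauge series.

    Returns ``(deseasonalized, raw_monthly, report)``; the series are None
    when the site fails the completeness screen.  ``raw_monthly`` retains the
    seasonal cycle and is what elevation-based flooding assessments use.
    """
    monthly = aggregate(daily, "monthly")
    filtered = apply_month_completeness(monthly, month_threshold)
    n_total = len(filtered)
    n_kept = filtered.n_present
    passed = site_passes(filtered, site_threshold, window)
    report = PrepReport(daily.site_id, n_total, n_kept, n_total - n_kept, passed)
    if not passed:
        return None, None, report
    deseason, _ = deseasonalize(filtered)
    return deseason, filtered, report
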