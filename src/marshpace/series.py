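"""Timestamped elevation series on a common geodetic datum.

The package moves water-surface and wetland-surface elevations around as
:class:`LevelSeries` objects: a site id, a cadence, and a pandas Series of
elevations in metres indexed by time.  Missing observations are NaN so that
the completeness bookkeeping of aggregated cadences (days present per month,
months present per study window) survives every transformation.

Elevations are stored in metres throughout; rates are reported in mm/yr only
at the reporting boundary (see :mod:`marshpace.trends`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CADENCES = ("hourly", "daily", "monthly", "biannual")

#: metres per millimetre — conversions happen only at reporting boundaries
MM_PER_M = 1000.0


def decimal_years(index: pd.DatetimeIndex, cadence: str = "daily") -> np.ndarray:
    """Convert timestamps to decimal years.

    Monthly stamps (stored at month start) are placed at mid-month,
    ``year + (month - 0.5)/12``; finer cadences use the exact position of the
    timestamp within its calendar year, honouring leap years.
    """
    index = pd.DatetimeIndex(index)
    if cadence == "monthly":
        return index.year.to_numpy() + (index.month.to_numpy() - 0.5) / 12.0
    year = index.year.to_numpy()
    start = pd.to_datetime({"year": year, "month": 1, "day": 1})
    end = pd.to_datetime({"year": year + 1, "month": 1, "day": 1})
    frac = (index.to_numpy() - start.to_numpy()) / (end.to_numpy() - start.to_numpy())
    return year + frac.astype(float)


@dataclass
class LevelSeries:
    """An elevation time series for one monitoring site.

    Parameters
    ----------
    site_id
        Site identifier (e.g. a CRMS-style station code).
    cadence
        One of ``hourly``, ``daily``, ``monthly``, ``biannual``.
    values
        Elevations in metres, indexed by a strictly increasing
        DatetimeIndex; NaN marks a missing period.
    completeness
        Per-period fraction of expected finer-cadence records present, on
        the same index.  Required downstream for aggregated cadences.
    """

    site_id: str
    cadence: str
    values: pd.Series
    completeness: pd.Series | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.cadence not in CADENCES:
            raise ValueError(f"unknown cadence {self.cadence!r}")
        if not isinstance(self.values.index, pd.DatetimeIndex):
            self.values = pd.Series(
                self.values.to_numpy(dtype=float),
                index=pd.DatetimeIndex(self.values.index),
            )
        if not self.values.index.is_monotonic_increasing or self.values.index.has_duplicates:
            raise ValueError(f"{self.site_id}: times must be strictly increasing")
        vals = self.values.to_numpy(dtype=float)
        if np.any(np.isinf(vals)):
            raise ValueError(f"{self.site_id}: non-finite elevation present")
        self.values = pd.Series(vals, index=self.values.index)
        if self.completeness is not None and not self.completeness.index.equals(
            self.values.index
        ):
            raise ValueError(f"{self.site_id}: completeness index mismatch")

    # ------------------------------------------------------------------
    def __len__(self) -> int:
        return len(self.values)

    @property
    def n_present(self) -> int:
        return int(self.values.notna().sum())

    def times_decimal(self) -> np.ndarray:
        """Observation times as decimal years (mid-month for monthly data)."""
        return decimal_years(self.values.index, self.cadence)

    def observed(self) -> pd.Series:
        """The non-missing part of the series."""
        return self.values.dropna()

    def with_values(self, values: pd.Series) -> "LevelSeries":
        """Copy of this series with replaced values (same site and cadence)."""
        return LevelSeries(self.site_id, self.cadence, values,
                           None if self.completeness is None else self.completeness.copy())


def ols_line(t: np.ndarray, y: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Least-squares line ``y = a + b t`` via the normal equations.

    Time is centred on its mean before solving, which keeps the system well
    conditioned for decimal-year axes; slope and residuals are invariant to
    the shift.  Returns ``(slope, intercept_at_t0, residuals)``.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 points for a line")
    tc = t - t.mean()
    denom = float(np.dot(tc, tc))
    if denom == 0.0:
        raise ValueError("rank-deficient design: all times equal")
    slope = float(np.dot(tc, y - y.mean()) / denom)
    intercept_c = float(y.mean())
    residuals = y - (intercept_c + slope * tc)
    intercept = intercept_c - slope * t.mean()
    return slope, intercept, residuals


def slope_weights(t: np.ndarray) -> np.ndarray:
    """Weights ``w`` such that the OLS slope of ``y`` on ``t`` is ``w @ y``.

    Used to vectorise slope estimation over large surrogate matrices.
    """
    t = np.asarray(t, dtype=float)
    tc = t - t.mean()
    denom = float(np.dot(tc, tc))
    if denom == 0.0:
        raise ValueError("rank-deficient design: all times equal")
    return tc / denom
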