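"""Degree of Functional Coupling (DFC): synchrony of behaviour with the
environmental 24 h rhythm.

Per-minute activity intensity (the summed per-axis SD of each ACC burst)
over a 3-day window is autocorrelated to suppress noise and enhance
rhythmic components, the autocorrelation function is decomposed into
Fourier components at periods T/m (T = 3 days = 4320 min, m = 1..2160, so
periods from 3 days down to 2 min), and the DFC is the share of rhythmic
power carried by components that harmonize with the 24 h day (period p
with p <= 24 h and 24 h / p an integer, i.e. m a multiple of 3).

For the biased sample ACF the correlogram evaluated at these Fourier
frequencies equals the periodogram of the original (mean-removed) series,
which keeps the spectrum non-negative and leak-free for signals with an
integer number of daily cycles.

Two numerator/denominator conventions are implemented:

* ``mode="peaks"`` (default, the classic protocol): only *significant*
  components count — local spectral maxima exceeding mean + 3 SD of the
  spectrum; DFC = significant harmonic power / all significant power.
  A pure 24 h signal gives 1, a non-harmonic (e.g. 31 h) oscillation gives
  0, and white noise fluctuates around the share of harmonic bins (~1/3).
* ``mode="full"``: all components count (harmonic power / total power).
  Under this convention finite-window leakage lets a non-harmonic
  oscillation deposit up to ~20% of its power into harmonic bins, so the
  peak mode is the default.

Sliding 3-day windows step by one day; each DFC is assigned to the first
day of its window.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .acc import MIN_RECORDS_PER_DAY, filter_complete_days

logger = logging.getLogger(__name__)

MINUTES_PER_DAY = 1440
WINDOW_DAYS = 3
WINDOW_MINUTES = WINDOW_DAYS * MINUTES_PER_DAY  # 4320
MAX_INTERPOLATED_GAP_MIN = 10


class DegenerateSeriesError(ValueError):
    """Zero-variance activity series: no rhythm is defined."""


# ---------------------------------------------------------------------------
# activity intensity
# ---------------------------------------------------------------------------

def activity_intensity(burst_table) -> pd.DataFrame:
    """Per-minute activity intensity: sum over x, y, z of the burst's
    sample SD.  Duplicate minutes keep the first burst (with a warning).

    Returns a frame with individual_id, timestamp (minute grid), intensity.
    """
    sds = np.nanstd(burst_table.samples, axis=1, ddof=0)  # (n_bursts, 3)
    intensity = sds.sum(axis=1)
    out = pd.DataFrame({
        "individual_id": burst_table.meta["individual_id"].to_numpy(),
        "timestamp": pd.DatetimeIndex(burst_table.meta["start_timestamp"]).floor("min"),
        "intensity": intensity,
    })
    dup = out.duplicated(subset=["individual_id", "timestamp"], keep="first")
    if dup.any():
        warnings.warn(f"{int(dup.sum())} duplicate minutes; keeping first burst")
        out = out.loc[~dup]
    return out.sort_values(["individual_id", "timestamp"]).reset_index(drop=True)


def fill_small_gaps(series: pd.Series,
                    max_gap: int = MAX_INTERPOLATED_GAP_MIN) -> pd.Series:
    """Linearly interpolate runs of up to ``max_gap`` consecutive missing
    minutes; longer gaps stay NaN (they invalidate the day)."""
    filled = series.interpolate(method="linear", limit=max_gap,
                                limit_area="inside")
    # limit= fills the first max_gap values of *any* gap; undo longer runs
    isna = series.isna()
    if isna.any():
        run_id = (~isna).cumsum()
        run_len = isna.groupby(run_id).transform("sum")
        filled[isna & (run_len > max_gap)] = np.nan
    return filled


# ---------------------------------------------------------------------------
# ACF -> spectrum -> DFC
# ---------------------------------------------------------------------------

def autocorrelate(values) -> np.ndarray:
    """Biased sample autocorrelation at lags 0..N-1, r(0) = 1.

    The window is expected to be a complete 3-day minute series (gaps
    of <= 10 min interpolated beforehand).  Raises
    :class:`DegenerateSeriesError` on zero variance.
    """
    x = np.asarray(values, dtype=float)
    if np.isnan(x).any():
        raise ValueError("series contains missing values; fill or drop first")
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom <= 0:
        raise DegenerateSeriesError("zero-variance activity series")
    n = len(x)
    f = np.fft.rfft(x, 2 * n)
    acov = np.fft.irfft(f * np.conj(f))[:n]
    return acov / denom


def fourier_spectrum(acf) -> tuple[np.ndarray, np.ndarray]:
    """Fractional Fourier power of the ACF at periods T/m, m = 1..N//2.

    The correlogram r(0) + 2 sum r(tau) cos(2 pi m tau / N), clipped at 0
    (for the biased ACF it equals the series' periodogram, non-negative up
    to rounding).  DC is excluded; returns ``(periods_min, fractions)``
    with fractions summing to 1.
    """
    r = np.asarray(acf, dtype=float)
    n = len(r)
    c = r.copy()
    c[1:] *= 2.0
    power = np.clip(np.fft.rfft(c).real, 0.0, None)
    power = power[1:]  # drop DC
    total = power.sum()
    if total <= 0:
        raise DegenerateSeriesError("zero total spectral power")
    m = np.arange(1, len(power) + 1)
    return n / m, power / total


def harmonic_mask(periods_min: np.ndarray,
                  day_minutes: int = MINUTES_PER_DAY) -> np.ndarray:
    """Components that harmonize with the 24 h rhythm: period <= 24 h and
    24 h an integer multiple of the period."""
    ratio = day_minutes / periods_min
    return (periods_min <= day_minutes) & (np.abs(ratio - np.round(ratio)) < 1e-9)


def dfc(periods_min, fractions, mode: str = "peaks",
        significance_sd: float = 3.0) -> float:
    """Degree of Functional Coupling in [0, 1] from a spectrum.

    ``mode="peaks"``: ratio of significant harmonic power to all
    significant power, where significant components are local spectral
    maxima exceeding mean + ``significance_sd`` x SD of the spectrum; 0 if
    nothing is significant.  ``mode="full"``: harmonic share of total
    power.
    """
    p = np.asarray(fractions, dtype=float)
    periods = np.asarray(periods_min, dtype=float)
    harm = harmonic_mask(periods)
    if mode == "full":
        return float(p[harm].sum())
    if mode != "peaks":
        raise ValueError(f"unknown mode {mode!r}")
    thr = p.mean() + significance_sd * p.std()
    local_max = np.zeros(len(p), dtype=bool)
    local_max[1:-1] = (p[1:-1] > p[:-2]) & (p[1:-1] >= p[2:])
    local_max[0] = len(p) > 1 and p[0] > p[1]
    local_max[-1] = len(p) > 1 and p[-1] > p[-2]
    sig = local_max & (p > thr)
    denom = p[sig].sum()
    if denom <= 0:
        return 0.0
    return float(p[sig & harm].sum() / denom)


def dfc_window(values, mode: str = "peaks") -> float:
    """ACF -> spectrum -> DFC for one complete 3-day minute series."""
    periods, fractions = fourier_spectrum(autocorrelate(values))
    return dfc(periods, fractions, mode=mode)


# ---------------------------------------------------------------------------
# sliding windows
# ---------------------------------------------------------------------------

@dataclass
class DfcSeries:
    """One DFC value per complete 3-day window, keyed by the window's
    first day."""

    individual_id: str
    days: list
    values: list

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"individual_id": self.individual_id,
                             "day": self.days, "dfc": self.values})


def sliding_dfc(activity: pd.DataFrame, window_days: int = WINDOW_DAYS,
                mode: str = "peaks",
                min_per_day: int = MIN_RECORDS_PER_DAY) -> pd.DataFrame:
    """Sliding 3-day DFC per individual, stepping one day at a time.

    Days failing the complete-day rule (fewer than ``min_per_day`` minute
    records) invalidate every window containing them.  Remaining in-day
    gaps of <= 10 min are linearly interpolated.  Returns a frame
    individual_id, day, dfc, dfc_arcsine, window_days.
    """
    rows = []
    work = activity.rename(columns={"timestamp": "start_timestamp"})
    complete, _dropped = filter_complete_days(work, min_per_day)
    for ind, grp in complete.groupby("individual_id", sort=True):
        grp = grp.sort_values("start_timestamp")
        days = pd.DatetimeIndex(grp["start_timestamp"]).normalize().unique()
        if len(days) < window_days:
            logger.warning("individual %s has %d complete day(s); "
                           "no %d-day DFC window", ind, len(days), window_days)
            continue
        indexed = grp.set_index("start_timestamp")["intensity"]
        for start in days:
            window = [start + pd.Timedelta(days=k) for k in range(window_days)]
            if not all(w in days for w in window):
                continue
            grid = pd.date_range(start, window[-1] + pd.Timedelta(hours=23, minutes=59),
                                 freq="1min")
            series = fill_small_gaps(indexed.reindex(grid))
            if series.isna().any():
                continue
            try:
                value = dfc_window(series.to_numpy(), mode=mode)
            except DegenerateSeriesError:
                continue
            rows.append({"individual_id": ind, "day": start.date(), "dfc": value,
                         "dfc_arcsine": float(arcsine_transform(value)),
                         "window_days": window_days})
    return pd.DataFrame(rows, columns=["individual_id", "day", "dfc",
                                       "dfc_arcsine", "window_days"])


def arcsine_transform(values):
    """arcsin(sqrt(x)) in radians, for proportions in [0, 1]."""
    x = np.asarray(values, dtype=float)
    if np.any((x < 0) | (x > 1)):
        bad = x[(x < 0) | (x > 1)].flat[0]
        raise ValueError(f"arcsine transform needs values in [0, 1]; got {bad}")
    out = np.arcsin(np.sqrt(x))
    return float(out) if out.ndim == 0 else out
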