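"""Nest-occupancy analysis: canonical nest identities, occupation
intervals with right-censoring, Kaplan-Meier survivorship and log-rank
(Mantel) group comparison.

A day-record within 2 m of an already-known nest of the same individual
is the same nest (the field convention for relocating a nest without
finding a new one).  Maximal runs of consecutive days in one nest become
occupation intervals; runs touching the study boundaries or a tracking
gap are right-censored — their duration is a minimum estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank

NEST_MERGE_RADIUS_M = 2.0
MIN_NESTS_PER_INDIVIDUAL = 5
CENSOR_GAP_DAYS = 1   # any missing survey day splits and censors


def resolve_nest_identity(records: pd.DataFrame,
                          radius_m: float = NEST_MERGE_RADIUS_M) -> pd.DataFrame:
    """Assign canonical nest ids by spatial proximity.

    Records need planar ``east``/``north`` columns.  Walking each
    individual's records in date order, a record within ``radius_m``
    (inclusive) of an already-seen nest of that individual inherits the
    nearest such nest's id; otherwise it founds a new canonical nest at
    its position.  Adds a ``canonical_nest_id`` column.
    """
    out = records.sort_values(["individual_id", "date"], kind="stable").copy()
    canonical = np.empty(len(out), dtype=object)
    for ind, grp in out.groupby("individual_id", sort=False):
        known_pos: list[np.ndarray] = []
        known_ids: list[str] = []
        counter = 0
        for row_pos, (_, row) in enumerate(grp.iterrows()):
            pos = np.array([row["east"], row["north"]])
            if known_pos:
                dists = np.hypot(*(np.array(known_pos) - pos).T)
                nearest = int(np.argmin(dists))
                if dists[nearest] <= radius_m:
                    canonical[out.index.get_loc(grp.index[row_pos])] = known_ids[nearest]
                    continue
            counter += 1
            new_id = f"{ind}_N{counter:03d}"
            known_pos.append(pos)
            known_ids.append(new_id)
            canonical[out.index.get_loc(grp.index[row_pos])] = new_id
    out["canonical_nest_id"] = canonical
    return out.reset_index(drop=True)


def exclude_sparse_individuals(records: pd.DataFrame,
                               min_nests: int = MIN_NESTS_PER_INDIVIDUAL,
                               nest_col: str = "canonical_nest_id"):
    """Drop individuals that occupied fewer than ``min_nests`` distinct
    nests (exactly ``min_nests`` is retained).  Returns
    ``(retained, removed_individuals)``."""
    if records.empty:
        return records.copy(), []
    counts = records.groupby("individual_id")[nest_col].nunique()
    removed = sorted(counts[counts < min_nests].index)
    return records[~records["individual_id"].isin(removed)].copy(), removed


@dataclass
class OccupationInterval:
    individual_id: str
    nest_id: str
    start_date: pd.Timestamp
    duration_days: int
    censored: bool       # right-censored: duration is a minimum estimate


def build_intervals(records: pd.DataFrame, study_start, study_end,
                    nest_col: str = "canonical_nest_id",
                    censor_gap_days: int = CENSOR_GAP_DAYS) -> pd.DataFrame:
    """Occupation intervals from daily records.

    Maximal runs of consecutive observed days in the same nest become
    intervals; a run is right-censored when it touches ``study_start`` or
    ``study_end`` or abuts a tracking gap of >= ``censor_gap_days`` missing
    days (its true duration extends beyond what was observed).  Re-visits
    after an absence form separate intervals.
    """
    study_start = pd.Timestamp(study_start)
    study_end = pd.Timestamp(study_end)
    rows = []
    work = records.sort_values(["individual_id", "date"], kind="stable")
    for ind, grp in work.groupby("individual_id", sort=True):
        dates = pd.DatetimeIndex(grp["date"])
        nests = grp[nest_col].to_numpy()
        run_start = 0
        for i in range(1, len(grp) + 1):
            end_of_run = (
                i == len(grp)
                or nests[i] != nests[i - 1]
                or (dates[i] - dates[i - 1]).days > 1
            )
            if not end_of_run:
                continue
            first, last = dates[run_start], dates[i - 1]
            gap_before = (run_start > 0
                          and (dates[run_start] - dates[run_start - 1]).days - 1
                          >= censor_gap_days)
            gap_after = (i < len(grp)
                         and (dates[i] - dates[i - 1]).days - 1 >= censor_gap_days)
            censored = (first <= study_start or last >= study_end
                        or gap_before or gap_after)
            rows.append({
                "individual_id": ind, "nest_id": nests[i - 1],
                "start_date": first,
                "duration_days": (last - first).days + 1,
                "censored": bool(censored)})
            run_start = i
    return pd.DataFrame(rows, columns=["individual_id", "nest_id", "start_date",
                                       "duration_days", "censored"])


@dataclass
class SurvivalCurve:
    """Product-limit survivorship of nest occupation durations."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    variance: np.ndarray      # Greenwood
    all_censored: bool = False


def km_estimate(intervals: pd.DataFrame) -> SurvivalCurve:
    """Kaplan-Meier estimate over interval durations with right-censoring.

    Exact intervals are events; censored ones only contribute exposure.
    An all-censored input yields the (flat) curve flagged as such.
    """
    if intervals.empty:
        raise ValueError("no intervals")
    durations = intervals["duration_days"].to_numpy()
    observed = (~intervals["censored"]).to_numpy().astype(int)
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=observed)
    table = kmf.event_table.iloc[1:] if 0.0 in kmf.event_table.index \
        else kmf.event_table
    times = table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(times).to_numpy()
    # Greenwood: S(t)^2 * sum_{t_i <= t} d_i / (n_i (n_i - d_i))
    d = table["observed"].to_numpy(dtype=float)
    n = table["at_risk"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        inc = np.where(n > d, d / (n * (n - d)), 0.0)
    variance = surv ** 2 * np.cumsum(inc)
    return SurvivalCurve(times=times, survival=surv,
                         at_risk=n, events=d, variance=variance,
                         all_censored=bool(observed.sum() == 0))


def logrank_test(group_a: pd.DataFrame, group_b: pd.DataFrame):
    """Log-rank (Mantel-Cox) comparison of two interval sets.

    Returns ``(chi_square, p_value)`` with 1 degree of freedom; symmetric
    in the group order.  Raises on an empty group.
    """
    if group_a.empty or group_b.empty:
        raise ValueError("both groups must contain intervals")
    res = _lifelines_logrank(
        group_a["duration_days"], group_b["duration_days"],
        event_observed_A=(~group_a["censored"]).astype(int),
        event_observed_B=(~group_b["censored"]).astype(int))
    return float(res.test_statistic), float(res.p_value)


def next_day_reuse(records: pd.DataFrame, by=None,
                   nest_col: str = "canonical_nest_id"):
    """Probability of using the same nest on the next observed day.

    Over all consecutive day-pairs (exactly one day apart) within an
    individual, the fraction with the same nest on both days.  ``by``
    (e.g. ``["sex", "treatment"]``) splits the estimate per group; fewer
    than one usable pair gives NaN.
    """
    work = records.sort_values(["individual_id", "date"], kind="stable").copy()
    if nest_col not in work.columns:
        nest_col = "nest_id"
    grp = work.groupby("individual_id")
    next_date = grp["date"].shift(-1)
    next_nest = grp[nest_col].shift(-1)
    usable = (next_date - work["date"]).dt.days == 1
    same = work[nest_col] == next_nest
    work["_usable"], work["_same"] = usable, same & usable
    if by is None:
        n = int(work["_usable"].sum())
        return float(work["_same"].sum() / n) if n else float("nan")
    out = work.groupby(by)[["_usable", "_same"]].sum()
    return (out["_same"] / out["_usable"].where(out["_usable"] > 0)).rename("reuse_prob")
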