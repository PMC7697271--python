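"""Turning-angle distributions and the permutation Kolmogorov-Smirnov
comparison between treatment groups.

Absolute turning angles (the unsigned angle between successive movement
headings, in [0, pi]) summarise how tortuous a night's path is.  Because
thousands of autocorrelated angles per group would make a single KS test
anti-conservative, groups are compared by repeatedly subsampling a fixed
number of angles from each group and applying the two-sample two-sided KS
test, 1000 times; the fraction of significant draws and the median p-value
summarise the comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def turning_angles(points) -> np.ndarray:
    """Absolute turning angles of a time-sorted planar path.

    For each interior position the angle between the incoming and outgoing
    heading vectors is returned in [0, pi]; zero-length steps are skipped
    (they define no heading).  Fewer than 3 effective positions give an
    empty array.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    steps = np.diff(pts, axis=0)
    lengths = np.hypot(steps[:, 0], steps[:, 1])
    steps = steps[lengths > 0]
    if len(steps) < 2:
        return np.empty(0)
    headings = np.arctan2(steps[:, 1], steps[:, 0])
    turns = np.diff(headings)
    turns = np.abs((turns + np.pi) % (2 * np.pi) - np.pi)
    return turns


def turning_angle_table(records: pd.DataFrame) -> pd.DataFrame:
    """Per individual-night turning angles from preprocessed records.

    Returns a long frame: individual_id, night_id, angle (radians), plus
    sex/treatment when present.
    """
    rows = []
    clean = records.dropna(subset=["night_id"])
    for (ind, night), grp in clean.groupby(["individual_id", "night_id"], sort=True):
        grp = grp.sort_values("timestamp", kind="stable")
        angles = turning_angles(grp[["east", "north"]].to_numpy())
        if len(angles) == 0:
            continue
        row = {"individual_id": ind, "night_id": night}
        for extra in ("sex", "treatment"):
            if extra in grp.columns:
                row[extra] = grp[extra].iloc[0]
        for a in angles:
            rows.append({**row, "angle": a})
    return pd.DataFrame(rows)


@dataclass
class PermKsResult:
    """Aggregate of the repeated subsampled KS comparisons."""

    n_iterations: int
    subsample_size: int
    ks_stats: np.ndarray
    p_values: np.ndarray
    alpha: float = 0.05

    @property
    def fraction_significant(self) -> float:
        return float(np.mean(self.p_values < self.alpha))

    @property
    def median_p(self) -> float:
        return float(np.median(self.p_values))


def permutation_ks(sample_a, sample_b, n_iterations: int = 1000,
                   subsample_size: int = 200, seed: int | None = None,
                   mode: str = "subsample", alpha: float = 0.05) -> PermKsResult:
    """Repeated two-sample two-sided KS comparison of two angle samples.

    ``mode="subsample"`` (default): each iteration draws ``subsample_size``
    angles without replacement from each group independently and tests
    them.  ``mode="permute"``: each iteration shuffles the pooled angles
    into two pseudo-groups of ``subsample_size`` (a label-permutation
    null).  Asymptotic KS p-values are used (subsamples of 200 make exact
    computation unnecessary).  If a group is smaller than
    ``subsample_size`` the size is reduced to the smaller group with a
    warning.  Seeded and reproducible.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    size = subsample_size
    if min(len(a), len(b)) < size:
        import warnings

        size = min(len(a), len(b))
        warnings.warn(f"subsample size reduced to {size} (smallest group)")
    rng = np.random.default_rng(seed)
    stats_out = np.empty(n_iterations)
    ps = np.empty(n_iterations)
    pooled = np.concatenate([a, b])
    for i in range(n_iterations):
        if mode == "subsample":
            xa = rng.choice(a, size=size, replace=False)
            xb = rng.choice(b, size=size, replace=False)
        elif mode == "permute":
            perm = rng.permutation(pooled)
            xa, xb = perm[:size], perm[size:2 * size]
        else:
            raise ValueError(f"unknown mode {mode!r}")
        res = stats.ks_2samp(xa, xb, alternative="two-sided", method="asymp")
        stats_out[i] = res.statistic
        ps[i] = res.pvalue
    return PermKsResult(n_iterations=n_iterations, subsample_size=size,
                        ks_stats=stats_out, p_values=ps, alpha=alpha)
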