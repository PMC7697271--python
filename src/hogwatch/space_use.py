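"""Nightly space-use metrics: MCP95, kernel core areas, path length,
search intensity and home-range centroids.

All functions operate on planar coordinates in metres (see
:func:`hogwatch.telemetry_io.project_to_plane`).  Areas are returned in
hectares (1 ha = 10 000 m2).  A night needs at least
:data:`MIN_POSITIONS_PER_NIGHT` positions to contribute any area metric;
sparser nights are excluded and logged by the summary builder.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, box
from shapely.ops import unary_union

logger = logging.getLogger(__name__)

M2_PER_HA = 10_000.0
MIN_POSITIONS_PER_NIGHT = 5


class InsufficientPositionsError(ValueError):
    """Fewer positions than the minimum required for an area metric."""


class DegenerateInputError(ValueError):
    """Zero spatial variance where spread is required (KDE bandwidth)."""


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of east/north metres")
    return pts


# ---------------------------------------------------------------------------
# minimum convex polygon
# ---------------------------------------------------------------------------

def mcp_area(points, percentile: float = 95.0):
    """Percentile minimum convex polygon.

    The classical peeling convention: compute the arithmetic-mean centroid,
    keep the ``ceil(percentile/100 * n)`` points nearest to it (ties broken
    by input order), and return the convex hull of the retained set.

    Returns ``(polygon, area_ha)``.  Degenerate hulls (collinear points)
    yield area 0.  Raises :class:`InsufficientPositionsError` below
    :data:`MIN_POSITIONS_PER_NIGHT` points.
    """
    pts = _as_points(points)
    n = len(pts)
    if n < MIN_POSITIONS_PER_NIGHT:
        raise InsufficientPositionsError(
            f"MCP needs >= {MIN_POSITIONS_PER_NIGHT} positions, got {n}"
        )
    centroid = pts.mean(axis=0)
    dist = np.hypot(*(pts - centroid).T)
    m = math.ceil(percentile / 100.0 * n)
    keep = np.argsort(dist, kind="stable")[:m]
    hull = MultiPoint(pts[keep]).convex_hull
    return hull, hull.area / M2_PER_HA


# ---------------------------------------------------------------------------
# kernel density core area
# ---------------------------------------------------------------------------

def href_bandwidth(points) -> float:
    """Ad hoc reference bandwidth: sigma * n^(-1/6), with sigma the pooled
    per-axis standard deviation sqrt((var_east + var_north) / 2)."""
    pts = _as_points(points)
    var = pts.var(axis=0, ddof=1)
    sigma = math.sqrt((var[0] + var[1]) / 2.0)
    if sigma <= 0:
        raise DegenerateInputError("zero coordinate variance; href undefined")
    return sigma * len(pts) ** (-1.0 / 6.0)


def kde_home_range(points, isopleth: float = 50.0, bandwidth: float | None = None,
                   grid_size: int = 200, pad_factor: float = 3.0,
                   build_polygon: bool = False):
    """Kernel-density home range by the volume (cumulative-cell) method.

    An isotropic Gaussian kernel of bandwidth ``h`` (default href) is
    evaluated on a ``grid_size`` x ``grid_size`` grid covering the data
    bounding box padded by ``pad_factor * h``.  The isopleth region is the
    smallest set of cells whose summed density reaches ``isopleth`` percent
    of the total; its area is cell count x cell area.

    Returns ``(polygon_or_None, area_ha)``; the polygon (a union of grid
    cells) is built only when ``build_polygon`` is true.
    """
    pts = _as_points(points)
    if len(pts) < MIN_POSITIONS_PER_NIGHT:
        raise InsufficientPositionsError(
            f"KDE needs >= {MIN_POSITIONS_PER_NIGHT} positions, got {len(pts)}"
        )
    h = href_bandwidth(pts) if bandwidth is None else float(bandwidth)
    if h <= 0:
        raise DegenerateInputError("bandwidth must be positive")

    pad = pad_factor * h
    x0, y0 = pts.min(axis=0) - pad
    x1, y1 = pts.max(axis=0) + pad
    xs = np.linspace(x0, x1, grid_size)
    ys = np.linspace(y0, y1, grid_size)
    cell_area = (xs[1] - xs[0]) * (ys[1] - ys[0])

    gx, gy = np.meshgrid(xs, ys)
    # isotropic Gaussian KDE evaluated cell-by-cell; n and grid are small
    dx = gx.ravel()[:, None] - pts[:, 0][None, :]
    dy = gy.ravel()[:, None] - pts[:, 1][None, :]
    dens = np.exp(-(dx * dx + dy * dy) / (2.0 * h * h)).sum(axis=1)

    total = dens.sum()
    if total <= 0:
        raise DegenerateInputError("zero total density")
    order = np.argsort(dens)[::-1]
    cum = np.cumsum(dens[order])
    n_cells = int(np.searchsorted(cum, isopleth / 100.0 * total) + 1)
    n_cells = min(n_cells, dens.size)
    area_ha = n_cells * cell_area / M2_PER_HA

    polygon = None
    if build_polygon:
        half_x = (xs[1] - xs[0]) / 2.0
        half_y = (ys[1] - ys[0]) / 2.0
        chosen = order[:n_cells]
        cx, cy = gx.ravel()[chosen], gy.ravel()[chosen]
        polygon = unary_union(
            [box(x - half_x, y - half_y, x + half_x, y + half_y) for x, y in zip(cx, cy)]
        )
    return polygon, area_ha


# ---------------------------------------------------------------------------
# path, intensity, centroids
# ---------------------------------------------------------------------------

def path_length(points) -> float:
    """Total travelled distance: sum of consecutive Euclidean step lengths.

    Points must be time-sorted within the night; fewer than 2 points give 0.
    """
    pts = _as_points(points) if len(points) else np.empty((0, 2))
    if len(pts) < 2:
        return 0.0
    return float(np.hypot(*np.diff(pts, axis=0).T).sum())


def search_intensity(path_length_m: float, mcp95_ha: float) -> float:
    """Path length per unit MCP95 area per day, m/(m2 x d) with d = 1 night."""
    if mcp95_ha <= 0:
        raise ValueError("search intensity undefined for zero MCP95 area")
    return path_length_m / (mcp95_ha * M2_PER_HA)


def nightly_centroid(points):
    """Coordinate-wise arithmetic mean of the night's positions."""
    pts = _as_points(points)
    if len(pts) == 0:
        raise ValueError("centroid of an empty point set")
    c = pts.mean(axis=0)
    return float(c[0]), float(c[1])


# ---------------------------------------------------------------------------
# per-night summary table
# ---------------------------------------------------------------------------

@dataclass
class NightExclusion:
    individual_id: str
    night_id: object
    reason: str


def nightly_summaries(records: pd.DataFrame,
                      mcp_percentile: float = 95.0,
                      kde_isopleth: float = 50.0) -> tuple[pd.DataFrame, list[NightExclusion]]:
    """Per individual-night metrics from preprocessed position records.

    ``records`` needs columns individual_id, night_id, timestamp, east,
    north (plus optional sex / treatment carried through).  Nights with
    fewer than 5 positions, or with degenerate geometry, are excluded and
    reported.  Returns ``(summaries, exclusions)``.
    """
    rows, exclusions = [], []
    records = records.dropna(subset=["night_id"])
    for (ind, night), grp in records.groupby(["individual_id", "night_id"], sort=True):
        grp = grp.sort_values("timestamp", kind="stable")
        pts = grp[["east", "north"]].to_numpy()
        if len(pts) < MIN_POSITIONS_PER_NIGHT:
            exclusions.append(NightExclusion(ind, night, f"only {len(pts)} positions"))
            continue
        try:
            _, mcp95_ha = mcp_area(pts, mcp_percentile)
            _, kde50_ha = kde_home_range(pts, kde_isopleth)
        except (DegenerateInputError, InsufficientPositionsError) as exc:
            exclusions.append(NightExclusion(ind, night, str(exc)))
            continue
        plen = path_length(pts)
        if mcp95_ha > 0:
            intensity = search_intensity(plen, mcp95_ha)
        else:
            exclusions.append(NightExclusion(ind, night, "zero MCP95 area"))
            continue
        ce, cn = nightly_centroid(pts)
        row = {
            "individual_id": ind,
            "night_id": night,
            "mcp95_ha": mcp95_ha,
            "kde50_ha": kde50_ha,
            "path_length_m": plen,
            "search_intensity": intensity,
            "centroid_east_m": ce,
            "centroid_north_m": cn,
            "n_positions": len(pts),
        }
        for extra in ("sex", "treatment"):
            if extra in grp.columns:
                row[extra] = grp[extra].iloc[0]
        rows.append(row)
    for excl in exclusions:
        logger.info("night excluded: %s %s (%s)", excl.individual_id, excl.night_id, excl.reason)
    return pd.DataFrame(rows), exclusions


def centroid_deviation(summaries: pd.DataFrame,
                       reference_treatment: str = "pre") -> pd.DataFrame:
    """Per-axis absolute deviation of nightly centroids from the
    individual's mean reference-phase centroid.

    Individuals without any reference-phase night are excluded with a
    warning.  Returns individual_id, night_id, treatment,
    abs_dev_east_m, abs_dev_north_m (plus sex when present).
    """
    out = []
    for ind, grp in summaries.groupby("individual_id", sort=True):
        ref = grp[grp["treatment"] == reference_treatment]
        if ref.empty:
            logger.warning("individual %s has no %s-phase nights; excluded from "
                           "centroid deviations", ind, reference_treatment)
            continue
        ref_e = ref["centroid_east_m"].mean()
        ref_n = ref["centroid_north_m"].mean()
        dev = grp[["individual_id", "night_id", "treatment"]].copy()
        if "sex" in grp.columns:
            dev["sex"] = grp["sex"]
        dev["abs_dev_east_m"] = (grp["centroid_east_m"] - ref_e).abs()
        dev["abs_dev_north_m"] = (grp["centroid_north_m"] - ref_n).abs()
        out.append(dev)
    if not out:
        return pd.DataFrame(columns=["individual_id", "night_id", "treatment",
                                     "abs_dev_east_m", "abs_dev_north_m"])
    return pd.concat(out, ignore_index=True)
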