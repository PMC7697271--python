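"""Readers, writers and the planar projection used by the whole pipeline.

GPS fixes, ACC bursts and nest records travel as pandas DataFrames with
fixed column names (see the ``*_COLUMNS`` constants).  Readers validate and
collect malformed rows into a rejects frame instead of silently dropping
them.  All metric quantities are computed in a local azimuthal-equidistant
plane about the study-site centre, so distances from the centre are exact —
which is what the 1000 m plausibility filter measures.

Timestamps are handled in local time (``Europe/Berlin`` by default); study
windows ("7 p.m. to 7 a.m.") are clock times, and the study season avoids
DST transitions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from shapely.geometry import mapping as geom_mapping, shape as geom_shape
from shapely.geometry.base import BaseGeometry

EARTH_RADIUS_M = 6_371_008.8  # mean Earth radius
DEFAULT_TIMEZONE = "Europe/Berlin"

GPS_COLUMNS = ["individual_id", "timestamp", "lon", "lat", "burst_id"]
NEST_COLUMNS = ["individual_id", "date", "nest_id", "lon", "lat"]
ACC_LONG_COLUMNS = ["individual_id", "start_timestamp", "sample_index", "x", "y", "z"]

#: Movebank-dialect column mapping accepted by :func:`read_gps`.
MOVEBANK_GPS_SCHEMA = {
    "individual_id": "individual-local-identifier",
    "timestamp": "timestamp",
    "lon": "location-long",
    "lat": "location-lat",
    "burst_id": "burst-id",
}


class SchemaError(ValueError):
    """A mandatory column is missing or unmappable."""


class GeometryError(ValueError):
    """Invalid geometry handed to a writer."""


# ---------------------------------------------------------------------------
# planar projection
# ---------------------------------------------------------------------------

def project_to_plane(lon, lat, site_centre):
    """Project lon/lat degrees to east/north metres.

    Azimuthal equidistant projection about ``site_centre`` (lon, lat in
    degrees) on a sphere of mean Earth radius: distances from the centre are
    preserved exactly, which makes the 1000 m site filter well defined.

    Returns ``(east, north)`` arrays (or scalars) in metres.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    lon0, lat0 = np.deg2rad(site_centre[0]), np.deg2rad(site_centre[1])
    lam, phi = np.deg2rad(lon), np.deg2rad(lat)
    dlam = lam - lon0
    cos_c = np.sin(lat0) * np.sin(phi) + np.cos(lat0) * np.cos(phi) * np.cos(dlam)
    cos_c = np.clip(cos_c, -1.0, 1.0)
    c = np.arccos(cos_c)
    # k = c / sin(c), with the removable singularity at c = 0
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(c > 1e-12, c / np.sin(np.where(c > 1e-12, c, 1.0)), 1.0)
    east = EARTH_RADIUS_M * k * np.cos(phi) * np.sin(dlam)
    north = EARTH_RADIUS_M * k * (
        np.cos(lat0) * np.sin(phi) - np.sin(lat0) * np.cos(phi) * np.cos(dlam)
    )
    if east.ndim == 0:
        return float(east), float(north)
    return east, north


def project_to_lonlat(east, north, site_centre):
    """Inverse of :func:`project_to_plane` (metres back to degrees)."""
    east = np.asarray(east, dtype=float)
    north = np.asarray(north, dtype=float)
    lon0, lat0 = np.deg2rad(site_centre[0]), np.deg2rad(site_centre[1])
    rho = np.hypot(east, north)
    c = rho / EARTH_RADIUS_M
    safe_rho = np.where(rho > 1e-12, rho, 1.0)
    sin_c, cos_c = np.sin(c), np.cos(c)
    phi = np.arcsin(
        np.clip(cos_c * np.sin(lat0) + north * sin_c * np.cos(lat0) / safe_rho, -1, 1)
    )
    lam = lon0 + np.arctan2(
        east * sin_c, safe_rho * cos_c * np.cos(lat0) - north * sin_c * np.sin(lat0)
    )
    lam = np.where(rho > 1e-12, lam, lon0)
    phi = np.where(rho > 1e-12, phi, lat0)
    lon, lat = np.rad2deg(lam), np.rad2deg(phi)
    if lon.ndim == 0:
        return float(lon), float(lat)
    return lon, lat


def add_planar_coordinates(frame: pd.DataFrame, site_centre) -> pd.DataFrame:
    """Return a copy of ``frame`` with ``east``/``north`` metre columns."""
    out = frame.copy()
    east, north = project_to_plane(out["lon"].to_numpy(), out["lat"].to_numpy(), site_centre)
    out["east"] = east
    out["north"] = north
    return out


# ---------------------------------------------------------------------------
# GPS fixes
# ---------------------------------------------------------------------------

def _rename_columns(frame: pd.DataFrame, schema: Mapping[str, str] | None,
                    required: Iterable[str]) -> pd.DataFrame:
    if schema:
        inverse = {v: k for k, v in schema.items()}
        frame = frame.rename(columns=inverse)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    return frame


def read_gps(path, schema: Mapping[str, str] | None = None,
             timezone: str = DEFAULT_TIMEZONE):
    """Read a GPS fix CSV.

    ``schema`` maps canonical names to file column names (use
    :data:`MOVEBANK_GPS_SCHEMA` for Movebank exports).  Returns
    ``(fixes, rejects)``: validated, time-sorted fixes and a frame of
    malformed rows with a ``reject_reason`` column.  Naive timestamps are
    interpreted as local time in ``timezone``.
    """
    raw = pd.read_csv(path, dtype={"individual_id": str, "burst_id": str})
    raw = _rename_columns(raw, schema, GPS_COLUMNS)
    return validate_gps(raw, timezone=timezone)


def validate_gps(raw: pd.DataFrame, timezone: str = DEFAULT_TIMEZONE):
    """Validate a GPS frame; see :func:`read_gps`."""
    frame = raw.copy()
    ts = pd.to_datetime(frame["timestamp"], errors="coerce")
    lon = pd.to_numeric(frame["lon"], errors="coerce")
    lat = pd.to_numeric(frame["lat"], errors="coerce")

    reasons = pd.Series("", index=frame.index, dtype=object)
    reasons[ts.isna()] = "unparseable timestamp"
    reasons[lon.isna()] = "unparseable longitude"
    reasons[(lon < -180) | (lon > 180)] = "longitude out of range"
    reasons[lat.isna()] = "unparseable latitude"
    reasons[(lat < -90) | (lat > 90)] = "latitude out of range"
    bad = reasons != ""

    rejects = frame.loc[bad].copy()
    rejects["reject_reason"] = reasons[bad]

    fixes = frame.loc[~bad].copy()
    fixes["timestamp"] = _to_local(ts[~bad], timezone)
    fixes["lon"] = lon[~bad]
    fixes["lat"] = lat[~bad]
    fixes = fixes.sort_values(["individual_id", "timestamp"], kind="stable")
    return fixes.reset_index(drop=True), rejects.reset_index(drop=True)


def _to_local(ts: pd.Series, timezone: str) -> pd.Series:
    if ts.dt.tz is None:
        return ts.dt.tz_localize(timezone, ambiguous="NaT", nonexistent="NaT")
    return ts.dt.tz_convert(timezone)


def write_gps(frame: pd.DataFrame, path) -> None:
    """Write fixes with canonical headers (timestamps in ISO local time)."""
    out = frame[GPS_COLUMNS].copy()
    out["timestamp"] = out["timestamp"].map(lambda t: t.isoformat())
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# nest records
# ---------------------------------------------------------------------------

def read_nests(path, schema: Mapping[str, str] | None = None):
    """Read daily nest records; returns ``(records, rejects)``.

    At most one record per individual per date; duplicates beyond the first
    are rejected.
    """
    raw = pd.read_csv(path, dtype={"individual_id": str, "nest_id": str})
    raw = _rename_columns(raw, schema, NEST_COLUMNS)
    frame = raw.copy()
    date = pd.to_datetime(frame["date"], errors="coerce")
    lon = pd.to_numeric(frame["lon"], errors="coerce")
    lat = pd.to_numeric(frame["lat"], errors="coerce")

    reasons = pd.Series("", index=frame.index, dtype=object)
    reasons[date.isna()] = "unparseable date"
    reasons[lon.isna() | (lon < -180) | (lon > 180)] = "longitude out of range"
    reasons[lat.isna() | (lat < -90) | (lat > 90)] = "latitude out of range"
    dup = frame.assign(_d=date).duplicated(subset=["individual_id", "_d"], keep="first")
    reasons[dup & (reasons == "")] = "duplicate record for individual and date"
    bad = reasons != ""

    rejects = frame.loc[bad].copy()
    rejects["reject_reason"] = reasons[bad]
    records = frame.loc[~bad].copy()
    records["date"] = date[~bad].dt.normalize()
    records["lon"] = lon[~bad]
    records["lat"] = lat[~bad]
    records = records.sort_values(["individual_id", "date"], kind="stable")
    return records.reset_index(drop=True), rejects.reset_index(drop=True)


# ---------------------------------------------------------------------------
# home-range polygons (GeoJSON)
# ---------------------------------------------------------------------------

@dataclass
class HomeRangeFeature:
    """One individual-night home-range polygon with its metadata."""

    individual_id: str
    night_id: str
    method: str          # "mcp95" or "kde50"
    area_ha: float
    geometry: BaseGeometry
    properties: dict = field(default_factory=dict)


def write_home_range_geojson(features: Iterable[HomeRangeFeature], path,
                             site_centre=None) -> None:
    """Write home-range polygons as a GeoJSON FeatureCollection.

    Geometries are expected in planar metres; if ``site_centre`` is given
    they are inverse-projected to lon/lat before writing (GeoJSON's native
    CRS), otherwise written as-is.  Self-intersecting polygons are refused.
    """
    out_features = []
    for feat in features:
        geom = feat.geometry
        if geom is None or geom.is_empty:
            continue
        if not geom.is_valid:
            raise GeometryError(
                f"invalid geometry for {feat.individual_id}/{feat.night_id}: "
                "self-intersecting or malformed polygon"
            )
        if site_centre is not None:
            geom = _reproject_geometry(geom, site_centre)
        props = {
            "individual_id": feat.individual_id,
            "night_id": str(feat.night_id),
            "method": feat.method,
            "area_ha": feat.area_ha,
            **feat.properties,
        }
        out_features.append(
            {"type": "Feature", "geometry": geom_mapping(geom), "properties": props}
        )
    collection = {"type": "FeatureCollection", "features": out_features}
    with open(path, "w") as fh:
        json.dump(collection, fh)


def read_home_range_geojson(path, site_centre=None) -> list[HomeRangeFeature]:
    """Read back a FeatureCollection written by :func:`write_home_range_geojson`."""
    with open(path) as fh:
        collection = json.load(fh)
    feats = []
    for feat in collection.get("features", []):
        geom = geom_shape(feat["geometry"])
        if site_centre is not None:
            geom = _reproject_geometry(geom, site_centre, inverse=True)
        props = dict(feat.get("properties", {}))
        feats.append(
            HomeRangeFeature(
                individual_id=props.pop("individual_id", ""),
                night_id=props.pop("night_id", ""),
                method=props.pop("method", ""),
                area_ha=props.pop("area_ha", float("nan")),
                geometry=geom,
                properties=props,
            )
        )
    return feats


def _reproject_geometry(geom: BaseGeometry, site_centre, inverse: bool = False):
    from shapely.ops import transform

    if inverse:
        def fn(x, y):
            return project_to_plane(x, y, site_centre)
    else:
        def fn(x, y):
            return project_to_lonlat(x, y, site_centre)
    return transform(fn, geom)


# ---------------------------------------------------------------------------
# raw ACC long format
# ---------------------------------------------------------------------------

def write_acc_long(burst_table, path) -> None:
    """Write a :class:`~hogwatch.synthetic.BurstTable` to the long CSV schema.

    One row per sample: individual_id, start_timestamp, sample_index, x, y, z.
    Intended for modest burst counts; a full study at 100 Hz is better kept
    in memory.
    """
    meta = burst_table.meta
    n_bursts, n_samples, _ = burst_table.samples.shape
    idx = np.tile(np.arange(n_samples), n_bursts)
    frame = pd.DataFrame(
        {
            "individual_id": np.repeat(meta["individual_id"].to_numpy(), n_samples),
            "start_timestamp": np.repeat(
                meta["start_timestamp"].map(lambda t: t.isoformat()).to_numpy(), n_samples
            ),
            "sample_index": idx,
            "x": burst_table.samples[:, :, 0].ravel(),
            "y": burst_table.samples[:, :, 1].ravel(),
            "z": burst_table.samples[:, :, 2].ravel(),
        }
    )
    # truncated bursts carry NaN padding; real files simply lack those rows
    frame = frame.dropna(subset=["x", "y", "z"], how="all")
    frame.to_csv(path, index=False)


def read_acc_long(path, sample_rate_hz: float = 100.0,
                  timezone: str = DEFAULT_TIMEZONE):
    """Read the long ACC CSV back into a BurstTable (NaN-padded if ragged)."""
    from .synthetic import BurstTable  # local import to avoid a cycle

    raw = pd.read_csv(path, dtype={"individual_id": str})
    raw["start_timestamp"] = _to_local(
        pd.to_datetime(raw["start_timestamp"]), timezone
    )
    groups = list(raw.groupby(["individual_id", "start_timestamp"], sort=True))
    n_samples = int(raw["sample_index"].max()) + 1
    samples = np.full((len(groups), n_samples, 3), np.nan, dtype=np.float32)
    meta_rows = []
    for i, ((ind, ts), grp) in enumerate(groups):
        sel = grp["sample_index"].to_numpy()
        samples[i, sel, 0] = grp["x"].to_numpy()
        samples[i, sel, 1] = grp["y"].to_numpy()
        samples[i, sel, 2] = grp["z"].to_numpy()
        meta_rows.append({"individual_id": ind, "start_timestamp": ts})
    meta = pd.DataFrame(meta_rows)
    return BurstTable(meta=meta, samples=samples, sample_rate_hz=sample_rate_hz)
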