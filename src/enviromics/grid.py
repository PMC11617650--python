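"""Prediction-grid construction over the target population of environments.

The study area is the convex hull of the trial locations, dilated by a buffer,
and discretised into square bins ("pixels") in a planar km projection. A bin
belongs to the grid iff its centroid falls inside the buffered hull. All
geometry is done in a local equirectangular projection about the centroid of
the trial points, which is accurate to well under a bin width at the spatial
extents this package targets (a few hundred km).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, Point

EARTH_RADIUS_KM = 6371.0088


class GeometryError(ValueError):
    """Raised when trial points cannot support a prediction grid."""


@dataclass(frozen=True)
class LocalProjection:
    """Equirectangular lon/lat <-> planar km chart centred on (lat0, lon0)."""

    lat0: float
    lon0: float

    def to_xy(self, lat, lon):
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        x = np.deg2rad(lon - self.lon0) * np.cos(np.deg2rad(self.lat0)) * EARTH_RADIUS_KM
        y = np.deg2rad(lat - self.lat0) * EARTH_RADIUS_KM
        return x, y

    def to_latlon(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        lat = self.lat0 + np.rad2deg(y / EARTH_RADIUS_KM)
        lon = self.lon0 + np.rad2deg(x / (EARTH_RADIUS_KM * np.cos(np.deg2rad(self.lat0))))
        return lat, lon


@dataclass
class PredictionGrid:
    """Square-bin grid covering the buffered trial hull.

    Attributes
    ----------
    bins : pandas.DataFrame
        Columns ``bin_id, lat, lon, x_km, y_km`` (one row per kept bin).
    cell_size_km, buffer_km : float
        Bin edge length and hull dilation distance.
    projection : LocalProjection
        The planar chart shared by every distance computation downstream.
    """

    bins: pd.DataFrame
    cell_size_km: float
    buffer_km: float
    projection: LocalProjection
    meta: dict = field(default_factory=dict)

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def bin_ids(self) -> np.ndarray:
        return self.bins["bin_id"].to_numpy()

    def centroids_xy(self) -> np.ndarray:
        return self.bins[["x_km", "y_km"]].to_numpy()


def build_prediction_grid(
    trial_points,
    cell_size_km: float = 5.0,
    buffer_km: float = 50.0,
) -> PredictionGrid:
    """Build the regular bin grid over the buffered convex hull of trials.

    Parameters
    ----------
    trial_points : iterable of (lat, lon)
        At least 3 non-collinear points.
    cell_size_km : float
        Bin edge length in km (default 5, i.e. 25 km^2 pixels).
    buffer_km : float
        Dilation of the hull polygon (default 50 km). The dilation uses
        mitred joins so the buffered region extends the hull edges squarely.

    Returns
    -------
    PredictionGrid
        Bins whose centroids lie inside the buffered hull, anchored at the
        buffered polygon's bounding-box minimum corner.
    """
    pts = np.asarray(sorted((float(a), float(b)) for a, b in trial_points), dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise GeometryError("need at least 3 trial points to define a study area")
    if cell_size_km <= 0:
        raise GeometryError("cell_size_km must be positive")
    if buffer_km < 0:
        raise GeometryError("buffer_km must be non-negative")

    proj = LocalProjection(lat0=float(pts[:, 0].mean()), lon0=float(pts[:, 1].mean()))
    x, y = proj.to_xy(pts[:, 0], pts[:, 1])
    hull = MultiPoint(list(zip(x, y))).convex_hull
    if hull.geom_type != "Polygon":
        raise GeometryError("trial points are collinear; convex hull is degenerate")

    # Mitred joins keep the dilation square at hull corners, so a rectangle of
    # points dilated by b becomes the enclosing rectangle grown by b on each side.
    area = hull.buffer(buffer_km, join_style="mitre") if buffer_km > 0 else hull

    minx, miny, maxx, maxy = area.bounds
    nx = max(1, int(np.ceil((maxx - minx) / cell_size_km)))
    ny = max(1, int(np.ceil((maxy - miny) / cell_size_km)))
    cx = minx + (np.arange(nx) + 0.5) * cell_size_km
    cy = miny + (np.arange(ny) + 0.5) * cell_size_km
    gx, gy = np.meshgrid(cx, cy, indexing="xy")
    gx, gy = gx.ravel(), gy.ravel()

    keep = np.array([area.covers(Point(px, py)) for px, py in zip(gx, gy)])
    if not keep.any():
        # Degenerate case: cell larger than the area extent. Keep the cell
        # holding the area centroid so the grid is never empty.
        c = area.centroid
        gx, gy, keep = np.array([c.x]), np.array([c.y]), np.array([True])

    gx, gy = gx[keep], gy[keep]
    lat, lon = proj.to_latlon(gx, gy)
    bins = pd.DataFrame(
        {
            "bin_id": [f"B{i:05d}" for i in range(len(gx))],
            "lat": lat,
            "lon": lon,
            "x_km": gx,
            "y_km": gy,
        }
    )
    meta = {
        "hull": "convex",
        "buffer_join_style": "mitre",
        "datum": "WGS84 degrees; planar local equirectangular km",
    }
    return PredictionGrid(
        bins=bins,
        cell_size_km=float(cell_size_km),
        buffer_km=float(buffer_km),
        projection=proj,
        meta=meta,
    )
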