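"""Planar and scene-frame projections for small-area field geometry.

Two deliberately different flat-earth projections coexist here:

* :func:`lonlat_to_plane` — the spacing projection.  Longitude and latitude
  are scaled straight to metres with a fixed 111 000 m/° latitude
  coefficient (longitude additionally scaled by ``cos(ref_lat)``).  It is
  used for in-row spacing, where only *differences* over a few metres
  matter, so the crude constant is harmless.
* :func:`geo_to_scene` — the scene (digital-twin) projection.  An
  equirectangular local-tangent-plane conversion anchored at a field
  origin, using the WGS-84 semi-major axis ``R = 6 378 137 m`` and rotated
  by the ridge azimuth so that scene axes align with the ridges.

Both are valid only over small areas (≲ 1 km) and ignore ellipsoidal
corrections entirely.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "GeoPoint",
    "PlanePoint",
    "ScenePoint",
    "ProjectionConfig",
    "WGS84_SEMI_MAJOR_AXIS_M",
    "DEFAULT_LAT_COEFF",
    "lonlat_to_plane",
    "plane_to_lonlat",
    "plane_distance",
    "geo_to_scene",
    "scene_to_geo",
    "scene_distance",
    "points_to_geojson",
    "write_geojson_points",
]

#: WGS-84 semi-major axis, metres.
WGS84_SEMI_MAJOR_AXIS_M = 6_378_137.0

#: Approximate metres per degree of latitude used by the spacing projection.
DEFAULT_LAT_COEFF = 111_000.0


@dataclass(frozen=True)
class GeoPoint:
    """A WGS-84 position in decimal degrees (north/east positive)."""

    latitude: float
    longitude: float

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude out of range: {self.latitude}")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude out of range: {self.longitude}")


@dataclass(frozen=True)
class PlanePoint:
    """A point in the spacing plane: x east, y north, metres."""

    x: float
    y: float


@dataclass(frozen=True)
class ScenePoint:
    """A point in the twin scene frame: X horizontal, Z vertical, metres."""

    X: float
    Z: float


@dataclass
class ProjectionConfig:
    """Parameters shared by the spacing and scene projections.

    Parameters
    ----------
    ref_lat
        Reference latitude (degrees) for the longitude scale of the
        spacing projection.  Conventionally the latitude of the first
        GNSS fix of a run.
    lat_coeff
        Metres per degree of latitude for the spacing projection.
    origin
        Field origin ``(φ0, λ0)`` for the scene projection; the initial
        position of the inspection platform.
    azimuth_theta
        Clockwise angle, in degrees, between the ridge direction and true
        north.  Stored in degrees for config readability; converted to
        radians internally.
    x_off, z_off
        Scene-frame translation offsets, metres.
    R
        Earth radius used by the scene projection (WGS-84 semi-major axis).
    """

    ref_lat: float = 0.0
    lat_coeff: float = DEFAULT_LAT_COEFF
    origin: GeoPoint | None = None
    azimuth_theta: float = 0.0
    x_off: float = 0.0
    z_off: float = 0.0
    R: float = WGS84_SEMI_MAJOR_AXIS_M

    def __post_init__(self) -> None:
        if self.lat_coeff <= 0:
            raise ValueError("lat_coeff must be positive")
        if abs(self.azimuth_theta) >= 360.0:
            raise ValueError("azimuth_theta must satisfy |θ| < 360°")


class DegenerateProjectionError(ValueError):
    """Raised when the reference latitude makes the projection singular."""


def _meters_per_deg_lon(cfg: ProjectionConfig) -> float:
    if abs(cfg.ref_lat) >= 90.0:
        raise DegenerateProjectionError(
            f"|ref_lat| must be < 90° for the longitude scale, got {cfg.ref_lat}"
        )
    return cfg.lat_coeff * math.cos(math.radians(cfg.ref_lat))


def lonlat_to_plane(p: GeoPoint, cfg: ProjectionConfig) -> PlanePoint:
    """Project a geographic point to the absolute spacing plane.

    ``x = longitude · lat_coeff · cos(ref_lat)``, ``y = latitude · lat_coeff``.
    Coordinates are absolute (not origin-relative); only differences are
    meaningful at sub-metre accuracy.
    """
    return PlanePoint(
        x=p.longitude * _meters_per_deg_lon(cfg),
        y=p.latitude * cfg.lat_coeff,
    )


def plane_to_lonlat(p: PlanePoint, cfg: ProjectionConfig) -> GeoPoint:
    """Exact inverse of :func:`lonlat_to_plane`."""
    return GeoPoint(
        latitude=p.y / cfg.lat_coeff,
        longitude=p.x / _meters_per_deg_lon(cfg),
    )


def plane_distance(a: PlanePoint, b: PlanePoint) -> float:
    """Euclidean distance in metres between two spacing-plane points."""
    return math.hypot(a.x - b.x, a.y - b.y)


def geo_to_scene(p: GeoPoint, cfg: ProjectionConfig) -> ScenePoint:
    """Map a geographic point into the rotated twin scene frame.

    East/north displacements from the origin,

        Lλ = R · cos(φ0) · (λ − λ0) · π/180
        Lφ = R · (φ − φ0) · π/180,

    are rotated by the ridge azimuth θ and translated by the scene offsets:

        [X, Z]ᵀ = [[cosθ, −sinθ], [sinθ, cosθ]] [Lλ, Lφ]ᵀ + [x_off, z_off]ᵀ.
    """
    if cfg.origin is None:
        raise ValueError("ProjectionConfig.origin must be set for scene mapping")
    o = cfg.origin
    l_lam = cfg.R * math.cos(math.radians(o.latitude)) * math.radians(p.longitude - o.longitude)
    l_phi = cfg.R * math.radians(p.latitude - o.latitude)
    th = math.radians(cfg.azimuth_theta)
    c, s = math.cos(th), math.sin(th)
    return ScenePoint(
        X=c * l_lam - s * l_phi + cfg.x_off,
        Z=s * l_lam + c * l_phi + cfg.z_off,
    )


def scene_to_geo(p: ScenePoint, cfg: ProjectionConfig) -> GeoPoint:
    """Analytic inverse of :func:`geo_to_scene` (inverse rotation, then unscale)."""
    if cfg.origin is None:
        raise ValueError("ProjectionConfig.origin must be set for scene mapping")
    o = cfg.origin
    th = math.radians(cfg.azimuth_theta)
    c, s = math.cos(th), math.sin(th)
    x, z = p.X - cfg.x_off, p.Z - cfg.z_off
    l_lam = c * x + s * z
    l_phi = -s * x + c * z
    return GeoPoint(
        latitude=o.latitude + math.degrees(l_phi / cfg.R),
        longitude=o.longitude + math.degrees(l_lam / (cfg.R * math.cos(math.radians(o.latitude)))),
    )


def scene_distance(a: ScenePoint, b: ScenePoint) -> float:
    """Euclidean distance in metres in the scene frame."""
    return math.hypot(a.X - b.X, a.Z - b.Z)


def points_to_geojson(
    points: Sequence[GeoPoint],
    properties: Sequence[dict] | None = None,
) -> dict:
    """Build a GeoJSON FeatureCollection of points (lon, lat order)."""
    if properties is None:
        properties = [{} for _ in points]
    if len(properties) != len(points):
        raise ValueError("properties must match points in length")
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [p.longitude, p.latitude]},
            "properties": dict(props),
        }
        for p, props in zip(points, properties)
    ]
    return {"type": "FeatureCollection", "features": features}


def write_geojson_points(
    path,
    points: Sequence[GeoPoint],
    properties: Sequence[dict] | None = None,
) -> None:
    with open(path, "w") as fh:
        json.dump(points_to_geojson(points, properties), fh, indent=1)
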