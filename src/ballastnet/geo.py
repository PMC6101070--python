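"""Great-circle geometry on a spherical Earth.

All distances use the haversine formula on a sphere of radius 6371 km,
which is accurate to ~0.5% against the ellipsoid — more than enough for
port-to-port route lengths feeding a distance kernel.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "EARTH_RADIUS_KM",
    "great_circle_distance_km",
    "interpolate_great_circle",
]


def _check_bounds(lon, lat) -> None:
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if np.any(~np.isfinite(lon)) or np.any(~np.isfinite(lat)):
        raise ValueError("coordinates must be finite")
    if np.any(np.abs(lon) > 180.0):
        raise ValueError("longitude out of [-180, 180]")
    if np.any(np.abs(lat) > 90.0):
        raise ValueError("latitude out of [-90, 90]")


def great_circle_distance_km(lon1, lat1, lon2, lat2):
    """Haversine distance in km between WGS84 lon/lat points.

    Accepts scalars or broadcastable arrays of decimal degrees.
    Symmetric, non-negative, and exactly 0 for identical points.
    """
    _check_bounds(lon1, lat1)
    _check_bounds(lon2, lat2)
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    if np.ndim(d) == 0:
        return float(d)
    return d


def _unit_vectors(lon_deg, lat_deg) -> np.ndarray:
    lon = np.radians(np.asarray(lon_deg, dtype=float))
    lat = np.radians(np.asarray(lat_deg, dtype=float))
    return np.stack(
        [np.cos(lat) * np.cos(lon), np.cos(lat) * np.sin(lon), np.sin(lat)],
        axis=-1,
    )


def interpolate_great_circle(lon1, lat1, lon2, lat2, fractions):
    """Points along the great circle from (lon1, lat1) to (lon2, lat2).

    ``fractions`` are in [0, 1]; 0 maps to the start point, 1 to the end.
    Uses spherical linear interpolation of unit vectors, so the track is
    the shortest path (ties for antipodal endpoints resolved arbitrarily
    by the numerics). Returns ``(lons, lats)`` arrays in degrees.
    """
    _check_bounds(lon1, lat1)
    _check_bounds(lon2, lat2)
    f = np.asarray(fractions, dtype=float)
    u = _unit_vectors(lon1, lat1)
    v = _unit_vectors(lon2, lat2)
    cross = np.cross(u, v)
    omega = float(np.arctan2(np.linalg.norm(cross), np.dot(u, v)))
    if omega < 1e-12:
        p = np.broadcast_to(u, f.shape + (3,))
    else:
        p = (np.sin((1.0 - f)[..., None] * omega) * u
             + np.sin(f[..., None] * omega) * v) / np.sin(omega)
    p = p / np.linalg.norm(p, axis=-1, keepdims=True)
    lats = np.degrees(np.arcsin(np.clip(p[..., 2], -1.0, 1.0)))
    lons = np.degrees(np.arctan2(p[..., 1], p[..., 0]))
    return lons, lats
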