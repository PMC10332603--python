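"""Great-circle helpers on a spherical Earth (R = 6371 km)."""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0

__all__ = ["EARTH_RADIUS_KM", "haversine_km", "sphere_centroid"]


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray | float:
    """Great-circle distance in km; accepts scalars or broadcastable arrays."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(a)))
    return float(d) if np.ndim(d) == 0 else d


def sphere_centroid(lons, lats) -> tuple[float, float]:
    """Unweighted mean position of points: 3-D mean on the unit sphere,
    renormalized, returned as (lon, lat) degrees."""
    lons = np.radians(np.asarray(lons, dtype=float))
    lats = np.radians(np.asarray(lats, dtype=float))
    if lons.size == 0:
        raise ValueError("cannot compute the centroid of zero points")
    x = np.mean(np.cos(lats) * np.cos(lons))
    y = np.mean(np.cos(lats) * np.sin(lons))
    z = np.mean(np.sin(lats))
    norm = np.sqrt(x * x + y * y + z * z)
    if norm == 0:
        raise ValueError("degenerate point set: centroid is the sphere center")
    lat = np.degrees(np.arcsin(z / norm))
    lon = np.degrees(np.arctan2(y, x))
    if lon >= 180.0:
        lon -= 360.0
    return float(lon), float(lat)
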