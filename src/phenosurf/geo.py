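"""Geodesic helpers on the WGS84 sphere.

All coordinates are geographic longitude/latitude in decimal degrees.
Distances use the haversine great-circle formula on a sphere of mean
radius 6371.0088 km, the convention for tracking-data work where
sub-permille ellipsoidal accuracy is irrelevant.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points (vectorized)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def _to_unit_vectors(lons, lats):
    lam = np.radians(np.asarray(lons, dtype=float))
    phi = np.radians(np.asarray(lats, dtype=float))
    return np.column_stack([np.cos(phi) * np.cos(lam),
                            np.cos(phi) * np.sin(lam),
                            np.sin(phi)])


def _spherical_triangle_area(a, b, c):
    """Area of the spherical triangle with unit-vector vertices a, b, c.

    Uses the tangent formula of Eriksson/Van Oosterom & Strackee which is
    numerically stable for small triangles (no L'Huilier cancellation).
    """
    triple = np.dot(a, np.cross(b, c))
    denom = 1.0 + np.dot(a, b) + np.dot(b, c) + np.dot(a, c)
    return 2.0 * abs(np.arctan2(triple, denom))


def spherical_polygon_area_km2(lons, lats):
    """Area in km^2 of a simple polygon given by vertex lon/lat arrays.

    The polygon is triangulated as a fan from its first vertex; for convex
    polygons (minimum convex polygon home ranges) this is exact.
    """
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    if lons.size < 3:
        raise ValueError("polygon needs at least 3 vertices")
    v = _to_unit_vectors(lons, lats)
    area = 0.0
    for i in range(1, len(v) - 1):
        area += _spherical_triangle_area(v[0], v[i], v[i + 1])
    return area * EARTH_RADIUS_KM ** 2


def offset_point(lon, lat, east_km, north_km):
    """Displace a point by local-tangent-plane east/north offsets in km."""
    dlat = north_km / 111.19
    dlon = east_km / (111.19 * np.cos(np.radians(lat)))
    return lon + dlon, lat + dlat


def great_circle_interp(lon1, lat1, lon2, lat2, frac):
    """Linear interpolation of position; adequate for short N-S flight legs."""
    frac = np.asarray(frac, dtype=float)
    return lon1 + (lon2 - lon1) * frac, lat1 + (lat2 - lat1) * frac
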