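"""Shared spherical-earth geometry helpers.

All horizontal distances in this package use a single equirectangular
local metric on a sphere of mean radius 6371.0 km: one degree of latitude
is ``KM_PER_DEG`` km everywhere, one degree of longitude is
``KM_PER_DEG * cos(lat)`` km.  The same constant is used by the velocity
estimators, the centroid tracker and the synthetic-data generator so that
kilometre displacements are directly comparable across modules.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0
#: km per degree of a great circle on the mean-radius sphere (2*pi*R/360).
KM_PER_DEG = 111.195


def wrap_lon_delta(dlon):
    """Wrap a longitude difference (deg) into (-180, 180]."""
    d = np.asarray(dlon, dtype=float)
    wrapped = -((-d + 180.0) % 360.0 - 180.0)
    return wrapped.item() if np.isscalar(dlon) else wrapped


def wrap_angle(angle):
    """Wrap an angle in degrees into [-180, 180)."""
    a = np.asarray(angle, dtype=float)
    wrapped = (a + 180.0) % 360.0 - 180.0
    return wrapped.item() if np.isscalar(angle) else wrapped


def heading_deg(east, north):
    """Heading of a horizontal vector, degrees clockwise from north in [0, 360)."""
    h = np.degrees(np.arctan2(east, north)) % 360.0
    return h.item() if np.isscalar(east) and np.isscalar(north) else h


def local_offset_km(lat0, lon0, lat1, lon1):
    """(east, north) km from (lat0, lon0) to (lat1, lon1), equirectangular."""
    mean_lat = 0.5 * (np.asarray(lat0, dtype=float) + np.asarray(lat1, dtype=float))
    north = KM_PER_DEG * (np.asarray(lat1, dtype=float) - np.asarray(lat0, dtype=float))
    east = KM_PER_DEG * np.cos(np.radians(mean_lat)) * wrap_lon_delta(
        np.asarray(lon1, dtype=float) - np.asarray(lon0, dtype=float)
    )
    return east, north


def displace_km(lat, lon, east_km, north_km):
    """Move a point by (east, north) km using the same local metric."""
    dlat = north_km / KM_PER_DEG
    mean_lat = lat + 0.5 * dlat
    dlon = east_km / (KM_PER_DEG * np.cos(np.radians(mean_lat)))
    return lat + dlat, lon + dlon
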