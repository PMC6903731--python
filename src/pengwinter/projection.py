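"""Map projections and spherical distances for the polar working plane.

All track smoothing, hexagonal binning, and area computation live in a
Lambert azimuthal equal-area (LAEA) plane in kilometres, south-polar
aspect with the +y axis pointing along the 60°W meridian.  The projection
is exactly area-preserving on the sphere, which makes hexagon cell areas
and habitat-polygon areas exact rather than approximate, and a polar
aspect avoids dateline seams for tracks spanning 170°W-25°W.

Longitude/latitude appear only at I/O boundaries; distances between
geographic points use the haversine formula on a sphere of radius
6371.0 km throughout the package.
"""

from __future__ import annotations

import numpy as np

#: Spherical Earth radius used for every distance and area in the package (km).
R_EARTH = 6371.0

#: Central meridian of the working plane (degrees east).
LON_0 = -60.0


def laea_forward(lon, lat, lon0: float = LON_0):
    """Project geographic coordinates to the equal-area plane.

    Parameters
    ----------
    lon, lat : array_like
        Degrees east / north (WGS84 treated as spherical).
    lon0 : float
        Central meridian; +y points from the South Pole along ``lon0``.

    Returns
    -------
    x, y : ndarray
        Plane coordinates in km.  The South Pole maps to (0, 0).
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    # colatitude from the South Pole
    c = np.radians(90.0 + lat)
    rho = 2.0 * R_EARTH * np.sin(c / 2.0)
    az = np.radians(lon - lon0)
    return rho * np.sin(az), rho * np.cos(az)


def laea_inverse(x, y, lon0: float = LON_0):
    """Inverse of :func:`laea_forward`; returns (lon, lat) in degrees."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rho = np.hypot(x, y)
    # clip guards roundoff at the antipode (rho = 2R)
    c = 2.0 * np.arcsin(np.clip(rho / (2.0 * R_EARTH), 0.0, 1.0))
    lat = np.degrees(c) - 90.0
    lon = lon0 + np.degrees(np.arctan2(x, y))
    lon = np.where(rho == 0.0, lon0, lon)
    return normalize_lon(lon), lat


def normalize_lon(lon):
    """Wrap longitudes into (-180, 180]."""
    lon = np.asarray(lon, dtype=float)
    wrapped = -(np.mod(-lon + 180.0, 360.0) - 180.0)
    return wrapped


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between geographic points (broadcasting)."""
    lon1, lat1, lon2, lat2 = map(lambda a: np.radians(np.asarray(a, dtype=float)),
                                 (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * R_EARTH * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def aeqd_forward(lon, lat, lon_c: float, lat_c: float):
    """Azimuthal equidistant projection centred on an arbitrary point (km).

    Used by the track simulator as a distortion-free local frame around a
    colony: radial great-circle distances from the centre are exact.
    """
    lon = np.radians(np.asarray(lon, dtype=float))
    lat = np.radians(np.asarray(lat, dtype=float))
    lon_c_r, lat_c_r = np.radians(lon_c), np.radians(lat_c)
    cos_c = (np.sin(lat_c_r) * np.sin(lat)
             + np.cos(lat_c_r) * np.cos(lat) * np.cos(lon - lon_c_r))
    c = np.arccos(np.clip(cos_c, -1.0, 1.0))
    k = np.where(c == 0.0, 1.0, c / np.where(c == 0.0, 1.0, np.sin(c)))
    x = R_EARTH * k * np.cos(lat) * np.sin(lon - lon_c_r)
    y = R_EARTH * k * (np.cos(lat_c_r) * np.sin(lat)
                       - np.sin(lat_c_r) * np.cos(lat) * np.cos(lon - lon_c_r))
    return x, y


def aeqd_inverse(x, y, lon_c: float, lat_c: float):
    """Inverse azimuthal equidistant; returns (lon, lat) in degrees."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    lon_c_r, lat_c_r = np.radians(lon_c), np.radians(lat_c)
    rho = np.hypot(x, y)
    c = rho / R_EARTH
    with np.errstate(invalid="ignore"):
        sin_c, cos_c = np.sin(c), np.cos(c)
        lat = np.arcsin(cos_c * np.sin(lat_c_r)
                        + np.where(rho == 0.0, 0.0, y * sin_c * np.cos(lat_c_r) / np.where(rho == 0.0, 1.0, rho)))
        lon = lon_c_r + np.arctan2(x * sin_c,
                                   rho * np.cos(lat_c_r) * cos_c - y * np.sin(lat_c_r) * sin_c)
    lon = np.where(rho == 0.0, lon_c_r, lon)
    return normalize_lon(np.degrees(lon)), np.degrees(lat)
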