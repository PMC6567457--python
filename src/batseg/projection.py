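"""Geographic to planar coordinates: UTM (transverse Mercator, WGS84).

Tracks are projected once at ingest to planar meters; all downstream
geometry is Euclidean. The default zone (12 N) covers the Gulf of
California study region. Two independent formulations are provided:
:func:`utm_forward` (Snyder's series, the implementation used by the
package) and :func:`utm_forward_kruger` (Karney/Krüger conformal-latitude
series, retained as an internal cross-check); they agree to < 1 cm over
the latitudes of interest.
"""

from __future__ import annotations

import math

import numpy as np

# WGS84
_A = 6378137.0
_F = 1.0 / 298.257223563
_E2 = _F * (2.0 - _F)           # first eccentricity squared
_EP2 = _E2 / (1.0 - _E2)        # second eccentricity squared
_K0 = 0.9996
_FALSE_E = 500_000.0


def zone_central_meridian(zone: int) -> float:
    if not 1 <= zone <= 60:
        raise ValueError(f"UTM zone must be in 1..60, got {zone}")
    return -183.0 + 6.0 * zone


def utm_forward(lon, lat, zone: int = 12, northern: bool = True):
    """Project lon/lat (degrees, WGS84) to UTM easting/northing (m).

    Snyder's transverse-Mercator series (Map Projections: A Working
    Manual, eq. 8-9..8-13), accurate to sub-millimeter within a zone.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    lam0 = math.radians(zone_central_meridian(zone))
    phi = np.radians(lat)
    lam = np.radians(lon)

    sin_phi = np.sin(phi)
    cos_phi = np.cos(phi)
    tan_phi = np.tan(phi)

    N = _A / np.sqrt(1.0 - _E2 * sin_phi**2)
    T = tan_phi**2
    C = _EP2 * cos_phi**2
    Aq = (lam - lam0) * cos_phi

    # meridional arc length
    e2, e4, e6 = _E2, _E2**2, _E2**3
    M = _A * (
        (1 - e2 / 4 - 3 * e4 / 64 - 5 * e6 / 256) * phi
        - (3 * e2 / 8 + 3 * e4 / 32 + 45 * e6 / 1024) * np.sin(2 * phi)
        + (15 * e4 / 256 + 45 * e6 / 1024) * np.sin(4 * phi)
        - (35 * e6 / 3072) * np.sin(6 * phi)
    )

    easting = _FALSE_E + _K0 * N * (
        Aq
        + (1 - T + C) * Aq**3 / 6
        + (5 - 18 * T + T**2 + 72 * C - 58 * _EP2) * Aq**5 / 120
    )
    northing = _K0 * (
        M
        + N
        * tan_phi
        * (
            Aq**2 / 2
            + (5 - T + 9 * C + 4 * C**2) * Aq**4 / 24
            + (61 - 58 * T + T**2 + 600 * C - 330 * _EP2) * Aq**6 / 720
        )
    )
    if not northern:
        northing = northing + 10_000_000.0
    return easting, northing


def utm_forward_kruger(lon, lat, zone: int = 12, northern: bool = True):
    """Independent UTM forward projection via the Krüger n-series.

    Kept as an internal oracle for :func:`utm_forward`; uses the
    conformal-latitude formulation with third-flattening series
    coefficients (order n^3, ~sub-mm).
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    lam0 = math.radians(zone_central_meridian(zone))
    phi = np.radians(lat)
    dlam = np.radians(lon) - lam0

    n = _F / (2.0 - _F)
    A = _A / (1 + n) * (1 + n**2 / 4 + n**4 / 64)
    alpha = (
        n / 2 - 2 * n**2 / 3 + 5 * n**3 / 16,
        13 * n**2 / 48 - 3 * n**3 / 5,
        61 * n**3 / 240,
    )
    e = math.sqrt(_E2)
    # conformal latitude
    t = np.sinh(np.arctanh(np.sin(phi)) - e * np.arctanh(e * np.sin(phi)))
    xi = np.arctan2(t, np.cos(dlam))
    eta = np.arctanh(np.sin(dlam) / np.sqrt(1 + t**2))
    xi_s, eta_s = xi.copy(), eta.copy()
    for j, a_j in enumerate(alpha, start=1):
        xi_s = xi_s + a_j * np.sin(2 * j * xi) * np.cosh(2 * j * eta)
        eta_s = eta_s + a_j * np.cos(2 * j * xi) * np.sinh(2 * j * eta)
    easting = _FALSE_E + _K0 * A * eta_s
    northing = _K0 * A * xi_s
    if not northern:
        northing = northing + 10_000_000.0
    return easting, northing
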