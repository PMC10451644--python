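"""Transverse Mercator (UTM) projection on the WGS84 ellipsoid.

Implements the exact-conformal / Krüger-series formulation (series truncated
at n^6, sub-millimetre accuracy anywhere within a UTM zone), both forward
(geographic -> easting/northing) and inverse.  GPS receivers report WGS84;
the NAD83 offset is below device error at the scales this package handles,
so a single configurable zone on WGS84 stands in for "NAD83 UTM".

All public functions are vectorised over numpy arrays.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "geographic_to_utm",
    "utm_to_geographic",
    "utm_zone_for",
    "central_meridian",
]

# WGS84 ellipsoid
_A = 6378137.0
_F = 1.0 / 298.257223563
_E2 = _F * (2.0 - _F)          # first eccentricity squared
_E = np.sqrt(_E2)
_N = _F / (2.0 - _F)           # third flattening

_K0 = 0.9996
_FALSE_EASTING = 500_000.0
_FALSE_NORTHING_SOUTH = 10_000_000.0

# Rectifying radius A = a/(1+n) * (1 + n^2/4 + n^4/64 + n^6/256)
_RECT_RADIUS = _A / (1.0 + _N) * (
    1.0 + _N**2 / 4.0 + _N**4 / 64.0 + _N**6 / 256.0
)

# Krüger series coefficients, order n^6 (Karney 2011, eqs. 35-36).
_ALPHA = np.array([
    _N / 2 - 2 * _N**2 / 3 + 5 * _N**3 / 16 + 41 * _N**4 / 180
    - 127 * _N**5 / 288 + 7891 * _N**6 / 37800,
    13 * _N**2 / 48 - 3 * _N**3 / 5 + 557 * _N**4 / 1440
    + 281 * _N**5 / 630 - 1983433 * _N**6 / 1935360,
    61 * _N**3 / 240 - 103 * _N**4 / 140 + 15061 * _N**5 / 26880
    + 167603 * _N**6 / 181440,
    49561 * _N**4 / 161280 - 179 * _N**5 / 168 + 6601661 * _N**6 / 7257600,
    34729 * _N**5 / 80640 - 3418889 * _N**6 / 1995840,
    212378941 * _N**6 / 319334400,
])

_BETA = np.array([
    _N / 2 - 2 * _N**2 / 3 + 37 * _N**3 / 96 - _N**4 / 360
    - 81 * _N**5 / 512 + 96199 * _N**6 / 604800,
    _N**2 / 48 + _N**3 / 15 - 437 * _N**4 / 1440 + 46 * _N**5 / 105
    - 1118711 * _N**6 / 3870720,
    17 * _N**3 / 480 - 37 * _N**4 / 840 - 209 * _N**5 / 4480
    + 5569 * _N**6 / 90720,
    4397 * _N**4 / 161280 - 11 * _N**5 / 504 - 830251 * _N**6 / 7257600,
    4583 * _N**5 / 161280 - 108847 * _N**6 / 3991680,
    20648693 * _N**6 / 638668800,
])

_J = np.arange(1, 7)


def utm_zone_for(lon: float) -> int:
    """UTM zone number (1-60) containing longitude ``lon`` (degrees)."""
    return int(np.floor((float(lon) + 180.0) / 6.0)) % 60 + 1


def central_meridian(zone: int) -> float:
    """Central meridian of a UTM zone, degrees east."""
    if not 1 <= zone <= 60:
        raise ValueError(f"UTM zone must be in 1..60, got {zone}")
    return -183.0 + 6.0 * zone


def geographic_to_utm(lat, lon, zone: int, northern: bool = True):
    """Project WGS84 geographic coordinates to UTM easting/northing (metres).

    Parameters
    ----------
    lat, lon : array_like
        Latitude/longitude in decimal degrees.
    zone : int
        UTM zone number (1-60).
    northern : bool
        Hemisphere; controls the false northing.

    Returns
    -------
    easting, northing : ndarray
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if np.any(np.abs(lat) > 84.5):
        raise ValueError("latitude outside the UTM domain (|lat| > 84)")

    phi = np.radians(lat)
    lam = np.radians(lon - central_meridian(zone))

    # conformal latitude
    sphi = np.sin(phi)
    tau = np.tan(phi)
    sigma = np.sinh(_E * np.arctanh(_E * sphi))
    taup = tau * np.sqrt(1.0 + sigma**2) - sigma * np.sqrt(1.0 + tau**2)

    xi_p = np.arctan2(taup, np.cos(lam))
    eta_p = np.arcsinh(np.sin(lam) / np.hypot(taup, np.cos(lam)))

    two_j_xi = 2.0 * np.multiply.outer(_J, xi_p)
    two_j_eta = 2.0 * np.multiply.outer(_J, eta_p)
    alpha = _ALPHA.reshape((6,) + (1,) * xi_p.ndim)
    xi = xi_p + np.sum(alpha * np.sin(two_j_xi) * np.cosh(two_j_eta), axis=0)
    eta = eta_p + np.sum(alpha * np.cos(two_j_xi) * np.sinh(two_j_eta), axis=0)

    easting = _FALSE_EASTING + _K0 * _RECT_RADIUS * eta
    northing = _K0 * _RECT_RADIUS * xi
    if not northern:
        northing = northing + _FALSE_NORTHING_SOUTH
    return easting, northing


def utm_to_geographic(easting, northing, zone: int, northern: bool = True):
    """Inverse UTM projection: easting/northing (metres) -> lat/lon degrees.

    Inverts the conformal latitude by Newton iteration on tan(phi)
    (converges to machine precision in a handful of steps).
    """
    easting = np.asarray(easting, dtype=float)
    northing = np.asarray(northing, dtype=float)
    if not northern:
        northing = northing - _FALSE_NORTHING_SOUTH

    xi = northing / (_K0 * _RECT_RADIUS)
    eta = (easting - _FALSE_EASTING) / (_K0 * _RECT_RADIUS)

    two_j_xi = 2.0 * np.multiply.outer(_J, xi)
    two_j_eta = 2.0 * np.multiply.outer(_J, eta)
    beta = _BETA.reshape((6,) + (1,) * xi.ndim)
    xi_p = xi - np.sum(beta * np.sin(two_j_xi) * np.cosh(two_j_eta), axis=0)
    eta_p = eta - np.sum(beta * np.cos(two_j_xi) * np.sinh(two_j_eta), axis=0)

    taup = np.sin(xi_p) / np.hypot(np.sinh(eta_p), np.cos(xi_p))
    lam = np.arctan2(np.sinh(eta_p), np.cos(xi_p))

    # Newton on tau = tan(phi): solve taup(tau) = taup  (Karney 2011, eq. 19-21)
    tau = taup / (1.0 - _E2)
    for _ in range(6):
        sigma = np.sinh(_E * np.arctanh(_E * tau / np.sqrt(1.0 + tau**2)))
        taup_i = tau * np.sqrt(1.0 + sigma**2) - sigma * np.sqrt(1.0 + tau**2)
        dtau = (
            (taup - taup_i)
            * (1.0 + (1.0 - _E2) * tau**2)
            / ((1.0 - _E2) * np.sqrt((1.0 + taup_i**2) * (1.0 + tau**2)))
        )
        tau = tau + dtau

    lat = np.degrees(np.arctan(tau))
    lon = np.degrees(lam) + central_meridian(zone)
    return lat, lon
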