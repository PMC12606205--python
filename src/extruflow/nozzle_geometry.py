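"""Axisymmetric nozzle geometries and the geometry integral.

For steady power-law flow through an axisymmetric nozzle of radius profile
``r(z)`` (``z = 0`` at the inlet at the top, ``z = L`` at the tip), the
pressure drop is proportional to the geometry integral

    I(n) = integral_0^L r(z)^-(3n+1) dz,

which is all the flow model needs to know about the nozzle shape.  Conical
and straight (cylindrical) nozzles admit closed forms; arbitrary profiles
are handled by adaptive quadrature.

All lengths are metres.  Unit conversion belongs at the I/O boundary
(see :mod:`extruflow.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence, Union

import numpy as np
from scipy.integrate import quad

__all__ = [
    "ConicalNozzle",
    "StraightNozzle",
    "GenericNozzle",
    "Nozzle",
    "geometry_integral",
    "as_generic",
    "conical_from_gauge",
    "TIP_CATALOGUE",
    "STANDARD_INLET_DIAMETER",
]

# Standard conical dispensing-tip outlet diameters (m) by needle gauge.
# The inlet (barrel) diameter is shared across gauges for this tip family.
STANDARD_INLET_DIAMETER = 4.02e-3
TIP_CATALOGUE = {
    "25G": 0.25e-3,
    "22G": 0.41e-3,
    "20G": 0.58e-3,
}

#: relative tolerance below which a cone is treated as a cylinder
_CYLINDER_RTOL = 1e-12
#: relative tolerance requested from adaptive quadrature
_QUAD_RTOL = 1e-10


@dataclass(frozen=True)
class ConicalNozzle:
    """Linearly tapering nozzle: inlet diameter ``Di``, outlet ``Do``, length ``Lc``.

    Parameters
    ----------
    Di : float
        Inlet (inner) diameter at the top of the nozzle, m.
    Do : float
        Outlet (tip) diameter, m.  Must satisfy ``Di >= Do > 0``.
    Lc : float
        Nozzle length along the axis, m.
    """

    Di: float
    Do: float
    Lc: float

    def __post_init__(self) -> None:
        if not (self.Do > 0 and self.Di >= self.Do):
            raise ValueError(
                f"conical nozzle requires Di >= Do > 0, got Di={self.Di}, Do={self.Do}"
            )
        if not self.Lc > 0:
            raise ValueError(f"nozzle length must be positive, got Lc={self.Lc}")

    @property
    def ri(self) -> float:
        """Inlet radius, m."""
        return self.Di / 2.0

    @property
    def ro(self) -> float:
        """Outlet (tip) radius, m."""
        return self.Do / 2.0

    @property
    def tan_theta(self) -> float:
        """Tangent of the wall half-angle, ``(ri - ro)/Lc`` (>= 0)."""
        return (self.ri - self.ro) / self.Lc

    @property
    def length(self) -> float:
        return self.Lc

    @property
    def tip_radius(self) -> float:
        return self.ro

    @property
    def tip_diameter(self) -> float:
        return self.Do

    @property
    def is_cylindrical(self) -> bool:
        """True when the taper is below numerical resolution (Di == Do)."""
        return abs(self.Di - self.Do) < _CYLINDER_RTOL * self.Di

    def radius_at(self, z: float) -> float:
        """Radius of the linear taper at axial position ``z`` in [0, Lc]."""
        return self.ri + (self.ro - self.ri) * z / self.Lc


@dataclass(frozen=True)
class StraightNozzle:
    """Straight cylindrical nozzle with bore diameter ``DN`` and length ``LN`` (m)."""

    DN: float
    LN: float

    def __post_init__(self) -> None:
        if not self.DN > 0:
            raise ValueError(f"bore diameter must be positive, got DN={self.DN}")
        if not self.LN > 0:
            raise ValueError(f"nozzle length must be positive, got LN={self.LN}")

    @property
    def RN(self) -> float:
        """Bore radius, m."""
        return self.DN / 2.0

    @property
    def length(self) -> float:
        return self.LN

    @property
    def tip_radius(self) -> float:
        return self.RN

    @property
    def tip_diameter(self) -> float:
        return self.DN

    def radius_at(self, z: float) -> float:
        return self.RN


ProfileLike = Union[Callable[[float], float], Sequence[Sequence[float]]]


@dataclass(frozen=True)
class GenericNozzle:
    """Arbitrary axisymmetric nozzle described by a radius profile ``r(z)``.

    The profile may be a callable ``z -> r`` or a table of ``(z, r)`` samples
    with strictly increasing ``z`` covering ``[0, L]``; tables are linearly
    interpolated.  ``z = 0`` is the inlet at the top of the nozzle, ``z = L``
    the tip, and ``r(z) > 0`` must hold everywhere on ``[0, L]``.
    """

    L: float
    radius_profile: ProfileLike
    _radius_fn: Callable[[float], float] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.L > 0:
            raise ValueError(f"nozzle length must be positive, got L={self.L}")
        profile = self.radius_profile
        if callable(profile):
            fn = profile
        else:
            table = np.asarray(profile, dtype=float)
            if table.ndim != 2 or table.shape[1] != 2 or table.shape[0] < 2:
                raise ValueError("profile table must be an (m, 2) array of (z, r), m >= 2")
            z, r = table[:, 0], table[:, 1]
            if np.any(np.diff(z) <= 0):
                raise ValueError("profile table z-samples must be strictly increasing")
            if z[0] > 0 or z[-1] < self.L:
                raise ValueError(f"profile table must cover [0, {self.L}]")
            if np.any(r <= 0):
                raise ValueError("profile radii must be positive")

            def fn(zq: float, _z=z, _r=r) -> float:
                return float(np.interp(zq, _z, _r))

        object.__setattr__(self, "_radius_fn", fn)
        # probe a handful of interior points so a bad callable fails loudly here
        for zq in np.linspace(0.0, self.L, 7):
            if not self.radius_at(float(zq)) > 0:
                raise ValueError(f"radius profile must be positive on [0, L]; r({zq}) <= 0")

    @property
    def length(self) -> float:
        return self.L

    @property
    def tip_radius(self) -> float:
        return self.radius_at(self.L)

    @property
    def tip_diameter(self) -> float:
        return 2.0 * self.tip_radius

    def radius_at(self, z: float) -> float:
        return float(self._radius_fn(z))


Nozzle = Union[ConicalNozzle, StraightNozzle, GenericNozzle]


def conical_from_gauge(gauge: str, Lc: float, Di: float = STANDARD_INLET_DIAMETER) -> ConicalNozzle:
    """Conical tip from the built-in gauge catalogue (25G / 22G / 20G).

    The catalogue fixes the outlet diameter per gauge and a shared inlet
    diameter; the tapered length ``Lc`` varies between manufacturers and must
    be supplied by the caller.
    """
    try:
        Do = TIP_CATALOGUE[gauge.upper()]
    except KeyError:
        raise KeyError(
            f"unknown gauge {gauge!r}; catalogue has {sorted(TIP_CATALOGUE)}"
        ) from None
    return ConicalNozzle(Di=Di, Do=Do, Lc=Lc)


def as_generic(nozzle: Nozzle) -> GenericNozzle:
    """View any nozzle as a :class:`GenericNozzle` (its exact radius profile).

    Used by tests to push closed-form geometries through the quadrature path.
    """
    if isinstance(nozzle, GenericNozzle):
        return nozzle
    return GenericNozzle(L=nozzle.length, radius_profile=nozzle.radius_at)


def _check_index(n: float) -> None:
    if not n > 0:
        raise ValueError(f"flow behaviour index must be positive, got n={n}")


def geometry_integral(nozzle: Nozzle, n: float) -> float:
    """Evaluate ``I(n) = integral_0^L r(z)^-(3n+1) dz`` for a nozzle.

    Dispatches to closed forms for conical and straight nozzles and to
    adaptive quadrature for generic profiles.  A cone with ``Di == Do``
    (within 1e-12 relative) uses the cylindrical closed form, which is the
    limit of the conical one.

    Parameters
    ----------
    nozzle : ConicalNozzle | StraightNozzle | GenericNozzle
    n : float
        Flow behaviour index (> 0).

    Returns
    -------
    float
        The geometry integral, units m^-3n.
    """
    _check_index(n)
    if isinstance(nozzle, StraightNozzle):
        return nozzle.LN / nozzle.RN ** (3.0 * n + 1.0)
    if isinstance(nozzle, ConicalNozzle):
        if nozzle.is_cylindrical:
            return nozzle.Lc / nozzle.ri ** (3.0 * n + 1.0)
        ri, ro = nozzle.ri, nozzle.ro
        p = 3.0 * n
        return (ri**p - ro**p) / (p * nozzle.tan_theta * (ri * ro) ** p)
    if isinstance(nozzle, GenericNozzle):
        power = -(3.0 * n + 1.0)

        def integrand(z: float) -> float:
            r = nozzle.radius_at(z)
            if not r > 0:
                raise ValueError(f"non-positive radius r({z}) = {r}")
            return r**power

        value, abserr = quad(integrand, 0.0, nozzle.L, epsrel=_QUAD_RTOL, limit=200)
        if not np.isfinite(value) or (value > 0 and abserr > 1e-6 * abs(value)):
            raise RuntimeError(
                f"geometry quadrature did not converge (value={value}, abserr={abserr})"
            )
        return value
    raise TypeError(f"unsupported nozzle type: {type(nozzle).__name__}")
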