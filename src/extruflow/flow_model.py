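"""Forward extrusion model for a power-law (Ostwald–de Waele) fluid.

The material obeys ``tau = K * gamma_dot**n`` with flow behaviour index ``n``
(shear-thinning for ``0 < n < 1``, Newtonian at ``n = 1`` where ``K`` is the
dynamic viscosity) and consistency index ``K`` (Pa·s^n).

For steady, axisymmetric, no-slip flow through a nozzle, a force balance on
each cross-section integrates along the nozzle to

    dP = 2 K ((3n+1)/(4n) * 4 Q / pi)**n * I(n),

with ``I(n)`` the geometry integral of :mod:`extruflow.nozzle_geometry` and
``Q`` the volumetric flow rate.  Mass conservation on the build platform,
``Q = pi d^2 U / 4`` (the extruded thread keeps a circular cross-section and
is dragged at travel speed ``U``), then predicts the printed filament
diameter ``d``.  Everything is SI internally: m, Pa, m/s.

The set air pressure on a pneumatic printer is the gauge pressure above the
atmospheric tip pressure, so it plays the role of ``dP`` directly (the
pressure drop in the wide syringe barrel is negligible).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .nozzle_geometry import Nozzle, geometry_integral

__all__ = [
    "ATMOSPHERIC_PRESSURE",
    "N_MIN",
    "N_MAX",
    "PowerLawFluid",
    "PrintingConditions",
    "FlowSolution",
    "wall_shear_rate",
    "pressure_drop_for_flux",
    "flux_from_pressure",
    "extrusion_speed",
    "predict_diameter",
    "predict_diameter_newtonian",
    "proportionality_coefficient",
    "solve_flow",
]

#: standard atmosphere at the nozzle tip, Pa
ATMOSPHERIC_PRESSURE = 101325.0

# Working range for the flow behaviour index.  The model raises pressure
# ratios to the power 1/n, so very small n is numerically explosive; fitted
# indices for printable inks lie well inside [0.01, 2].
N_MIN = 0.01
N_MAX = 2.0


@dataclass(frozen=True)
class PowerLawFluid:
    """Power-law material: shear stress ``K * gamma_dot**n``.

    Parameters
    ----------
    n : float
        Flow behaviour index, dimensionless, in [0.01, 2].
    K : float
        Consistency index, Pa·s^n (> 0).  Equals the dynamic viscosity for
        a Newtonian fluid (n = 1).
    """

    n: float
    K: float

    def __post_init__(self) -> None:
        if not (N_MIN <= self.n <= N_MAX):
            raise ValueError(
                f"flow behaviour index n={self.n} outside working range [{N_MIN}, {N_MAX}]"
            )
        if not self.K > 0:
            raise ValueError(f"consistency index must be positive, got K={self.K}")

    @classmethod
    def newtonian(cls, mu: float) -> "PowerLawFluid":
        """Newtonian fluid of dynamic viscosity ``mu`` (Pa·s)."""
        return cls(n=1.0, K=mu)

    @property
    def is_shear_thinning(self) -> bool:
        return self.n < 1.0


@dataclass(frozen=True)
class PrintingConditions:
    """Gauge pressure drop across the nozzle and the travel speed.

    ``delta_P`` is the set air pressure minus the atmospheric pressure at the
    tip, Pa (>= 0).  ``U`` is the build-platform or nozzle travel speed, m/s
    (> 0); the two are interchangeable for the flux balance.
    """

    delta_P: float
    U: float

    def __post_init__(self) -> None:
        if self.delta_P < 0:
            raise ValueError(f"pressure drop must be non-negative, got {self.delta_P}")
        if not self.U > 0:
            raise ValueError(f"travel speed must be positive, got U={self.U}")


@dataclass(frozen=True)
class FlowSolution:
    """Solved extrusion state: flow rate, mean tip speed, filament diameter."""

    Q: float
    u_bar: float
    d: float


def wall_shear_rate(Q: float, r: float, n: float) -> float:
    """Wall shear rate of power-law flow rate ``Q`` in a tube of radius ``r``.

    The Newtonian value ``4Q/(pi r^3)`` times the Rabinowitsch factor
    ``(3n+1)/(4n)``.
    """
    if not r > 0:
        raise ValueError(f"radius must be positive, got r={r}")
    if not n > 0:
        raise ValueError(f"flow behaviour index must be positive, got n={n}")
    if Q < 0:
        raise ValueError(f"flow rate must be non-negative, got Q={Q}")
    return (3.0 * n + 1.0) / (4.0 * n) * 4.0 * Q / (math.pi * r**3)


def pressure_drop_for_flux(fluid: PowerLawFluid, nozzle: Nozzle, Q: float) -> float:
    """Pressure drop (Pa) needed to drive flow rate ``Q`` (m^3/s) through a nozzle."""
    if Q < 0:
        raise ValueError(f"flow rate must be non-negative, got Q={Q}")
    if Q == 0.0:
        return 0.0
    n = fluid.n
    I = geometry_integral(nozzle, n)
    base = (3.0 * n + 1.0) / (4.0 * n) * 4.0 * Q / math.pi
    # log-space power keeps 1/n and n exponents overflow-safe at small n
    return 2.0 * fluid.K * math.exp(n * math.log(base)) * I


def flux_from_pressure(fluid: PowerLawFluid, nozzle: Nozzle, delta_P: float) -> float:
    """Volumetric flow rate ``Q`` (m^3/s) driven by pressure drop ``delta_P`` (Pa).

    Inverts :func:`pressure_drop_for_flux`:

        Q = (pi/4) * (4n/(3n+1)) * (dP / (2 K I(n)))**(1/n).

    With the closed-form geometry integrals this reproduces the conical and
    straight closed forms exactly; with a generic profile it runs through
    quadrature.
    """
    if delta_P < 0:
        raise ValueError(f"pressure drop must be non-negative, got {delta_P}")
    if delta_P == 0.0:
        return 0.0
    n = fluid.n
    I = geometry_integral(nozzle, n)
    ratio = delta_P / (2.0 * fluid.K * I)
    return math.pi / 4.0 * (4.0 * n) / (3.0 * n + 1.0) * math.exp(math.log(ratio) / n)


def extrusion_speed(fluid: PowerLawFluid, nozzle: Nozzle, delta_P: float) -> float:
    """Mean extrusion speed at the tip, ``Q / (pi r_tip^2)`` (m/s)."""
    Q = flux_from_pressure(fluid, nozzle, delta_P)
    return Q / (math.pi * nozzle.tip_radius**2)


def predict_diameter(fluid: PowerLawFluid, nozzle: Nozzle, conditions: PrintingConditions) -> float:
    """Printed filament diameter ``d`` (m) from the nozzle/platform flux balance.

    ``pi d^2 U / 4 = Q`` gives ``d = sqrt(4 Q / (pi U))``; the filament is
    assumed to keep a circular cross-section from tip to platform.
    """
    Q = flux_from_pressure(fluid, nozzle, conditions.delta_P)
    return math.sqrt(4.0 * Q / (math.pi * conditions.U))


def predict_diameter_newtonian(mu: float, nozzle: Nozzle, conditions: PrintingConditions) -> float:
    """Newtonian-limit filament diameter via the closed forms at ``n = 1``.

    Conical:  d = sqrt(3 Di^3 Do^3 dP / (32 mu Lc U (Di^2 + Di Do + Do^2)))
    Straight: d = DN^2 * sqrt(dP / (32 mu LN U))  (Poiseuille's law)

    Agrees with :func:`predict_diameter` at ``n = 1, K = mu``; generic
    profiles fall back to the general model.
    """
    if not mu > 0:
        raise ValueError(f"viscosity must be positive, got mu={mu}")
    from .nozzle_geometry import ConicalNozzle, StraightNozzle

    dP, U = conditions.delta_P, conditions.U
    if isinstance(nozzle, ConicalNozzle) and not nozzle.is_cylindrical:
        Di, Do, Lc = nozzle.Di, nozzle.Do, nozzle.Lc
        return math.sqrt(
            3.0 * Di**3 * Do**3 * dP / (32.0 * mu * Lc * U * (Di**2 + Di * Do + Do**2))
        )
    if isinstance(nozzle, (ConicalNozzle, StraightNozzle)):
        DN = nozzle.tip_diameter
        LN = nozzle.length
        return DN**2 * math.sqrt(dP / (32.0 * mu * LN * U))
    return predict_diameter(PowerLawFluid.newtonian(mu), nozzle, conditions)


def proportionality_coefficient(fluid: PowerLawFluid, nozzle: Nozzle, U: float) -> float:
    """Coefficient ``a`` of the pressure–width proportionality ``d = a * dP**(1/2n)``.

    At fixed material, geometry and travel speed the flux balance collapses
    to a pure power law in the pressure drop; ``a`` carries everything else:

        a = sqrt( (4n/(3n+1)) * (2 K I(n))**(-1/n) / U ),

    in m·Pa^-(1/2n) with dP in Pa.  For a conical nozzle this equals the
    closed form in Di, Do, Lc; it is defined for any nozzle whose full
    geometry (including the tapered length) is known.
    """
    if not U > 0:
        raise ValueError(f"travel speed must be positive, got U={U}")
    n = fluid.n
    I = geometry_integral(nozzle, n)
    log_a2 = (
        math.log(4.0 * n / (3.0 * n + 1.0))
        - math.log(2.0 * fluid.K * I) / n
        - math.log(U)
    )
    return math.exp(0.5 * log_a2)


def solve_flow(fluid: PowerLawFluid, nozzle: Nozzle, conditions: PrintingConditions) -> FlowSolution:
    """Full forward solve: flow rate, mean tip speed and filament diameter."""
    Q = flux_from_pressure(fluid, nozzle, conditions.delta_P)
    u_bar = Q / (math.pi * nozzle.tip_radius**2)
    d = math.sqrt(4.0 * Q / (math.pi * conditions.U))
    return FlowSolution(Q=Q, u_bar=u_bar, d=d)
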