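"""Window of printability: travel-speed / pressure pairs that print at tip width.

Shape fidelity is best when the printed filament diameter ``d`` matches the
nozzle tip diameter ``D_tip``.  Setting ``d = D_tip`` in the flux balance
collapses the forward model to a single curve in the (U, dP) plane,

    U = A * dP**(1/n),

with a window coefficient ``A`` that depends only on material and geometry
(for a straight nozzle ``A = (DN/8) (4n/(3n+1)) (DN/(4 K LN))**(1/n)``, with
a conical analogue in Di, Do, Lc).  On that curve the travel speed exactly
equals the mean extrusion speed at the tip.  Allowing a small relative width
tolerance ``eps`` around ``D_tip`` widens the curve into a *window* — the
reduced parameter space on which print-and-test tuning then operates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .flow_model import PowerLawFluid, PrintingConditions, extrusion_speed, predict_diameter, proportionality_coefficient
from .nozzle_geometry import Nozzle

__all__ = [
    "PrintabilityWindow",
    "window_coefficient",
    "optimal_pressure",
    "optimal_speed",
    "printability_window",
]


def window_coefficient(fluid: PowerLawFluid, nozzle: Nozzle) -> float:
    """Window coefficient ``A`` such that ``d = D_tip`` iff ``U = A * dP**(1/n)``.

    Units (m/s)·Pa^-(1/n).  Equals the mean extrusion speed at unit pressure
    drop, since width matches the tip exactly when the travel speed matches
    the extrusion speed.
    """
    return extrusion_speed(fluid, nozzle, 1.0)


def optimal_pressure(fluid: PowerLawFluid, nozzle: Nozzle, U: float) -> float:
    """Pressure drop (Pa) at which the printed width equals the tip diameter."""
    if not U > 0:
        raise ValueError(f"travel speed must be positive, got U={U}")
    A = window_coefficient(fluid, nozzle)
    return math.exp(fluid.n * math.log(U / A))


def optimal_speed(fluid: PowerLawFluid, nozzle: Nozzle, delta_P: float) -> float:
    """Travel speed (m/s) at which the printed width equals the tip diameter.

    ``U* = A * dP**(1/n)``, identically the mean extrusion speed at the tip:
    matching the travel speed to the extrusion speed is the optimal-printing
    rule.
    """
    if not delta_P > 0:
        raise ValueError(f"pressure drop must be positive, got {delta_P}")
    return extrusion_speed(fluid, nozzle, delta_P)


@dataclass(frozen=True)
class PrintabilityWindow:
    """Feasible (U, dP) pairs and the closed-form window boundaries.

    Attributes
    ----------
    A : float
        Window coefficient, (m/s)·Pa^-(1/n).
    tip_diameter : float
        Target filament width, m.
    tolerance : float
        Relative width tolerance ``eps`` (two-sided).
    feasible_pairs : ndarray, shape (k, 2)
        Grid pairs (U, dP) with ``|d - D_tip| <= eps * D_tip``.
    n : float
        Flow behaviour index of the material (fixes the boundary exponent).
    a_over_sqrtU : float
        Width-law coefficient at unit speed; ``d = a_over_sqrtU/sqrt(U) * dP**(1/2n)``.
    """

    A: float
    tip_diameter: float
    tolerance: float
    feasible_pairs: np.ndarray
    n: float
    a_over_sqrtU: float

    def boundary_pressures(self, U: float) -> tuple[float, float]:
        """Pressure drops at which width equals ``(1 -/+ eps) * D_tip`` at speed ``U``."""
        a = self.a_over_sqrtU / math.sqrt(U)
        lo = ((1.0 - self.tolerance) * self.tip_diameter / a) ** (2.0 * self.n)
        hi = ((1.0 + self.tolerance) * self.tip_diameter / a) ** (2.0 * self.n)
        return lo, hi

    def contains(self, U: float, delta_P: float) -> bool:
        lo, hi = self.boundary_pressures(U)
        return lo <= delta_P <= hi


def printability_window(
    fluid: PowerLawFluid,
    nozzle: Nozzle,
    U_grid: Sequence[float],
    delta_P_grid: Sequence[float],
    tolerance: float = 0.05,
) -> PrintabilityWindow:
    """Scan a (speed, pressure) grid for pairs that print within tolerance.

    Parameters
    ----------
    U_grid, delta_P_grid : sequences of float
        Candidate travel speeds (m/s) and pressure drops (Pa); both non-empty.
    tolerance : float
        Two-sided relative width tolerance around the tip diameter,
        ``0 < tolerance < 1``.  Default 0.05.

    Returns
    -------
    PrintabilityWindow
        Feasible grid pairs (possibly empty — not an error) plus the
        continuous boundary curves.
    """
    U_grid = np.asarray(list(U_grid), dtype=float)
    dP_grid = np.asarray(list(delta_P_grid), dtype=float)
    if U_grid.size == 0 or dP_grid.size == 0:
        raise ValueError("speed and pressure grids must be non-empty")
    if not 0.0 < tolerance < 1.0:
        raise ValueError(f"tolerance must lie in (0, 1), got {tolerance}")

    D_tip = nozzle.tip_diameter
    pairs = []
    for U in U_grid:
        for dP in dP_grid:
            d = predict_diameter(fluid, nozzle, PrintingConditions(delta_P=dP, U=U))
            if abs(d - D_tip) <= tolerance * D_tip:
                pairs.append((U, dP))
    feasible = np.asarray(pairs, dtype=float).reshape(-1, 2)

    return PrintabilityWindow(
        A=window_coefficient(fluid, nozzle),
        tip_diameter=D_tip,
        tolerance=tolerance,
        feasible_pairs=feasible,
        n=fluid.n,
        a_over_sqrtU=proportionality_coefficient(fluid, nozzle, 1.0),
    )
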