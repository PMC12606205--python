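"""Inverse problem: fit the pressure–width power law and rheometry data.

At fixed material, nozzle and travel speed the forward model predicts

    d = a * dP**(1/(2n)),

so a width-versus-pressure experiment determines the flow behaviour index
``n`` and the coefficient ``a`` (hence the consistency index ``K`` when the
full nozzle geometry and travel speed are known).  The fit minimises the sum
of squared residuals between per-pressure mean widths and the curve; for
fixed ``n`` the optimal ``a`` is a linear least-squares problem with closed
form, which reduces the free fit to a one-dimensional, deterministic search
over ``n``.

Also provided: the classical rheometer route, fitting
``ln mu = ln K + (n - 1) ln gamma_dot`` to viscosity–shear-rate data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .dataset import MeasurementDataset
from .flow_model import N_MAX, N_MIN, PowerLawFluid, proportionality_coefficient
from .nozzle_geometry import Nozzle, geometry_integral

__all__ = [
    "AggregatedSeries",
    "PowerLawCurve",
    "FitResult",
    "aggregate_measurements",
    "fit_power_law",
    "fit_newtonian",
    "fit_fixed_n",
    "consistency_from_coefficient",
    "coefficient_from_consistency",
    "r_squared",
    "average_index",
    "fit_rheometry",
]

# profile-search seeds for the free fit; refinement then localises the optimum
_N_GRID = np.arange(0.05, 1.5001, 0.05)
_XATOL = 1e-12


@dataclass(frozen=True)
class AggregatedSeries:
    """Per-pressure width summaries: (dP, mean width, sd, number of line means)."""

    pressures: np.ndarray
    d_mean: np.ndarray
    d_sd: np.ndarray
    m_lines: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.pressures, dtype=float)
        if p.size != np.unique(p).size:
            raise ValueError("pressures must be unique")
        if np.any(p <= 0):
            raise ValueError("pressures must be positive")
        if np.any(np.asarray(self.d_mean) <= 0):
            raise ValueError("mean widths must be positive")
        if np.any(np.asarray(self.m_lines) < 1):
            raise ValueError("each pressure needs at least one line mean")

    def __len__(self) -> int:
        return len(self.pressures)


@dataclass(frozen=True)
class PowerLawCurve:
    """Fitted curve ``d = a * dP**(1/(2n))``; callable on scalar or array dP."""

    a: float
    n: float

    def __call__(self, delta_P):
        return self.a * np.power(delta_P, 1.0 / (2.0 * self.n))


@dataclass(frozen=True)
class FitResult:
    """Outcome of a pressure–width fit.

    ``K`` is populated only when the fit was given the full nozzle geometry
    (including the tapered length) and travel speed; the coefficient ``a``
    alone is identifiable from the data.
    """

    a: float
    n: float
    SSR: float
    R2: float
    model: PowerLawCurve
    K: float | None = None

    def __post_init__(self) -> None:
        if self.SSR < 0:
            raise ValueError("SSR must be non-negative")
        if self.K is not None and not self.K > 0:
            raise ValueError("consistency index must be positive")


def aggregate_measurements(
    dataset: MeasurementDataset, convention: str = "line_mean"
) -> AggregatedSeries:
    """Collapse the measurement hierarchy to one (mean, sd) per pressure.

    ``convention="line_mean"`` (default, the protocol's own aggregation):
    positions are averaged into line means; line means, pooled across
    repeats, are averaged into the per-pressure mean, with sd and count
    taken over the line means.  ``convention="raw"`` averages all raw
    position-level widths per pressure instead.
    """
    if convention == "line_mean":
        per_line = dataset.line_means()
        grouped = per_line.groupby("pressure", sort=True)["line_mean"]
    elif convention == "raw":
        grouped = dataset.frame.groupby("pressure", sort=True)["width"]
    else:
        raise ValueError(f"unknown aggregation convention {convention!r}")

    stats = grouped.agg(["mean", "std", "count"])
    sd = stats["std"].to_numpy()
    sd = np.where(np.isnan(sd), 0.0, sd)  # single line: sd undefined -> 0
    return AggregatedSeries(
        pressures=stats.index.to_numpy(dtype=float),
        d_mean=stats["mean"].to_numpy(),
        d_sd=sd,
        m_lines=stats["count"].to_numpy(dtype=int),
    )


def _optimal_a(pressures: np.ndarray, widths: np.ndarray, n: float) -> tuple[float, float]:
    """Closed-form least-squares ``a`` at fixed ``n``, and the resulting SSR.

    Works in the scaled basis (p / p_max)^(1/2n) so the regressor stays in
    (0, 1] even at extreme exponents (1/2n is 50 at the lower n bound, where
    Pa-scale pressures overflow a direct power).
    """
    e = 1.0 / (2.0 * n)
    p_max = float(pressures.max())
    z = np.power(pressures / p_max, e)
    a_scaled = float(z @ widths) / float(z @ z)  # > 0: both factors positive
    resid = widths - a_scaled * z
    a = math.exp(math.log(a_scaled) - e * math.log(p_max))
    return a, float(resid @ resid)


def _with_K(
    a: float, n: float, SSR: float, R2: float, nozzle: Nozzle | None, U: float | None
) -> FitResult:
    K = None
    if nozzle is not None:
        if U is None:
            raise ValueError("travel speed U is required to convert a to K")
        K = consistency_from_coefficient(a, n, nozzle, U)
    return FitResult(a=a, n=n, SSR=SSR, R2=R2, model=PowerLawCurve(a=a, n=n), K=K)


def fit_power_law(
    series: AggregatedSeries, nozzle: Nozzle | None = None, U: float | None = None
) -> FitResult:
    """Free fit of ``d = a * dP**(1/(2n))`` over (a, n), minimising the SSR.

    ``a`` is profiled out in closed form at each ``n``, making the search
    one-dimensional; a fixed grid of seeds (n = 0.05 … 1.5, step 0.05)
    followed by bounded local refinement makes the optimiser deterministic.
    Ties break toward smaller ``n``.  Supplying ``nozzle`` (with full
    geometry) and ``U`` also reports the consistency index ``K``.

    Requires at least three distinct pressures; two points would make the
    exponent a closed-form identity and leave nothing to validate.
    """
    if len(series) < 3:
        raise ValueError(f"free (a, n) fit needs >= 3 distinct pressures, got {len(series)}")
    p = np.asarray(series.pressures, dtype=float)
    d = np.asarray(series.d_mean, dtype=float)

    def profiled_ssr(n: float) -> float:
        return _optimal_a(p, d, n)[1]

    best_n, best_ssr = None, math.inf
    for n_seed in _N_GRID:
        ssr = profiled_ssr(float(n_seed))
        if ssr < best_ssr * (1.0 - 1e-12):
            best_n, best_ssr = float(n_seed), ssr

    lo = max(N_MIN, best_n - 0.05)
    hi = min(N_MAX, best_n + 0.05)
    res = minimize_scalar(profiled_ssr, bounds=(lo, hi), method="bounded", options={"xatol": _XATOL})
    n_hat = float(res.x) if res.fun <= best_ssr else best_n
    # guard the working bounds and also refine across the full range once, in
    # case the optimum sits outside the seeded neighbourhood
    res_full = minimize_scalar(
        profiled_ssr, bounds=(N_MIN, N_MAX), method="bounded", options={"xatol": _XATOL}
    )
    if res_full.fun < profiled_ssr(n_hat):
        n_hat = float(res_full.x)

    a_hat, ssr = _optimal_a(p, d, n_hat)
    R2 = _r2_from_ssr(d, ssr)
    return _with_K(a_hat, n_hat, ssr, R2, nozzle, U)


def fit_fixed_n(
    series: AggregatedSeries,
    n_fixed: float,
    nozzle: Nozzle | None = None,
    U: float | None = None,
) -> FitResult:
    """Fit the coefficient ``a`` (closed form) with the exponent ``n`` held fixed."""
    if not (N_MIN <= n_fixed <= N_MAX):
        raise ValueError(f"n_fixed={n_fixed} outside working range [{N_MIN}, {N_MAX}]")
    if len(series) < 2:
        raise ValueError(f"fixed-n fit needs >= 2 distinct pressures, got {len(series)}")
    p = np.asarray(series.pressures, dtype=float)
    d = np.asarray(series.d_mean, dtype=float)
    a_hat, ssr = _optimal_a(p, d, n_fixed)
    R2 = _r2_from_ssr(d, ssr)
    return _with_K(a_hat, n_fixed, ssr, R2, nozzle, U)


def fit_newtonian(
    series: AggregatedSeries, nozzle: Nozzle | None = None, U: float | None = None
) -> FitResult:
    """Newtonian fit ``d = a * sqrt(dP)`` (the power law with n fixed at 1)."""
    return fit_fixed_n(series, 1.0, nozzle=nozzle, U=U)


def consistency_from_coefficient(a: float, n: float, nozzle: Nozzle, U: float) -> float:
    """Consistency index ``K`` (Pa·s^n) implied by a fitted coefficient ``a``.

    Inverts ``a**2 = (4n/(3n+1)) * (2 K I(n))**(-1/n) / U`` where ``I(n)`` is
    the nozzle's geometry integral; requires the full geometry including the
    tapered length.  Round-trips with :func:`coefficient_from_consistency`.
    """
    if not (a > 0 and U > 0):
        raise ValueError("coefficient a and travel speed U must be positive")
    I = geometry_integral(nozzle, n)
    log_2K = -n * (math.log(U) + 2.0 * math.log(a) - math.log(4.0 * n / (3.0 * n + 1.0)))
    return math.exp(log_2K) / (2.0 * I)


def coefficient_from_consistency(K: float, n: float, nozzle: Nozzle, U: float) -> float:
    """Coefficient ``a`` implied by material (n, K), geometry and travel speed."""
    return proportionality_coefficient(PowerLawFluid(n=n, K=K), nozzle, U)


def _r2_from_ssr(widths: np.ndarray, ssr: float) -> float:
    sst = float(np.sum((widths - widths.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("zero total sum of squares: all mean widths identical")
    return 1.0 - ssr / sst


def r_squared(series: AggregatedSeries, model: Callable[[np.ndarray], np.ndarray]) -> float:
    """Coefficient of determination of ``model`` against the per-pressure means."""
    if len(series) < 2:
        raise ValueError("R^2 needs at least 2 points")
    d = np.asarray(series.d_mean, dtype=float)
    pred = np.asarray(model(np.asarray(series.pressures, dtype=float)), dtype=float)
    ssr = float(np.sum((d - pred) ** 2))
    return _r2_from_ssr(d, ssr)


def average_index(fits: Iterable[FitResult | float]) -> float:
    """Arithmetic mean flow behaviour index across fits (or bare n values)."""
    ns = [f.n if isinstance(f, FitResult) else float(f) for f in fits]
    if not ns:
        raise ValueError("need at least one fit")
    return float(np.mean(ns))


def fit_rheometry(
    shear_rates: Sequence[float], viscosities: Sequence[float]
) -> tuple[float, float]:
    """Fit (n, K) to rheometer viscosity–shear-rate data.

    Ordinary least squares of ``ln mu`` on ``ln gamma_dot``: the slope is
    ``n - 1`` and the intercept ``ln K``, from the power-law viscosity
    ``mu = K * gamma_dot**(n-1)``.

    Returns
    -------
    (n, K) : tuple of float
    """
    g = np.asarray(shear_rates, dtype=float)
    mu = np.asarray(viscosities, dtype=float)
    if g.size < 2:
        raise ValueError("rheometry fit needs >= 2 points")
    if np.any(g <= 0) or np.any(mu <= 0):
        raise ValueError("shear rates and viscosities must be positive")
    slope, intercept = np.polyfit(np.log(g), np.log(mu), 1)
    return float(slope + 1.0), float(math.exp(intercept))
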