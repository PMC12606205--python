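"""Model-validation statistics: per-pressure residual t-tests with FDR control.

After fitting the pressure–width curve, the residual at each pressure is the
deviation of the measured line widths from the fitted prediction.  Each
pressure gets a one-sample, two-sided Student t-test of zero mean residual
(df = m - 1 over its m line means) and an uncorrected 95 % confidence
interval; the per-pressure p-values are then adjusted jointly with the
Benjamini–Hochberg step-up false-discovery-rate procedure.  A pressure is
flagged as a significant misfit when its adjusted q-value falls below alpha.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dataset import MeasurementDataset

__all__ = ["residual_tests", "fdr_adjust"]


def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values, in input order.

    Sort p ascending, take ``q_(i) = min_{j >= i} p_(j) * m / j`` capped at
    1, and un-sort.  Rejecting ``q < alpha`` reproduces the BH step-up rule
    at level alpha.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def residual_tests(
    dataset: MeasurementDataset,
    model: Callable[[np.ndarray], np.ndarray],
    alpha: float = 0.05,
    unit: str = "line_mean",
) -> pd.DataFrame:
    """Per-pressure residual statistics for a fitted pressure–width curve.

    Parameters
    ----------
    dataset : MeasurementDataset
        The width measurements (SI units).
    model : callable
        Fitted curve, pressure (Pa) -> predicted width (m); e.g. a
        :class:`~extruflow.fitting.PowerLawCurve`.
    alpha : float
        Significance level applied to the FDR-adjusted q-values.
    unit : {"line_mean", "raw"}
        Residual unit of analysis: per-line mean widths (default — the
        protocol's aggregation) or raw position-level widths.

    Returns
    -------
    pandas.DataFrame
        One row per pressure with columns ``pressure``, ``m`` (residual
        count), ``mean_residual``, ``ci95_half_width`` (uncorrected),
        ``t_stat``, ``p_value``, ``q_value`` (BH-adjusted) and
        ``significant`` (q < alpha).

    Notes
    -----
    A pressure whose residuals have zero variance carries no evidence of
    misfit and is assigned t = 0, p = 1 (this arises for noiseless
    synthetic data).  With a single residual the t-test is undefined and is
    treated the same way.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if unit == "line_mean":
        per = dataset.line_means().rename(columns={"line_mean": "width"})
    elif unit == "raw":
        per = dataset.frame[["pressure", "width"]]
    else:
        raise ValueError(f"unknown residual unit {unit!r}")

    rows = []
    for pressure, group in per.groupby("pressure", sort=True):
        widths = group["width"].to_numpy(dtype=float)
        m = widths.size
        resid = widths - float(model(np.asarray(pressure, dtype=float)))
        mean_r = float(resid.mean())
        if m < 2 or np.allclose(resid, resid[0]):
            t_stat, p_value, ci_half = 0.0, 1.0, np.nan if m < 2 else 0.0
        else:
            t_stat, p_value = stats.ttest_1samp(resid, 0.0)
            sem = resid.std(ddof=1) / np.sqrt(m)
            ci_half = float(stats.t.ppf(0.975, m - 1) * sem)
        rows.append(
            {
                "pressure": float(pressure),
                "m": int(m),
                "mean_residual": mean_r,
                "ci95_half_width": ci_half,
                "t_stat": float(t_stat),
                "p_value": float(p_value),
            }
        )

    out = pd.DataFrame(rows)
    out["q_value"] = fdr_adjust(out["p_value"].to_numpy())
    out["significant"] = out["q_value"] < alpha
    return out
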