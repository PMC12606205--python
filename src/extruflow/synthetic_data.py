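"""Synthetic width-vs-pressure datasets with known ground truth.

Emulates the validation experiment's structure — per-pressure repeated
prints, a fixed number of lines per print, and three width measurements per
line (start, middle, end) — so that fitting and residual statistics can be
exercised end-to-end without the original raw data.  Widths are the forward
model's prediction perturbed by independent Gaussian measurement noise
(multiplicative by default, matching spread that grows with width).

Defaults reproduce the room-temperature soft-colloid protocol: 5 mm/s
travel speed, gauge pressures 60–75, 77 and 80 kPa, 3 repeats x 9 lines x
3 positions, pressures quantised to the 1 kPa gauge display.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import MeasurementDataset
from .flow_model import PowerLawFluid, PrintingConditions, predict_diameter
from .nozzle_geometry import Nozzle, conical_from_gauge

__all__ = ["SyntheticConfig", "generate_dataset", "default_config", "MeasurementDataset"]

_POSITIONS_3 = ("start", "middle", "end")
#: floor applied to noisy widths so dataset invariants survive extreme draws, m
_WIDTH_FLOOR = 1e-6

#: gauge pressures of the 22G validation series, Pa
DEFAULT_PRESSURES = tuple(p * 1e3 for p in list(range(60, 76)) + [77, 80])


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground truth and replication structure for a synthetic experiment.

    Parameters
    ----------
    fluid : PowerLawFluid
        Ground-truth material.
    nozzle : Nozzle
        Nozzle geometry used by the forward model.
    U : float
        Travel speed, m/s.
    pressures : sequence of float
        Gauge pressure drops, Pa.
    repeats, lines_per_repeat, positions_per_line : int
        Replication counts (>= 1 each).
    noise_sd_rel : float
        Standard deviation of the Gaussian measurement noise, relative to
        the true width (multiplicative mode) or to the nozzle tip diameter
        (additive mode).
    noise_mode : {"multiplicative", "additive"}
    pressure_quantum : float or None
        Gauge display resolution, Pa; pressures are rounded to this quantum
        before the forward model is evaluated.  None disables rounding.
    seed : int or None
        Required whenever ``noise_sd_rel > 0``.
    """

    fluid: PowerLawFluid
    nozzle: Nozzle
    U: float = 5e-3
    pressures: Sequence[float] = DEFAULT_PRESSURES
    repeats: int = 3
    lines_per_repeat: int = 9
    positions_per_line: int = 3
    noise_sd_rel: float = 0.05
    noise_mode: str = "multiplicative"
    pressure_quantum: float | None = 1e3
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.U > 0:
            raise ValueError(f"travel speed must be positive, got U={self.U}")
        if len(self.pressures) == 0 or any(p <= 0 for p in self.pressures):
            raise ValueError("pressures must be a non-empty sequence of positive Pa values")
        for name in ("repeats", "lines_per_repeat", "positions_per_line"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.noise_sd_rel < 0:
            raise ValueError("noise_sd_rel must be non-negative")
        if self.noise_mode not in ("multiplicative", "additive"):
            raise ValueError(f"unknown noise mode {self.noise_mode!r}")
        if self.noise_sd_rel > 0 and self.seed is None:
            raise ValueError("a seed is required when noise_sd_rel > 0")


def default_config(seed: int | None = None, **overrides) -> SyntheticConfig:
    """Study-condition defaults: shear-thinning soft colloid, 22G conical tip.

    Ground truth n = 0.165 and K = 560 Pa·s^n; conical tip Do = 0.41 mm with
    the family's shared 4.02 mm inlet and an assumed 30 mm tapered length
    (tip length is manufacturer-specific and is a free choice here).  With
    these values the forward widths span ~0.37–0.89 mm over 60–80 kPa and
    the width-matching optimum sits at ~62 kPa, the behaviour the validation
    experiments observed for this tip.
    """
    params = dict(
        fluid=PowerLawFluid(n=0.165, K=560.0),
        nozzle=conical_from_gauge("22G", Lc=30e-3),
        seed=seed,
    )
    params.update(overrides)
    return SyntheticConfig(**params)


def _position_labels(k: int) -> list[str]:
    return list(_POSITIONS_3) if k == 3 else [f"pos{i}" for i in range(k)]


def generate_dataset(config: SyntheticConfig) -> MeasurementDataset:
    """Draw one synthetic experiment; identical seeds give identical datasets.

    Each position-level width is ``d_model * (1 + eps)`` (multiplicative
    mode) or ``d_model + eps * D_tip`` (additive mode) with
    ``eps ~ Normal(0, noise_sd_rel)`` drawn i.i.d. per position.
    Widths are floored at 1 um so the dataset invariants hold for any draw.
    """
    rng = np.random.default_rng(config.seed)
    labels = _position_labels(config.positions_per_line)

    records: dict[str, list] = {c: [] for c in ("pressure", "repeat", "line", "position", "width")}
    for pressure in config.pressures:
        p_eff = pressure
        if config.pressure_quantum:
            p_eff = round(pressure / config.pressure_quantum) * config.pressure_quantum
        d_true = predict_diameter(
            config.fluid, config.nozzle, PrintingConditions(delta_P=p_eff, U=config.U)
        )
        n_draws = config.repeats * config.lines_per_repeat * config.positions_per_line
        eps = rng.normal(0.0, config.noise_sd_rel, size=n_draws) if config.noise_sd_rel > 0 else np.zeros(n_draws)
        if config.noise_mode == "multiplicative":
            widths = d_true * (1.0 + eps)
        else:
            # additive: constant absolute sd across pressures, scaled off the
            # tip diameter rather than the (pressure-dependent) true width
            widths = d_true + eps * config.nozzle.tip_diameter
        widths = np.maximum(widths, _WIDTH_FLOOR)

        i = 0
        for repeat in range(1, config.repeats + 1):
            for line in range(1, config.lines_per_repeat + 1):
                for pos in labels:
                    records["pressure"].append(p_eff)
                    records["repeat"].append(repeat)
                    records["line"].append(line)
                    records["position"].append(pos)
                    records["width"].append(float(widths[i]))
                    i += 1

    return MeasurementDataset(pd.DataFrame(records))
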