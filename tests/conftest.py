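import numpy as np
import pandas as pd
import pytest

from extruflow import (
    ConicalNozzle,
    MeasurementDataset,
    PowerLawFluid,
    StraightNozzle,
)


@pytest.fixture
def conical_22g() -> ConicalNozzle:
    """22G conical tip (0.41 mm outlet) with the shared 4.02 mm inlet."""
    return ConicalNozzle(Di=4.02e-3, Do=0.41e-3, Lc=30e-3)


@pytest.fixture
def conical_25g() -> ConicalNozzle:
    """25G conical tip (0.25 mm outlet)."""
    return ConicalNozzle(Di=4.02e-3, Do=0.25e-3, Lc=30e-3)


@pytest.fixture
def straight_nozzle() -> StraightNozzle:
    return StraightNozzle(DN=4e-4, LN=0.01)


@pytest.fixture
def shear_thinning_fluid() -> PowerLawFluid:
    """Soft-colloid-like ground truth used across recovery tests."""
    return PowerLawFluid(n=0.165, K=560.0)


@pytest.fixture
def newtonian_fluid() -> PowerLawFluid:
    return PowerLawFluid.newtonian(1.0)


def _make_dataset(rows) -> MeasurementDataset:
    """Build a MeasurementDataset from (pressure, repeat, line, position, width) tuples."""
    return MeasurementDataset(
        pd.DataFrame(rows, columns=["pressure", "repeat", "line", "position", "width"])
    )


@pytest.fixture
def make_dataset():
    return _make_dataset


@pytest.fixture
def tiny_dataset() -> MeasurementDataset:
    """One pressure, one line, three positions (hand-checkable aggregation)."""
    return _make_dataset(
        [
            (6.2e4, 1, 1, "start", 0.30e-3),
            (6.2e4, 1, 1, "middle", 0.32e-3),
            (6.2e4, 1, 1, "end", 0.34e-3),
        ]
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)
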