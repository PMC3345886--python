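import numpy as np
import pytest

from favsdm import (DetectionGrid, EnvironmentalGrid, SimulationTruth,
                    generate_landscape)


@pytest.fixture
def small_grid() -> EnvironmentalGrid:
    """Deterministic 4x5 grid with two covariates and no mask."""
    rng = np.random.default_rng(42)
    return EnvironmentalGrid({
        "Prec": rng.uniform(500, 1500, (4, 5)),
        "Temp": rng.uniform(-2, 12, (4, 5)),
    })


@pytest.fixture
def recovery_truth() -> SimulationTruth:
    """Linear two-covariate truth used for parameter-recovery experiments."""
    return SimulationTruth(
        intercept=-0.3,
        coefficients={"x1": 0.8, "x2": -0.5},
        covariate_ranges={"train": {"x1": (-2.0, 2.0), "x2": (-2.0, 2.0)}},
        autocorrelation_range=2.0,
        seed=0,
    )


@pytest.fixture
def fitted_landscape(recovery_truth):
    """A 40x40 landscape plus its generating truth, for fit/evaluate tests."""
    grid, det = generate_landscape(recovery_truth, 40, 40)
    return grid, det, recovery_truth


def make_detections(outcomes) -> DetectionGrid:
    return DetectionGrid(np.asarray(outcomes, dtype=float))
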