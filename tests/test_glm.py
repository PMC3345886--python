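"""Favourability transform and logistic fitting against closed-form,
hand-computed and simulation-truth oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from favsdm import (CoefficientSet, InputError, SeparationWarning,
                    favourability, favourability_from_logit,
                    favourability_surface, fit_logistic, forward_stepwise,
                    generate_landscape, linear_predictor, published_models,
                    read_coefficients_csv, write_coefficients_csv)
from favsdm.grids import DetectionGrid, EnvironmentalGrid
from favsdm.synthetic import SimulationTruth


# ---------------------------------------------------------------------------
# favourability transform
# ---------------------------------------------------------------------------

def test_favourability_hand_example():
    # odds(0.8) = 4; prevalence odds 1/3; F = 4 / (1/3 + 4) = 12/13
    assert favourability(0.8, 100, 300) == pytest.approx(12 / 13, abs=1e-12)


def test_favourability_identity_at_equal_prevalence():
    p = np.linspace(0.0, 1.0, 1001)
    f = favourability(p, 57, 57)
    assert np.abs(f - p).max() <= 1e-12


@pytest.mark.parametrize("n1,n0", [(1, 1), (10, 40), (100, 300), (7, 3),
                                   (1576, 424)])
def test_favourability_half_at_training_prevalence(n1, n0):
    assert favourability(n1 / (n1 + n0), n1, n0) == pytest.approx(0.5,
                                                                  abs=1e-12)


@given(p=st.floats(0.001, 0.999), n1=st.integers(1, 500),
       n0=st.integers(1, 500))
@settings(deadline=None, max_examples=100, derandomize=True)
def test_favourability_monotone_in_p_and_prevalence(p, n1, n0):
    f = favourability(p, n1, n0)
    assert 0.0 <= f <= 1.0
    # strictly increasing in P
    assert favourability(min(p + 1e-4, 0.9995), n1, n0) > f
    # strictly decreasing in the prevalence odds n1/n0 at fixed P
    assert favourability(p, n1 + 1, n0) < f


def test_favourability_rejects_bad_inputs():
    with pytest.raises(InputError):
        favourability(0.5, 0, 10)
    with pytest.raises(InputError):
        favourability(0.5, 10, -1)
    with pytest.raises(InputError):
        favourability(1.2, 10, 10)


def test_favourability_from_logit_agrees_with_probability_form():
    # |y| <= 25 keeps expit(y) clear of the probability-form guard clip
    y = np.linspace(-25, 25, 401)
    from scipy.special import expit
    np.testing.assert_allclose(favourability_from_logit(y, 30, 70),
                               favourability(expit(y), 30, 70), atol=1e-12)


# ---------------------------------------------------------------------------
# linear predictor
# ---------------------------------------------------------------------------

def _zero_grid(variables):
    return EnvironmentalGrid({v: np.zeros((2, 2)) for v in variables})


def test_spanish_constant_on_all_zero_covariates():
    spanish = published_models()[0]
    y = linear_predictor(spanish, _zero_grid(spanish.variables))
    np.testing.assert_allclose(y, -44.63)


def test_constant_model_everywhere(small_grid):
    coefs = CoefficientSet(intercept=2.5, coefficients={})
    np.testing.assert_array_equal(linear_predictor(coefs, small_grid), 2.5)


def test_linear_predictor_matches_extended_precision_dot_product():
    rng = np.random.default_rng(8)
    variables = [f"v{i}" for i in range(5)]
    grid = EnvironmentalGrid({v: rng.normal(size=(6, 7)) for v in variables})
    betas = dict(zip(variables, rng.normal(size=5)))
    coefs = CoefficientSet(intercept=rng.normal(), coefficients=betas)
    y = linear_predictor(coefs, grid)
    # oracle: term-by-term accumulation in long double per cell
    expected = np.full(grid.shape, np.longdouble(coefs.intercept))
    for v in variables:
        expected = expected + np.longdouble(betas[v]) * grid.layer(v).astype(
            np.longdouble)
    assert np.abs(y - expected.astype(float)).max() < 1e-12


def test_linear_predictor_names_missing_variable(small_grid):
    coefs = CoefficientSet(intercept=0.0, coefficients={"SRad": 1.0})
    with pytest.raises(InputError, match="SRad"):
        linear_predictor(coefs, small_grid)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def test_intercept_only_fit_is_log_prevalence_odds(fitted_landscape):
    grid, det, _ = fitted_landscape
    m = fit_logistic(grid, det, [])
    assert m.intercept == pytest.approx(np.log(det.n1 / det.n0), abs=1e-12)
    assert (m.n1, m.n0) == (det.n1, det.n0)


def test_null_data_recovers_zero_slopes():
    rng = np.random.default_rng(0)
    grid = EnvironmentalGrid({"a": rng.normal(size=(50, 50)),
                              "b": rng.normal(size=(50, 50))})
    det = DetectionGrid((rng.random((50, 50)) < 0.4).astype(float))
    m = fit_logistic(grid, det, ["a", "b"])
    for v in ("a", "b"):
        assert abs(m.coefficients[v]) < 3 * m.se[v]


def test_parameter_recovery_within_3se(recovery_truth):
    """Fitted coefficients bracket the generating truth at 3 estimated SE
    (oracle: the simulation truth itself); 10-replicate spot check."""
    hits = 0
    for rep in range(10):
        truth = SimulationTruth(**{**recovery_truth.__dict__, "seed": rep})
        grid, det = generate_landscape(truth, 50, 100)
        m = fit_logistic(grid, det, ["x1", "x2"])
        ok = abs(m.intercept - truth.intercept) < 3 * m.intercept_se
        for v, beta in truth.coefficients.items():
            ok &= abs(m.coefficients[v] - beta) < 3 * m.se[v]
        hits += ok
    assert hits >= 9


def test_training_ranges_recorded(fitted_landscape):
    grid, det, _ = fitted_landscape
    m = fit_logistic(grid, det, ["x1"])
    lo, hi = m.training_ranges["x1"]
    assert lo == grid.layer("x1").min() and hi == grid.layer("x1").max()


def test_constant_covariate_rejected(fitted_landscape):
    grid, det, _ = fitted_landscape
    grid2 = EnvironmentalGrid({"x1": grid.layer("x1"),
                               "flat": np.ones(grid.shape)})
    with pytest.raises(InputError, match="flat"):
        fit_logistic(grid2, det, ["x1", "flat"])


def test_single_class_outcomes_rejected(fitted_landscape):
    grid, _, _ = fitted_landscape
    det = DetectionGrid(np.ones(grid.shape))
    with pytest.raises(InputError):
        fit_logistic(grid, det, ["x1"])


def test_complete_separation_warns():
    x = np.linspace(-1, 1, 100).reshape(10, 10)
    grid = EnvironmentalGrid({"x": x})
    det = DetectionGrid((x > 0).astype(float))
    with pytest.warns(SeparationWarning):
        fit_logistic(grid, det, ["x"])


# ---------------------------------------------------------------------------
# stepwise selection
# ---------------------------------------------------------------------------

def _stepwise_landscape(seed):
    truth = SimulationTruth(
        intercept=0.0, coefficients={"signal": 2.0},
        covariate_ranges={"train": {"signal": (-2.0, 2.0),
                                    "noise1": (-2.0, 2.0),
                                    "noise2": (-2.0, 2.0),
                                    "noise3": (-2.0, 2.0)}},
        autocorrelation_range=2.0, seed=seed)
    return generate_landscape(truth, 40, 40)


def test_stepwise_picks_true_signal_first():
    grid, det = _stepwise_landscape(4)
    m = forward_stepwise(grid, det, ["noise1", "signal", "noise2", "noise3"])
    assert m.inclusion_order["signal"] == 1


def test_stepwise_ranks_are_a_permutation():
    grid, det = _stepwise_landscape(5)
    m = forward_stepwise(grid, det, ["noise1", "signal", "noise2", "noise3"])
    ranks = sorted(m.inclusion_order.values())
    assert ranks == list(range(1, len(ranks) + 1))
    assert m.rank_warnings() == []
    assert set(m.inclusion_order) == set(m.variables)


def test_stepwise_zero_alpha_admits_nothing():
    grid, det = _stepwise_landscape(6)
    m = forward_stepwise(grid, det, ["signal", "noise1"], entry_alpha=0.0)
    assert m.coefficients == {}
    assert m.intercept == pytest.approx(np.log(det.n1 / det.n0), abs=1e-12)


def test_stepwise_empty_candidates_rejected(fitted_landscape):
    grid, det, _ = fitted_landscape
    with pytest.raises(InputError):
        forward_stepwise(grid, det, [])


def test_stepwise_aic_mode_selects_signal():
    grid, det = _stepwise_landscape(7)
    m = forward_stepwise(grid, det, ["noise1", "signal"], criterion="aic")
    assert m.inclusion_order["signal"] == 1


# ---------------------------------------------------------------------------
# favourability surfaces
# ---------------------------------------------------------------------------

def test_constant_surface_at_equal_prevalence(small_grid):
    coefs = CoefficientSet(intercept=0.0, coefficients={}, n1=50, n0=50)
    surf = favourability_surface(coefs, small_grid)
    np.testing.assert_allclose(surf.values, 0.5)


def test_surface_monotone_in_positive_covariate(fitted_landscape):
    grid, det, _ = fitted_landscape
    m = fit_logistic(grid, det, ["x1", "x2"])
    surf = favourability_surface(m, grid)
    bumped = EnvironmentalGrid({"x1": grid.layer("x1") + 0.5,
                                "x2": grid.layer("x2")})
    surf2 = favourability_surface(m, bumped)
    sign = np.sign(m.coefficients["x1"])
    assert np.all(sign * (surf2.values - surf.values) > 0)


def test_surface_matches_unfused_recomputation(fitted_landscape):
    grid, det, _ = fitted_landscape
    m = fit_logistic(grid, det, ["x1", "x2"])
    surf = favourability_surface(m, grid)
    from scipy.special import expit
    expected = favourability(expit(linear_predictor(m, grid)), m.n1, m.n0)
    assert np.abs(surf.values - expected).max() < 1e-12
    assert np.isfinite(surf.values).all()
    assert surf.values.min() >= 0 and surf.values.max() <= 1


def test_surface_requires_prevalence_for_published_models(small_grid):
    coefs = CoefficientSet(intercept=0.0, coefficients={}, n1=None, n0=None)
    with pytest.raises(InputError, match="n1"):
        favourability_surface(coefs, small_grid)


# ---------------------------------------------------------------------------
# CoefficientSet IO
# ---------------------------------------------------------------------------

def test_fitted_model_round_trips_through_csv(tmp_path, fitted_landscape):
    grid, det, _ = fitted_landscape
    m = forward_stepwise(grid, det, ["x1", "x2"])
    p = tmp_path / "model.csv"
    write_coefficients_csv(p, m)
    back = read_coefficients_csv(p)
    assert back.label == m.label
    assert back.inclusion_order == m.inclusion_order
    assert (back.n1, back.n0) == (m.n1, m.n0)
    assert back.intercept == pytest.approx(m.intercept, rel=1e-12)
    for v in m.variables:
        assert back.coefficients[v] == m.coefficients[v]
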