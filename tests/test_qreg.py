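"""Check-loss minimization, estimator API, screening and fit comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

import rygbtraj as rt
from rygbtraj.exceptions import (
    ConfigurationError,
    EmptyInputError,
    InvalidInputError,
    RankError,
    SchemaError,
)
from rygbtraj.model import design_matrix
from rygbtraj.qreg import QuantileTrajectoryRegressor


def brute_force_quantile(y, tau):
    """Independent oracle: scan the check loss over the sample values and
    return the smallest value attaining the minimum (lowest-minimizer rule)."""
    y = np.sort(np.asarray(y, dtype=float))
    losses = np.array([rt.check_loss(y - c, tau) for c in y])
    return float(y[np.flatnonzero(losses <= losses.min() + 1e-12)[0]])


@pytest.mark.parametrize(
    "residuals, tau, expected",
    [([1, -1], 0.5, 0.5), ([1, -1], 0.25, 0.5), ([0, 0, 0], 0.7, 0.0)],
)
def test_check_loss(residuals, tau, expected):
    assert rt.check_loss(residuals, tau) == pytest.approx(expected, abs=1e-15)


def test_check_loss_empty():
    with pytest.raises(EmptyInputError):
        rt.check_loss([], 0.5)


@pytest.mark.parametrize(
    "y, tau, expected",
    [
        ([1, 2, 3], 0.5, 2.0),
        ([1, 2, 3, 4], 0.5, 2.0),  # flat optimum [2, 3]: lowest minimizer
        (list(range(101)), 0.25, 25.0),
    ],
)
def test_intercept_only_fits(y, tau, expected):
    res = rt.fit_quantile(np.ones((len(y), 1)), y, tau)
    assert res.beta[0] == pytest.approx(expected, abs=1e-6)
    assert res.converged and res.loss >= 0


def test_intercept_only_matches_brute_force_oracle():
    rng = np.random.default_rng(123)
    for _ in range(40):
        n = int(rng.integers(2, 21))
        y = np.round(rng.normal(size=n), 2)  # rounding induces ties/flat optima
        tau = float(rng.choice(np.arange(0.1, 0.95, 0.1)))
        fit = rt.fit_quantile(np.ones((n, 1)), y, tau)
        assert fit.beta[0] == pytest.approx(brute_force_quantile(y, tau), abs=1e-6)


def _toy_design(n=120, seed=0):
    rng = np.random.default_rng(seed)
    bmi0 = rng.uniform(36, 70, n)
    age = rng.uniform(20, 70, n)
    t = rng.uniform(0, 36, n)
    D = design_matrix(bmi0, age, t)
    y = D @ np.array([36.0, 0.7, 0.03, -0.9, 0.04, -0.0005, -0.005, 0.0015])
    y = y + rng.normal(0, 2.0, n)
    return D, y


def test_equivariance_scaling_and_shift():
    D, y = _toy_design()
    base = rt.fit_quantile(D, y, 0.25).beta
    scaled = rt.fit_quantile(D, 3.0 * y, 0.25).beta
    assert scaled == pytest.approx(3.0 * base, abs=1e-5)
    shifted = rt.fit_quantile(D, y + 7.0, 0.25).beta
    expected = base.copy()
    expected[0] += 7.0
    assert shifted == pytest.approx(expected, abs=1e-5)


def test_fitted_loss_never_exceeds_truth_loss(recovery_cohort, recovery_fit, published_ms):
    """Optimality: the minimized check loss is ≤ the loss of the generating
    coefficients on the same data."""
    X, y, _ = recovery_cohort.regression_arrays()
    D = design_matrix(X[:, 0], X[:, 1], X[:, 2])
    for fitted, truth in zip(recovery_fit.entries, published_ms.entries):
        tau = fitted.tau
        loss_fit = rt.check_loss(y - D @ fitted.as_array(), tau)
        loss_truth = rt.check_loss(y - D @ truth.as_array(), tau)
        assert loss_fit <= loss_truth + 1e-10


def test_recovery_rmse_shrinks_with_n(published_ms):
    """Coefficient recovery error decreases as the cohort grows."""
    errs = []
    for n, seed in ((500, 61), (2000, 62), (8000, 63)):
        ms = rt.fit_modelset(rt.generate_cohort(rt.CohortSpec(n_patients=n, seed=seed)))
        diffs = []
        for fit, truth in zip(ms.entries, published_ms.entries):
            diffs.extend(
                [fit.b0 - truth.b0, fit.b_bmi - truth.b_bmi, fit.b_age - truth.b_age]
            )
        errs.append(float(np.sqrt(np.mean(np.square(diffs)))))
    assert errs[2] < errs[0]
    assert errs[2] < 0.1


def test_rank_deficiency_detected():
    D = np.ones((20, 2))  # duplicated intercept column
    with pytest.raises(RankError):
        rt.fit_quantile(D, np.arange(20.0), 0.5)


def test_fit_quantile_validation():
    with pytest.raises(InvalidInputError):
        rt.fit_quantile(np.ones((5, 1)), np.arange(5.0), 1.5)
    with pytest.raises(EmptyInputError):
        rt.fit_quantile(np.ones((0, 1)), np.array([]), 0.5)


def test_estimator_api(small_cohort):
    est = QuantileTrajectoryRegressor(taus=(0.5,))
    assert clone(est).get_params()["taus"] == (0.5,)
    X, y, pid = small_cohort.regression_arrays()
    est.fit(X, y, patient_ids=pid)
    assert est.coef_.shape == (1, 8)
    assert est.model_set_.taus == (0.5,)
    pred = est.predict(X[:5])
    assert pred.shape == (5, 1)
    assert est.n_patients_ == small_cohort.n_patients


def test_duplicate_taus_rejected(small_cohort):
    with pytest.raises(SchemaError):
        rt.fit_modelset(small_cohort, taus=(0.5, 0.5))
    with pytest.raises(SchemaError):
        rt.fit_modelset(small_cohort, taus=(0.5, 0.25))


def test_patient_weighting_requires_ids(small_cohort):
    est = QuantileTrajectoryRegressor(patient_weighting=True)
    X, y, _ = small_cohort.regression_arrays()
    with pytest.raises(ConfigurationError):
        est.fit(X, y)


def test_screening_on_generator_truth(screening_cohort):
    """Baseline BMI drives both outcomes strongly; sex and diabetes are null
    covariates and are never retained; the age signal is directionally
    consistent and significant but weak under these conditions."""
    tab = rt.screen_covariates(screening_cohort, threshold=0.1).set_index("covariate")
    assert bool(tab.loc["bmi_baseline", "retained"])
    assert not bool(tab.loc["sex", "retained"])
    assert not bool(tab.loc["diabetes", "retained"])
    age = tab.loc["age"]
    assert np.sign(age["effect_6mo"]) == -np.sign(age["effect_nadir"])
    assert age["p_6mo"] < 0.01 and age["p_nadir"] < 0.01
    lower = rt.screen_covariates(screening_cohort, threshold=0.05).set_index("covariate")
    assert bool(lower.loc["age", "retained"])


def test_screening_zero_threshold_keeps_consistent_signs(screening_cohort):
    tab = rt.screen_covariates(screening_cohort, threshold=0.0).set_index("covariate")
    assert bool(tab.loc["bmi_baseline", "retained"])
    assert bool(tab.loc["age", "retained"])


def test_compare_fits_identity_and_shift(published_ms):
    same = rt.compare_fits(published_ms, published_ms)
    assert np.allclose(same["max_abs_diff"], 0)
    shifted_entries = list(published_ms.entries)
    e = shifted_entries[1]
    shifted_entries[1] = rt.QuantileCoefficients.from_array(
        e.tau, e.as_array() + np.array([1.0, 0, 0, 0, 0, 0, 0, 0])
    )
    shifted = rt.ModelSet(tuple(shifted_entries))
    out = rt.compare_fits(published_ms, shifted).set_index("tau")
    assert out.loc[0.5, "max_abs_diff"] == pytest.approx(1.0, abs=1e-12)
    assert out.loc[0.5, "mean_abs_diff"] == pytest.approx(1.0, abs=1e-12)
    assert out.loc[0.25, "max_abs_diff"] == 0


def test_compare_fits_tau_mismatch(published_ms):
    single = rt.ModelSet((published_ms.entries[1],))
    with pytest.raises(ConfigurationError):
        rt.compare_fits(published_ms, single)
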