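"""Synthetic cohort generator: demographics, inverse CDF, dropout, determinism."""

import numpy as np
import pytest
from scipy.stats import truncnorm

import rygbtraj as rt
from rygbtraj.exceptions import ConfigurationError, CrossingError, InvalidInputError
from rygbtraj.simulate import (
    _ranks,
    calibrate_dropout,
    interval_survival_ratios,
)


def test_profiles_respect_truncation_and_determinism():
    spec = rt.CohortSpec(n_patients=1000, seed=4)
    profiles = rt.sample_profiles(spec)
    ages = np.array([p.age for p in profiles])
    bmis = np.array([p.bmi_baseline for p in profiles])
    assert ages.min() >= 18 and ages.max() <= 74
    assert bmis.min() >= 35 and bmis.max() <= 95
    again = rt.sample_profiles(spec)
    assert [p.age for p in again] == pytest.approx(ages)


def test_profile_means_match_truncated_normal():
    """Oracle: the analytic mean of the truncated normal via scipy."""
    spec = rt.CohortSpec(n_patients=10000, seed=8)
    profiles = rt.sample_profiles(spec)
    a, b = (18 - 45.8) / 11.2, (74 - 45.8) / 11.2
    expected = truncnorm.mean(a, b, loc=45.8, scale=11.2)
    assert np.mean([p.age for p in profiles]) == pytest.approx(expected, abs=0.5)
    frac_female = np.mean([p.sex == "female" for p in profiles])
    assert frac_female == pytest.approx(0.81, abs=0.02)


def test_impossible_truncation_bounds():
    with pytest.raises(ConfigurationError):
        rt.sample_profiles(rt.CohortSpec(n_patients=5, age_mean=10.0, age_sd=0.0))


def test_inverse_cdf_knot_identity(published_ms):
    for tau, expected in zip((0.25, 0.5, 0.75), (34.43, 36.71, 39.11)):
        assert rt.inverse_cdf(published_ms, 50, 50, 6, tau) == pytest.approx(expected, abs=1e-12)


def test_inverse_cdf_interpolation_midpoint(published_ms):
    assert rt.inverse_cdf(published_ms, 50, 50, 6, 0.375) == pytest.approx(
        (34.43 + 36.71) / 2, abs=1e-9
    )


def test_inverse_cdf_monotone_including_tails(published_ms):
    u = np.linspace(0.005, 0.995, 199)
    vals = rt.inverse_cdf(published_ms, 55, 40, 12, u)
    assert np.all(np.diff(vals) > 0)
    # tails continue smoothly from the outer knots
    assert vals[0] < rt.inverse_cdf(published_ms, 55, 40, 12, 0.25)
    assert vals[-1] > rt.inverse_cdf(published_ms, 55, 40, 12, 0.75)


def test_inverse_cdf_rejects_crossing():
    crossed = rt.ModelSet(
        (
            rt.QuantileCoefficients(0.25, 40.0, 0.7, 0.03, -1, 0.04, -0.0005, -0.007, 0.0016),
            rt.QuantileCoefficients(0.50, 36.0, 0.7, 0.03, -1, 0.04, -0.0005, -0.007, 0.0016),
        )
    )
    with pytest.raises(CrossingError):
        rt.inverse_cdf(crossed, 50, 50, 6, 0.4)


def test_inverse_cdf_rejects_bad_u(published_ms):
    with pytest.raises(InvalidInputError):
        rt.inverse_cdf(published_ms, 50, 50, 6, 0.0)


def test_rank_persistence_limits():
    rng = np.random.default_rng(0)
    shared, _ = _ranks(rng, 5, 8, 1.0)
    assert np.all(shared == shared[:, [0]])  # one latent percentile per patient
    rng = np.random.default_rng(0)
    indep, _ = _ranks(rng, 2000, 2, 0.0)
    r = np.corrcoef(indep[:, 0], indep[:, 1])[0, 1]
    assert abs(r) < 0.06  # visit ranks decorrelate entirely


def test_ranks_are_marginally_uniform():
    rng = np.random.default_rng(1)
    ranks, _ = _ranks(rng, 20000, 1, 0.8)
    q = np.quantile(ranks[:, 0], [0.25, 0.5, 0.75])
    assert q == pytest.approx([0.25, 0.5, 0.75], abs=0.015)


def test_sample_trajectory_single_quantile_when_persistent(published_ms):
    spec = rt.CohortSpec(n_patients=1, seed=0, persistence=1.0, jitter_days=0.0)
    profile = rt.PatientProfile(age=50, height=1.7, bmi_baseline=50.0, weight_baseline=50 * 1.7**2)
    series = rt.sample_trajectory(profile, spec, np.random.default_rng(10))
    bmi = series.weights / 1.7**2
    # invert each visit's BMI back to its rank: all equal under persistence 1
    from scipy.optimize import brentq

    us = [
        brentq(lambda u, t=t, b=b: rt.inverse_cdf(published_ms, 50, 50, t, u) - b, 1e-4, 1 - 1e-4)
        for t, b in zip(series.times, bmi)
    ]
    assert np.ptp(us) < 1e-8


def test_dropout_targets_all_one_removes_nothing():
    spec = rt.CohortSpec(n_patients=1, seed=0, attrition_targets=(1.0, 1.0, 1.0))
    series = rt.WeightSeries.from_pairs([(t, 100.0) for t in spec.schedule])
    out = rt.apply_dropout(series, spec, 99)
    assert len(out) == len(series)


def test_dropout_always_keeps_first_visit():
    spec = rt.CohortSpec(n_patients=1, seed=0, attrition_targets=(0.05, 0.04, 0.03))
    series = rt.WeightSeries.from_pairs([(t, 100.0) for t in spec.schedule])
    for seed in range(20):
        out = rt.apply_dropout(series, spec, seed)
        assert len(out) >= 1
        assert out.times[0] == series.times[0]


def test_interval_survival_ratios():
    ratios = interval_survival_ratios((0.88, 0.77, 0.53))
    assert ratios == pytest.approx((0.88, 0.77 / 0.88, 0.53 / 0.77))
    assert ratios[1] == pytest.approx(0.875, abs=1e-9)
    assert ratios[2] == pytest.approx(0.688, abs=5e-4)


def test_calibrated_hazard_is_monotone_structure():
    hz = calibrate_dropout(rt.CohortSpec(n_patients=1, seed=0))
    assert np.all(np.diff(hz.edges) > 0)
    assert np.all(hz.rates >= 0)
    # survival decreases over the horizons
    s = [hz.survival(t) for t in (6, 12, 24)]
    assert s[0] > s[1] > s[2]


def test_empirical_retention_matches_targets(retention_cohort):
    last = retention_cohort.measurements.groupby("patient_id")["months_post_op"].max()
    for horizon, target in zip((6, 12, 24), (0.88, 0.77, 0.53)):
        assert (last > horizon).mean() == pytest.approx(target, abs=0.02)


def test_retention_is_monotone_in_horizon(retention_cohort):
    last = retention_cohort.measurements.groupby("patient_id")["months_post_op"].max()
    fracs = [(last > h).mean() for h in (6, 12, 24)]
    assert fracs[0] >= fracs[1] >= fracs[2]


def test_conditional_quantiles_match_truth(fidelity_bmis):
    q = np.quantile(fidelity_bmis, [0.25, 0.5, 0.75])
    assert q == pytest.approx([34.43, 36.71, 39.11], abs=0.3)


def test_rank_covariate_independence(retention_cohort):
    """Residuals from the median truth curve do not track the covariates."""
    ms = rt.published_model()
    merged = retention_cohort.measurements.merge(retention_cohort.profiles)
    from rygbtraj.model import design_matrix

    D = design_matrix(
        merged["bmi_baseline"], merged["age"], merged["months_post_op"]
    )
    resid = (
        merged["weight_kg"] / merged["height_m"] ** 2 - D @ ms.entries[1].as_array()
    )
    by_patient = (
        merged.assign(resid=resid).groupby("patient_id")[["resid", "bmi_baseline", "age"]].mean()
    )
    assert abs(np.corrcoef(by_patient["resid"], by_patient["bmi_baseline"])[0, 1]) < 0.05
    assert abs(np.corrcoef(by_patient["resid"], by_patient["age"])[0, 1]) < 0.05


def test_generate_cohort_reproducible_and_complete(tmp_path):
    spec = rt.CohortSpec(n_patients=50, seed=7)
    c1, c2 = rt.generate_cohort(spec), rt.generate_cohort(spec)
    p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
    rt.write_cohort(p1, c1)
    rt.write_cohort(p2, c2)
    assert p1.read_bytes() == p2.read_bytes()
    assert c1.n_patients == 50
    counts = c1.measurements.groupby("patient_id").size()
    assert len(counts) == 50 and counts.min() >= 1


def test_spec_validation():
    with pytest.raises(ConfigurationError):
        rt.CohortSpec(n_patients=0)
    with pytest.raises(ConfigurationError):
        rt.CohortSpec(n_patients=5, persistence=1.5)
    with pytest.raises(ConfigurationError):
        rt.CohortSpec(n_patients=5, attrition_targets=(0.5, 0.8, 0.3))
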