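"""Synthetic longitudinal post-RYGB cohorts for testing fitting and tracking.

The generator emulates the study conditions of a large single-center RYGB
cohort: ages ~ truncated Normal(45.8, 11.2²) on [18, 74]; baseline BMI ~
truncated Normal(49.5, 8.7²) on [35, 95]; 81% female; a clinic visit
schedule of 1 wk, 2 wk, 2, 5, 8, 12 months and then every 6 months out to
36; and progressive attrition calibrated so the expected fractions of
patients with any measurement beyond 6/12/24 months are 88%/77%/53%.

Conditional BMI quantiles follow a truth :class:`~rygbtraj.model.ModelSet`
exactly: each measurement's BMI is the inverse conditional CDF — piecewise
linear between the model's (τ, BMI) knots, Gaussian tails anchored at the
outer knots — evaluated at a per-visit rank. Ranks come from a Gaussian
copula, ``rank = Φ(√w·Z_patient + √(1−w)·ε_visit)``, so each visit's rank
is exactly Uniform(0,1) marginally (conditional quantiles are undistorted)
while a patient largely tracks one percentile when the persistence weight
``w`` is near 1.

Dropout is a piecewise-constant-hazard censoring time; visits after the
censoring time are removed (the first visit is always kept). Hazard rates
are solved numerically, accounting for the discrete visit schedule and the
±10-day visit jitter, so the expected empirical retention matches the
targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import ndtr, ndtri

from .anthro import PatientProfile, WeightSeries
from .cohort import Cohort
from .exceptions import ConfigurationError, CrossingError, InvalidInputError
from .model import DAYS_PER_MONTH, ModelSet, published_model

__all__ = [
    "CohortSpec",
    "sample_profiles",
    "inverse_cdf",
    "sample_trajectory",
    "apply_dropout",
    "generate_cohort",
    "interval_survival_ratios",
]

_RANK_CLIP = 1e-3  # ranks clipped to (1e-3, 1 - 1e-3): only three quantiles are
# published, so extreme tails are deliberately never exercised

DEFAULT_SCHEDULE = (0.25, 0.5, 2.0, 5.0, 8.0, 12.0, 18.0, 24.0, 30.0, 36.0)


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one simulated cohort.

    Defaults are the study-cohort values (demographics, visit schedule,
    attrition); the truth model defaults to the packaged published
    coefficients. ``persistence`` in [0, 1] is the within-patient
    rank-persistence weight (1 → a patient rides a single percentile,
    0 → independent ranks per visit). Height is not reported by the study;
    its Normal(1.66, 0.09²) m distribution truncated to [1.4, 2.1] is a
    package choice so weights are derivable from BMI.
    """

    n_patients: int
    seed: int = 0
    age_mean: float = 45.8
    age_sd: float = 11.2
    age_range: tuple[float, float] = (18.0, 74.0)
    bmi_mean: float = 49.5
    bmi_sd: float = 8.7
    bmi_range: tuple[float, float] = (35.0, 95.0)
    female_fraction: float = 0.81
    diabetes_fraction: float = 0.33  # null covariate: never drives trajectories
    height_mean: float = 1.66
    height_sd: float = 0.09
    height_range: tuple[float, float] = (1.4, 2.1)
    schedule: tuple[float, ...] = DEFAULT_SCHEDULE
    attrition_horizons: tuple[float, ...] = (6.0, 12.0, 24.0)
    attrition_targets: tuple[float, ...] | None = (0.88, 0.77, 0.53)
    persistence: float = 0.8
    jitter_days: float = 10.0
    truth: ModelSet = field(default_factory=published_model)

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        if not (0.0 <= self.persistence <= 1.0):
            raise ConfigurationError("persistence must lie in [0, 1]")
        if not self.schedule or any(
            b <= a for a, b in zip(self.schedule, self.schedule[1:])
        ):
            raise ConfigurationError("schedule must be strictly increasing and nonempty")
        if self.attrition_targets is not None:
            t = self.attrition_targets
            if len(t) != len(self.attrition_horizons):
                raise ConfigurationError("attrition targets and horizons must align")
            if any(not (0 < x <= 1) for x in t) or any(b > a for a, b in zip(t, t[1:])):
                raise ConfigurationError("attrition targets must be non-increasing in (0, 1]")
        for name in ("age_range", "bmi_range", "height_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigurationError(f"{name} bounds are inverted")

    @property
    def jitter_months(self) -> float:
        return self.jitter_days / DAYS_PER_MONTH


def _truncated_normal(rng: np.random.Generator, n: int, mean, sd, lo, hi) -> np.ndarray:
    """Rejection sampling from Normal(mean, sd²) truncated to [lo, hi]."""
    if sd == 0:
        if not (lo <= mean <= hi):
            raise ConfigurationError(f"degenerate value {mean} outside bounds [{lo}, {hi}]")
        return np.full(n, float(mean))
    if ndtr((hi - mean) / sd) - ndtr((lo - mean) / sd) < 1e-12:
        raise ConfigurationError(f"truncation bounds [{lo}, {hi}] carry no mass")
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=2 * (n - filled) + 16)
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(draw.size, n - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out


def _profile_frame(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    n = spec.n_patients
    age = _truncated_normal(rng, n, spec.age_mean, spec.age_sd, *spec.age_range)
    bmi = _truncated_normal(rng, n, spec.bmi_mean, spec.bmi_sd, *spec.bmi_range)
    height = _truncated_normal(rng, n, spec.height_mean, spec.height_sd, *spec.height_range)
    female = rng.random(n) < spec.female_fraction
    diabetes = rng.random(n) < spec.diabetes_fraction
    return pd.DataFrame(
        {
            "patient_id": [f"P{i:05d}" for i in range(n)],
            "age": age,
            "sex": np.where(female, "female", "male"),
            "height_m": height,
            "weight_baseline_kg": bmi * height**2,
            "bmi_baseline": bmi,
            "diabetes": diabetes.astype(int),
        }
    )


def sample_profiles(spec: CohortSpec, rng: np.random.Generator | None = None) -> list[PatientProfile]:
    """Draw ``spec.n_patients`` preoperative profiles (reproducible given seed)."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    frame = _profile_frame(spec, rng)
    return [
        PatientProfile(
            age=float(r.age),
            height=float(r.height_m),
            weight_baseline=float(r.weight_baseline_kg),
            bmi_baseline=float(r.bmi_baseline),
            sex=str(r.sex),
            diabetes=bool(r.diabetes),
            patient_id=str(r.patient_id),
        )
        for r in frame.itertuples()
    ]


# inverse conditional CDF --------------------------------------------------


def _inverse_cdf_array(model_set: ModelSet, bmi0, age, time, u) -> np.ndarray:
    """Vectorized inverse conditional CDF; inputs broadcast together."""
    from .model import design_matrix

    taus = np.asarray(model_set.taus)
    # direct evaluation: visit jitter may push times marginally past the
    # validity edge, which is part of the generator's own mechanism
    knots = design_matrix(bmi0, age, time) @ model_set.coefficient_matrix().T  # (..., k)
    if np.any(np.diff(knots, axis=-1) < 0):
        bad = np.argwhere(np.diff(knots, axis=-1) < 0)
        raise CrossingError(
            f"quantile curves cross at query index {bad[0][:-1].tolist()}; "
            "generation requires a non-crossing truth model"
        )
    u = np.asarray(u, dtype=float)
    if np.any((u <= 0) | (u >= 1)):
        raise InvalidInputError("u must lie strictly in (0, 1)")
    u_b, _ = np.broadcast_arrays(u, knots[..., 0])
    lo_k, hi_k = knots[..., 0], knots[..., -1]
    # matched spread: sigma from the outer-knot gap on the normal scale
    z_span = ndtri(taus[-1]) - ndtri(taus[0])
    sigma = (hi_k - lo_k) / z_span if z_span > 0 else np.zeros_like(hi_k)
    # interior: piecewise-linear in tau between knots
    interior = np.empty_like(u_b)
    flat_u = u_b.ravel()
    flat_knots = knots.reshape(-1, taus.size) if knots.ndim > 1 else np.broadcast_to(
        knots, (flat_u.size, taus.size)
    )
    if knots.ndim == 1:
        interior = np.interp(flat_u, taus, knots).reshape(u_b.shape)
    else:
        idx = np.clip(np.searchsorted(taus, flat_u, side="right"), 1, taus.size - 1)
        t0, t1 = taus[idx - 1], taus[idx]
        k0 = np.take_along_axis(flat_knots, (idx - 1)[:, None], axis=1)[:, 0]
        k1 = np.take_along_axis(flat_knots, idx[:, None], axis=1)[:, 0]
        interior = (k0 + (flat_u - t0) / (t1 - t0) * (k1 - k0)).reshape(u_b.shape)
    # tails: Gaussian, anchored at the outer knots so knot identity holds
    out = np.where(
        u_b < taus[0],
        lo_k + sigma * (ndtri(np.clip(u_b, 1e-12, None)) - ndtri(taus[0])),
        np.where(
            u_b > taus[-1],
            hi_k + sigma * (ndtri(np.clip(u_b, None, 1 - 1e-12)) - ndtri(taus[-1])),
            interior,
        ),
    )
    return out


def inverse_cdf(model_set: ModelSet, bmi_baseline: float, age: float, time: float, u):
    """BMI at rank ``u`` of the conditional distribution at one query point.

    Piecewise linear between the model's (τ, BMI) knots; Gaussian tails with
    σ = (outer-knot gap)/(z_span) anchored so ``inverse_cdf(·, τ_k)`` equals
    the k-th percentile curve exactly. Raises :class:`CrossingError` when the
    knots cross at the query.
    """
    out = _inverse_cdf_array(model_set, bmi_baseline, age, time, u)
    return float(out) if np.ndim(u) == 0 else out


# dropout ------------------------------------------------------------------


def interval_survival_ratios(targets: Sequence[float]) -> tuple[float, ...]:
    """Conditional survival ratios between successive retention targets.

    Diagnostic identity: for targets (0.88, 0.77, 0.53) the ratios are
    (0.88, 0.77/0.88, 0.53/0.77) ≈ (0.88, 0.875, 0.688).
    """
    out, prev = [], 1.0
    for t in targets:
        out.append(t / prev)
        prev = t
    return tuple(out)


def _visit_exceeds_prob(schedule: np.ndarray, jm: float, horizon: float, s: float) -> float:
    """P(some kept visit has jittered time in (horizon, s]) for censor time s."""
    if jm == 0:
        keep = schedule <= s
        return float(np.any(keep & (schedule > horizon)))
    lo = np.maximum(horizon - schedule, -jm)
    hi = np.minimum(s - schedule, jm)
    p = np.clip(hi - lo, 0.0, None) / (2 * jm)
    return float(1.0 - np.prod(1.0 - p))


class _PiecewiseHazard:
    """Piecewise-constant hazard: edges are upper bounds, last rate extends to ∞."""

    def __init__(self, edges: Sequence[float], rates: Sequence[float]):
        self.edges = np.asarray(edges, dtype=float)
        self.rates = np.asarray(rates, dtype=float)
        b = np.concatenate([[0.0], self.edges])
        self.cum = np.concatenate([[0.0], np.cumsum(self.rates * np.diff(b))])

    def survival(self, t: float) -> float:
        b = np.concatenate([[0.0], self.edges])
        H = 0.0
        for k, rate in enumerate(self.rates):
            H += rate * max(0.0, min(t, self.edges[k]) - b[k])
        if t > self.edges[-1]:
            H += self.rates[-1] * (t - self.edges[-1])
        return math.exp(-H)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        e = rng.exponential(size=n)
        b = np.concatenate([[0.0], self.edges])
        k = np.searchsorted(self.cum[1:], e, side="left")
        out = np.empty(n)
        inside = k < self.rates.size
        with np.errstate(divide="ignore", invalid="ignore"):
            ki = k[inside]
            out[inside] = b[ki] + (e[inside] - self.cum[ki]) / self.rates[ki]
            tail_rate = self.rates[-1]
            if tail_rate > 0:
                out[~inside] = self.edges[-1] + (e[~inside] - self.cum[-1]) / tail_rate
            else:
                out[~inside] = np.inf
        out[np.isnan(out)] = np.inf
        return out


_HAZARD_CACHE: dict[tuple, _PiecewiseHazard] = {}


def calibrate_dropout(spec: CohortSpec) -> _PiecewiseHazard | None:
    """Solve hazard rates so expected empirical retention matches the targets.

    For each horizon h the rate applies up to just past the first scheduled
    visit that certainly exceeds h (nominal + max jitter); rates are found by
    1-D root finding on the exact expected retention under the keep-if-
    jittered-time ≤ censor rule. Returns None when attrition is disabled.
    """
    if spec.attrition_targets is None:
        return None
    key = (spec.schedule, spec.attrition_horizons, spec.attrition_targets, round(spec.jitter_months, 9))
    if key in _HAZARD_CACHE:
        return _HAZARD_CACHE[key]
    schedule = np.asarray(spec.schedule, dtype=float)
    jm = spec.jitter_months
    edges, rates = [], []
    for horizon, target in zip(spec.attrition_horizons, spec.attrition_targets):
        certain = schedule[schedule - jm > horizon]
        if certain.size == 0:
            raise ConfigurationError(
                f"visit schedule has no visit certainly beyond horizon {horizon} months"
            )
        edge = float(certain[0]) + jm
        grid = np.linspace(0.0, edge, 1600)
        g = np.array([_visit_exceeds_prob(schedule, jm, horizon, s) for s in grid])

        def retention(rate: float) -> float:
            hz = _PiecewiseHazard(edges + [edge], rates + [rate])
            surv = np.array([hz.survival(s) for s in grid])
            # retention = S(edge) + ∫ g(s) f(s) ds, integrated by parts on the grid
            dens_mass = -np.diff(surv)
            g_mid = 0.5 * (g[:-1] + g[1:])
            return float(hz.survival(edge) + np.sum(g_mid * dens_mass))

        hi_val = retention(1e-9)
        if target >= hi_val - 1e-9:
            rate = 0.0
        else:
            lo_val = retention(5.0)
            if target < lo_val:
                raise ConfigurationError(
                    f"retention target {target} beyond {horizon} months is unreachable"
                )
            rate = brentq(lambda r: retention(r) - target, 1e-9, 5.0, xtol=1e-10)
        edges.append(edge)
        rates.append(float(rate))
    hz = _PiecewiseHazard(edges, rates)
    _HAZARD_CACHE[key] = hz
    return hz


def apply_dropout(
    series: WeightSeries, spec: CohortSpec, rng: np.random.Generator | int
) -> WeightSeries:
    """Censor a patient's series with the spec-calibrated dropout process.

    Visits after the drawn censoring time are removed; the earliest visit is
    always kept.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    hz = calibrate_dropout(spec)
    if hz is None or len(series) == 0:
        return series
    censor = float(hz.sample(rng, 1)[0])
    keep = series.times <= censor
    keep[int(np.argmin(series.times))] = True
    return WeightSeries(series.times[keep], series.weights[keep], series.patient_id)


# trajectories -------------------------------------------------------------


def _ranks(rng: np.random.Generator, n_patients: int, n_visits: int, persistence: float):
    """Gaussian-copula visit ranks: exactly Uniform(0,1) marginally."""
    z = rng.standard_normal((n_patients, 1))
    eps = rng.standard_normal((n_patients, n_visits))
    latent = math.sqrt(persistence) * z + math.sqrt(1.0 - persistence) * eps
    return np.clip(ndtr(latent), _RANK_CLIP, 1.0 - _RANK_CLIP), ndtr(z[:, 0])


def sample_trajectory(
    profile: PatientProfile, spec: CohortSpec, rng: np.random.Generator
) -> WeightSeries:
    """One patient's full (pre-dropout) visit series from the truth model."""
    m = len(spec.schedule)
    times = np.asarray(spec.schedule, dtype=float)
    if spec.jitter_months > 0:
        times = times + rng.uniform(-spec.jitter_months, spec.jitter_months, size=m)
        times = np.maximum(times, 1e-2)
    ranks, _ = _ranks(rng, 1, m, spec.persistence)
    bmi = _inverse_cdf_array(spec.truth, profile.bmi_baseline, profile.age, times, ranks[0])
    order = np.argsort(times, kind="stable")
    times, bmi = times[order], bmi[order]
    keep = np.concatenate([[True], np.diff(times) > 0])  # drop exact time ties
    return WeightSeries(times[keep], bmi[keep] * profile.height**2, profile.patient_id)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Profiles plus dropout-filtered trajectories, reproducible from the seed."""
    rng = np.random.default_rng(spec.seed)
    frame = _profile_frame(spec, rng)
    n = spec.n_patients
    schedule = np.asarray(spec.schedule, dtype=float)
    m = schedule.size
    jm = spec.jitter_months
    times = np.broadcast_to(schedule, (n, m)).copy()
    if jm > 0:
        times = times + rng.uniform(-jm, jm, size=(n, m))
        times = np.maximum(times, 1e-2)
    ranks, _ = _ranks(rng, n, m, spec.persistence)
    hz = calibrate_dropout(spec)
    if hz is not None:
        censor = hz.sample(rng, n)
        keep = times <= censor[:, None]
        keep[np.arange(n), np.argmin(times, axis=1)] = True
    else:
        keep = np.ones((n, m), dtype=bool)
    bmi0 = frame["bmi_baseline"].to_numpy()
    age = frame["age"].to_numpy()
    height = frame["height_m"].to_numpy()
    rows_i, cols_j = np.nonzero(keep)
    bmi = _inverse_cdf_array(
        spec.truth, bmi0[rows_i], age[rows_i], times[rows_i, cols_j], ranks[rows_i, cols_j]
    )
    meas = pd.DataFrame(
        {
            "patient_id": frame["patient_id"].to_numpy()[rows_i],
            "months_post_op": times[rows_i, cols_j],
            "weight_kg": bmi * height[rows_i] ** 2,
        }
    )
    meas = meas.sort_values(["patient_id", "months_post_op"], kind="stable").reset_index(drop=True)
    meas = meas.drop_duplicates(["patient_id", "months_post_op"]).reset_index(drop=True)
    return Cohort(frame, meas)
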