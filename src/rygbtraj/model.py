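"""Conditional-quantile BMI trajectory model for post-RYGB weight loss.

The model expresses the :math:`\\tau`-th conditional percentile of BMI at
``t`` months after Roux-en-Y gastric bypass as a cubic polynomial in time
with linear adjustments for preoperative BMI and patient age, plus
BMI×time and age×time interactions:

.. math::

    Q_\\tau(\\mathrm{BMI} \\mid b_0, a, t) =
        \\beta_0 + \\beta_1 (b_0 - 50) + \\beta_2 (a - 50)
        + \\beta_3 d + \\beta_4 d^2 + \\beta_5 d^3
        + \\beta_6 (b_0 - 50) d + \\beta_7 (a - 50) d,
    \\qquad d = t - 6,

where ``b0`` is the preoperative (baseline) BMI in kg/m², ``a`` the age in
years at the initial preoperative visit, and ``t`` months after surgery.
The centered parameterization — deviations from BMI 50 kg/m², age 50 y,
time 6 months — is canonical here; :func:`uncentered_to_centered` converts
coefficients written against raw ``(b0, a, t)``.

A packaged coefficient file carries the published fits for the 25th, 50th
and 75th percentiles (lower percentile = more weight loss); load it with
:func:`published_model`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InvalidInputError, RangeError, SchemaError

__all__ = [
    "COEF_FIELDS",
    "CENTER_BMI",
    "CENTER_AGE",
    "CENTER_TIME",
    "QuantileCoefficients",
    "ModelSet",
    "PercentileCurve",
    "design_vector",
    "design_matrix",
    "evaluate_percentile",
    "trajectory",
    "lookup_table",
    "uncentered_to_centered",
    "read_model_set",
    "write_model_set",
    "published_model",
]

#: Coefficient names in design order.
COEF_FIELDS = ("b0", "b_bmi", "b_age", "b_t", "b_t2", "b_t3", "b_bmi_t", "b_age_t")

CENTER_BMI = 50.0
CENTER_AGE = 50.0
CENTER_TIME = 6.0

DAYS_PER_MONTH = 30.4375  # mean Gregorian month; fixed divisor for date→month conversion


@dataclass(frozen=True)
class QuantileCoefficients:
    """The eight fitted parameters of one percentile curve.

    Parameters are in the centered parameterization: ``b0`` is the predicted
    BMI (kg/m²) at baseline BMI 50, age 50, six months after surgery;
    ``b_bmi`` and ``b_age`` are main effects per kg/m² and per year;
    ``b_t, b_t2, b_t3`` the time polynomial; ``b_bmi_t``/``b_age_t`` the
    interactions with centered time.
    """

    tau: float
    b0: float
    b_bmi: float
    b_age: float
    b_t: float
    b_t2: float
    b_t3: float
    b_bmi_t: float
    b_age_t: float

    def __post_init__(self) -> None:
        if not (0.0 < self.tau < 1.0):
            raise InvalidInputError(f"tau must lie strictly in (0, 1), got {self.tau!r}")
        for name in COEF_FIELDS:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise InvalidInputError(f"coefficient {name} is not finite: {v!r}")

    def as_array(self) -> np.ndarray:
        """Coefficients as a length-8 array in design order."""
        return np.array([getattr(self, name) for name in COEF_FIELDS], dtype=float)

    @classmethod
    def from_array(cls, tau: float, beta: Sequence[float]) -> "QuantileCoefficients":
        beta = np.asarray(beta, dtype=float)
        if beta.shape != (8,):
            raise InvalidInputError(f"expected 8 coefficients, got shape {beta.shape}")
        return cls(tau, *beta.tolist())


def uncentered_to_centered(tau: float, alpha: Sequence[float]) -> QuantileCoefficients:
    """Convert coefficients of the raw-covariate model to the centered form.

    ``alpha`` is ``(a0..a7)`` for
    ``a0 + a1·b0 + a2·age + a3·t + a4·t² + a5·t³ + a6·b0·t + a7·age·t``.
    Substituting ``b0 = 50 + b``, ``age = 50 + a``, ``t = 6 + d`` and
    collecting terms gives the centered coefficients returned here.
    """
    a = np.asarray(alpha, dtype=float)
    if a.shape != (8,):
        raise InvalidInputError(f"expected 8 uncentered coefficients, got shape {a.shape}")
    a0, a1, a2, a3, a4, a5, a6, a7 = a
    B, A, T = CENTER_BMI, CENTER_AGE, CENTER_TIME
    beta = np.array(
        [
            a0 + B * a1 + A * a2 + T * a3 + T**2 * a4 + T**3 * a5 + B * T * a6 + A * T * a7,
            a1 + T * a6,
            a2 + T * a7,
            a3 + 2 * T * a4 + 3 * T**2 * a5 + B * a6 + A * a7,
            a4 + 3 * T * a5,
            a5,
            a6,
            a7,
        ]
    )
    return QuantileCoefficients.from_array(tau, beta)


@dataclass(frozen=True)
class ModelSet:
    """An ordered set of percentile models plus their validity ranges.

    ``entries`` must have strictly increasing ``tau``. Ranges are the
    intervals of baseline BMI (kg/m²), age (years) and post-operative time
    (months) over which predictions are supported; outside them,
    :func:`evaluate_percentile` raises unless extrapolation is allowed.
    """

    entries: tuple[QuantileCoefficients, ...]
    bmi_range: tuple[float, float] = (35.0, 95.0)
    age_range: tuple[float, float] = (18.0, 74.0)
    time_range: tuple[float, float] = (0.0, 36.0)

    def __post_init__(self) -> None:
        entries = tuple(self.entries)
        object.__setattr__(self, "entries", entries)
        if not entries:
            raise ConfigurationError("ModelSet needs at least one percentile entry")
        taus = [e.tau for e in entries]
        if any(b <= a for a, b in zip(taus, taus[1:])):
            raise SchemaError(f"taus must be strictly increasing, got {taus}")
        for name in ("bmi_range", "age_range", "time_range"):
            lo, hi = getattr(self, name)
            object.__setattr__(self, name, (float(lo), float(hi)))
            if not (lo < hi):
                raise ConfigurationError(f"{name} must be a nonempty interval, got {(lo, hi)}")

    @property
    def taus(self) -> tuple[float, ...]:
        return tuple(e.tau for e in self.entries)

    def coefficients(self, tau: float) -> QuantileCoefficients:
        for e in self.entries:
            if e.tau == tau:
                return e
        raise KeyError(f"no entry for tau={tau}; available: {self.taus}")

    def coefficient_matrix(self) -> np.ndarray:
        """(n_taus, 8) array of coefficients, rows ordered by tau."""
        return np.vstack([e.as_array() for e in self.entries])

    # prediction -----------------------------------------------------------

    def check_ranges(self, bmi_baseline, age, time, *, allow_extrapolation: bool = False) -> None:
        """Raise :class:`RangeError` for out-of-range queries (warn if allowed).

        Negative times are always rejected: time 0 is the date of surgery and
        the model is post-operative only.
        """
        b = np.asarray(bmi_baseline, dtype=float)
        a = np.asarray(age, dtype=float)
        t = np.asarray(time, dtype=float)
        if not (np.all(np.isfinite(b)) and np.all(np.isfinite(a)) and np.all(np.isfinite(t))):
            raise InvalidInputError("query values must be finite")
        if np.any(t < 0):
            raise RangeError("negative time: the model is defined for months after surgery only")
        out = (
            (b < self.bmi_range[0]) | (b > self.bmi_range[1])
            | (a < self.age_range[0]) | (a > self.age_range[1])
            | (t < self.time_range[0]) | (t > self.time_range[1])
        )
        if np.any(out):
            msg = (
                f"query outside validity ranges bmi={self.bmi_range}, "
                f"age={self.age_range}, time={self.time_range}"
            )
            if allow_extrapolation:
                import warnings

                warnings.warn(msg + " (extrapolating)", stacklevel=3)
            else:
                raise RangeError(msg)

    def predict(self, bmi_baseline, age, time, *, allow_extrapolation: bool = False) -> np.ndarray:
        """Predicted BMI for each percentile.

        Broadcasts ``bmi_baseline``, ``age`` and ``time`` together; returns an
        array of shape ``broadcast_shape + (n_taus,)`` (a length-``n_taus``
        vector for scalar input).
        """
        self.check_ranges(bmi_baseline, age, time, allow_extrapolation=allow_extrapolation)
        X = design_matrix(bmi_baseline, age, time)
        return X @ self.coefficient_matrix().T


def design_vector(bmi_baseline: float, age: float, time: float) -> np.ndarray:
    """The centered 8-component basis at one query point.

    Returns ``[1, b, a, d, d², d³, b·d, a·d]`` with ``b = bmi−50``,
    ``a = age−50``, ``d = time−6``.
    """
    for name, v in (("bmi_baseline", bmi_baseline), ("age", age), ("time", time)):
        if not math.isfinite(v):
            raise InvalidInputError(f"{name} is not finite: {v!r}")
    return design_matrix(bmi_baseline, age, time)


def design_matrix(bmi_baseline, age, time) -> np.ndarray:
    """Vectorized :func:`design_vector`: broadcast inputs, stack basis on the last axis."""
    b = np.asarray(bmi_baseline, dtype=float) - CENTER_BMI
    a = np.asarray(age, dtype=float) - CENTER_AGE
    d = np.asarray(time, dtype=float) - CENTER_TIME
    b, a, d = np.broadcast_arrays(b, a, d)
    one = np.ones_like(d)
    return np.stack([one, b, a, d, d**2, d**3, b * d, a * d], axis=-1)


def evaluate_percentile(
    coef: QuantileCoefficients,
    bmi_baseline,
    age,
    time,
    *,
    model_set: ModelSet | None = None,
    allow_extrapolation: bool = False,
):
    """Predicted BMI (kg/m²) for one percentile at one or more query points.

    When ``model_set`` is given its validity ranges are enforced (raising
    :class:`RangeError`, or warning when ``allow_extrapolation``). Negative
    times are rejected unconditionally. The result is the exact dot product
    of the design basis with the coefficients — no rounding.
    """
    t = np.asarray(time, dtype=float)
    if not np.all(np.isfinite(np.asarray(bmi_baseline, dtype=float))) or not np.all(
        np.isfinite(np.asarray(age, dtype=float))
    ) or not np.all(np.isfinite(t)):
        raise InvalidInputError("query values must be finite")
    if np.any(t < 0):
        raise RangeError("negative time: the model is defined for months after surgery only")
    if model_set is not None:
        model_set.check_ranges(bmi_baseline, age, time, allow_extrapolation=allow_extrapolation)
    out = design_matrix(bmi_baseline, age, time) @ coef.as_array()
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class PercentileCurve:
    """One percentile trajectory evaluated on a time grid."""

    tau: float
    times: np.ndarray
    bmi_values: np.ndarray
    weight_values: np.ndarray | None = None  # kg, requires height

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        bmi = np.asarray(self.bmi_values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "bmi_values", bmi)
        if times.shape != bmi.shape:
            raise InvalidInputError("times and bmi_values must have equal length")
        if times.size > 1 and np.any(np.diff(times) <= 0):
            raise InvalidInputError("times must be strictly increasing")
        if self.weight_values is not None:
            w = np.asarray(self.weight_values, dtype=float)
            object.__setattr__(self, "weight_values", w)
            if w.shape != times.shape:
                raise InvalidInputError("weight_values must match times in length")


def trajectory(
    model_set: ModelSet,
    *,
    bmi_baseline: float,
    age: float,
    times: Sequence[float],
    height: float | None = None,
    include_weights: bool | None = None,
    allow_extrapolation: bool = False,
) -> list[PercentileCurve]:
    """Percentile BMI (and optionally weight) curves for one patient profile.

    One :class:`PercentileCurve` per model percentile. With ``height`` (m),
    weight curves ``BMI × height²`` are attached; requesting weights
    explicitly (``include_weights=True``) without a height is a
    configuration error.
    """
    if include_weights and height is None:
        raise ConfigurationError("weight curves requested but no height given")
    if include_weights is False:
        height = None
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        return [PercentileCurve(e.tau, times, np.empty(0)) for e in model_set.entries]
    pred = model_set.predict(bmi_baseline, age, times, allow_extrapolation=allow_extrapolation)
    curves = []
    for j, e in enumerate(model_set.entries):
        bmi = pred[..., j]
        weight = bmi * height**2 if height is not None else None
        curves.append(PercentileCurve(e.tau, times, bmi, weight))
    return curves


def lookup_table(
    model_set: ModelSet,
    bmi_grid: Sequence[float] = (40, 45, 50, 55, 60, 65, 70),
    age_grid: Sequence[float] = (30, 50, 70),
    times: Sequence[float] = (6, 12, 24),
    *,
    decimals: int = 1,
) -> pd.DataFrame:
    """Grid of predicted percentile BMIs, long format.

    Default grids give the 7 baseline-BMI levels × 3 ages × 3 horizons × the
    model's percentiles. Columns: ``bmi_baseline, age, months_post_op,
    percentile, bmi_predicted`` (full precision) and ``bmi_display``
    (round-half-even to ``decimals``). Display rounding is a presentation
    convention of this package.
    """
    bmi_grid = np.asarray(bmi_grid, dtype=float)
    age_grid = np.asarray(age_grid, dtype=float)
    times = np.asarray(times, dtype=float)
    if bmi_grid.size == 0 or age_grid.size == 0 or times.size == 0:
        raise InvalidInputError("grids must be nonempty")
    B, A, T = np.meshgrid(bmi_grid, age_grid, times, indexing="ij")
    pred = model_set.predict(B.ravel(), A.ravel(), T.ravel())  # (n, k)
    rows = []
    for j, e in enumerate(model_set.entries):
        rows.append(
            pd.DataFrame(
                {
                    "bmi_baseline": B.ravel(),
                    "age": A.ravel(),
                    "months_post_op": T.ravel(),
                    "percentile": e.tau,
                    "bmi_predicted": pred[:, j],
                }
            )
        )
    table = pd.concat(rows, ignore_index=True)
    table = table.sort_values(
        ["bmi_baseline", "age", "months_post_op", "percentile"], kind="stable"
    ).reset_index(drop=True)
    table["bmi_display"] = np.round(table["bmi_predicted"].to_numpy(), decimals)
    return table


# serialization ------------------------------------------------------------

_RANGE_KEYS = {"bmi_range": "bmi_range", "age_range": "age_range", "time_range": "time_range"}


def model_set_to_dict(model_set: ModelSet) -> dict:
    return {
        "percentiles": [
            {"tau": e.tau, **{k: getattr(e, k) for k in COEF_FIELDS}} for e in model_set.entries
        ],
        "bmi_range": list(model_set.bmi_range),
        "age_range": list(model_set.age_range),
        "time_range": list(model_set.time_range),
    }


def model_set_from_dict(doc: dict) -> ModelSet:
    if not isinstance(doc, dict) or "percentiles" not in doc:
        raise SchemaError("coefficient document must be an object with a 'percentiles' list")
    entries = []
    for i, rec in enumerate(doc["percentiles"]):
        if "tau" not in rec:
            raise SchemaError(f"percentiles[{i}] is missing field 'tau'")
        for k in COEF_FIELDS:
            if k not in rec:
                raise SchemaError(f"percentiles[{i}] (tau={rec['tau']}) is missing field '{k}'")
        try:
            entries.append(
                QuantileCoefficients(float(rec["tau"]), *(float(rec[k]) for k in COEF_FIELDS))
            )
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"percentiles[{i}]: {exc}") from exc
    kwargs = {}
    for key in _RANGE_KEYS:
        if key in doc:
            rng = doc[key]
            if not (isinstance(rng, (list, tuple)) and len(rng) == 2):
                raise SchemaError(f"{key} must be a [low, high] pair")
            kwargs[key] = (float(rng[0]), float(rng[1]))
    taus = [e.tau for e in entries]
    if any(b <= a for a, b in zip(taus, taus[1:])):
        raise SchemaError(f"taus must be strictly increasing, got {taus}")
    return ModelSet(tuple(entries), **kwargs)


def read_model_set(path: str | Path) -> ModelSet:
    """Read a coefficient JSON file; raises :class:`SchemaError` naming any defect."""
    try:
        with open(path, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"malformed JSON in {path}: {exc}") from exc
    return model_set_from_dict(doc)


def write_model_set(path: str | Path, model_set: ModelSet) -> None:
    """Write coefficients as JSON at full float precision (round-trips exactly)."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(model_set_to_dict(model_set), fh, indent=1)
        fh.write("\n")


def published_model() -> ModelSet:
    """The packaged published coefficient set (25th/50th/75th percentiles)."""
    with resources.files("rygbtraj.data").joinpath("published_coefficients.json").open(
        "r", encoding="utf-8"
    ) as fh:
        return model_set_from_dict(json.load(fh))
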