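"""Anthropometric conversions, outcome extraction and percentile-band tracking.

Outcomes mirror the quantities bariatric programs monitor after surgery:
percent excess weight loss (%EWL, with "ideal weight" the weight at BMI 25,
the dominant convention in the field), the weight-loss nadir (minimum
observed BMI and its time), and %EWL near six months. :func:`track`
classifies each post-operative measurement against the model's percentile
curves — a lower BMI percentile means more weight loss than expected.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    ConfigurationError,
    EmptyInputError,
    InvalidInputError,
)
from .model import DAYS_PER_MONTH, ModelSet

__all__ = [
    "PatientProfile",
    "WeightSeries",
    "TrackRecord",
    "TrackReport",
    "compute_bmi",
    "ideal_weight",
    "percent_ewl",
    "nadir",
    "six_month_loss",
    "track",
    "months_between",
]

BANDS = ("below_25", "25_to_50", "50_to_75", "above_75")

_HEIGHT_RANGE = (1.0, 2.5)
SIX_MONTH_WINDOW = 1.5  # months either side of 6.0 accepted as "the 6-month visit"


def months_between(date: _dt.date, surgery_date: _dt.date) -> float:
    """Fractional months from surgery to ``date`` (fixed divisor 30.4375 d/month)."""
    return (date - surgery_date).days / DAYS_PER_MONTH


def compute_bmi(weight: float, height: float) -> float:
    """BMI in kg/m² from weight (kg) and height (m)."""
    if not (math.isfinite(weight) and weight > 0):
        raise InvalidInputError(f"weight must be positive and finite, got {weight!r}")
    if not (_HEIGHT_RANGE[0] < height < _HEIGHT_RANGE[1]):
        raise InvalidInputError(f"height must lie in {_HEIGHT_RANGE} m, got {height!r}")
    return weight / height**2


def ideal_weight(height: float) -> float:
    """Reference ("ideal") weight in kg: the weight at BMI 25 for this height."""
    if not (_HEIGHT_RANGE[0] < height < _HEIGHT_RANGE[1]):
        raise InvalidInputError(f"height must lie in {_HEIGHT_RANGE} m, got {height!r}")
    return 25.0 * height**2


@dataclass(frozen=True)
class PatientProfile:
    """Preoperative patient characteristics.

    ``bmi_baseline`` is derived from weight and height when absent; if both
    are given they must agree to within 0.05 kg/m².
    """

    age: float
    height: float | None = None
    weight_baseline: float | None = None
    bmi_baseline: float | None = None
    sex: str | None = None  # "female" / "male"
    diabetes: bool | None = None
    surgery_date: _dt.date | None = None
    patient_id: str | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.age) or self.age <= 0:
            raise InvalidInputError(f"age must be positive, got {self.age!r}")
        if self.sex is not None and self.sex not in ("female", "male"):
            raise InvalidInputError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if self.height is not None and not (_HEIGHT_RANGE[0] < self.height < _HEIGHT_RANGE[1]):
            raise InvalidInputError(f"height must lie in {_HEIGHT_RANGE} m, got {self.height!r}")
        if self.weight_baseline is not None and self.weight_baseline <= 0:
            raise InvalidInputError("weight_baseline must be positive")
        bmi = self.bmi_baseline
        if bmi is None and self.weight_baseline is not None and self.height is not None:
            bmi = compute_bmi(self.weight_baseline, self.height)
            object.__setattr__(self, "bmi_baseline", bmi)
        elif bmi is not None and self.weight_baseline is not None and self.height is not None:
            implied = compute_bmi(self.weight_baseline, self.height)
            if abs(implied - bmi) >= 0.05:
                raise InvalidInputError(
                    f"bmi_baseline {bmi:.3f} inconsistent with weight/height ({implied:.3f})"
                )

    def require(self, *fields_: str) -> None:
        missing = [f for f in fields_ if getattr(self, f) is None]
        if missing:
            raise ConfigurationError(f"profile is missing required fields: {missing}")


@dataclass(frozen=True)
class WeightSeries:
    """Time-stamped post-operative weights for one patient.

    Times are months after surgery, strictly increasing and non-negative;
    weights are kg.
    """

    times: np.ndarray
    weights: np.ndarray
    patient_id: str | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "weights", w)
        if t.shape != w.shape or t.ndim != 1:
            raise InvalidInputError("times and weights must be equal-length 1-D sequences")
        if t.size:
            if np.any(t < 0):
                raise InvalidInputError("series times must be non-negative (months after surgery)")
            if np.any(np.diff(t) <= 0):
                raise InvalidInputError("series times must be strictly increasing")
            if np.any(w <= 0) or not np.all(np.isfinite(w)):
                raise InvalidInputError("weights must be positive and finite")

    def __len__(self) -> int:
        return int(self.times.size)

    @classmethod
    def from_pairs(cls, pairs: Sequence[tuple[float, float]], patient_id: str | None = None):
        pairs = sorted(pairs)
        return cls(
            np.array([p[0] for p in pairs], dtype=float),
            np.array([p[1] for p in pairs], dtype=float),
            patient_id,
        )

    @classmethod
    def from_dates(
        cls,
        dated_pairs: Sequence[tuple[_dt.date, float]],
        surgery_date: _dt.date,
        patient_id: str | None = None,
    ):
        return cls.from_pairs(
            [(months_between(d, surgery_date), w) for d, w in dated_pairs], patient_id
        )


def percent_ewl(profile: PatientProfile, current_weight: float) -> float:
    """Percent excess weight lost relative to the BMI-25 reference weight.

    ``100·(baseline − current) / (baseline − ideal)``; 0 at baseline weight,
    100 at the reference weight, negative for weight gain.
    """
    profile.require("height", "weight_baseline")
    iw = ideal_weight(profile.height)
    excess = profile.weight_baseline - iw
    if excess <= 0:
        raise InvalidInputError(
            f"baseline weight {profile.weight_baseline} kg does not exceed the "
            f"reference weight {iw} kg; %EWL is undefined"
        )
    if not (math.isfinite(current_weight) and current_weight > 0):
        raise InvalidInputError(f"current weight must be positive, got {current_weight!r}")
    return 100.0 * (profile.weight_baseline - current_weight) / excess


def nadir(series: WeightSeries, height: float) -> tuple[float, float]:
    """Minimum observed post-operative BMI and its time (ties → earliest)."""
    if len(series) == 0:
        raise EmptyInputError("cannot take the nadir of an empty series")
    bmi = series.weights / height**2
    i = int(np.argmin(bmi))  # argmin returns the first minimum: earliest time wins
    return float(bmi[i]), float(series.times[i])


def six_month_loss(series: WeightSeries, profile: PatientProfile) -> float:
    """%EWL at the measurement nearest 6 months within ±1.5 months.

    Returns NaN when no measurement falls in the window (missing is a value,
    not an error). Ties in distance resolve to the earlier measurement.
    """
    if len(series) == 0:
        raise EmptyInputError("cannot compute six-month loss of an empty series")
    dist = np.abs(series.times - 6.0)
    in_window = dist <= SIX_MONTH_WINDOW
    if not np.any(in_window):
        return float("nan")
    cand = np.flatnonzero(in_window)
    best = cand[np.lexsort((series.times[cand], dist[cand]))][0]
    return percent_ewl(profile, float(series.weights[best]))


@dataclass(frozen=True)
class TrackRecord:
    """One classified measurement."""

    time: float
    weight: float
    bmi: float
    percent_ewl: float
    band: str
    in_range: bool


@dataclass(frozen=True)
class TrackReport:
    """Per-measurement classifications plus summary outcomes for one patient."""

    records: tuple[TrackRecord, ...]
    nadir_bmi: float = float("nan")
    nadir_time: float = float("nan")
    six_month_ewl: float = float("nan")
    current_band: str | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "months_post_op": r.time,
                    "weight_kg": r.weight,
                    "bmi": r.bmi,
                    "percent_ewl": r.percent_ewl,
                    "band": r.band,
                    "in_range": r.in_range,
                }
                for r in self.records
            ],
            columns=["months_post_op", "weight_kg", "bmi", "percent_ewl", "band", "in_range"],
        )

    def summary(self) -> dict:
        return {
            "nadir_bmi": self.nadir_bmi,
            "nadir_time": self.nadir_time,
            "six_month_ewl": self.six_month_ewl,
            "current_band": self.current_band,
        }


def classify_band(bmi: float, p25: float, p50: float, p75: float) -> str:
    """Band of an observed BMI against the three percentile predictions.

    Boundaries are half-open upward: a BMI equal to a percentile belongs to
    the band above it. Lower band = more weight loss than expected.
    """
    if bmi < p25:
        return "below_25"
    if bmi < p50:
        return "25_to_50"
    if bmi < p75:
        return "50_to_75"
    return "above_75"


def track(model_set: ModelSet, profile: PatientProfile, series: WeightSeries) -> TrackReport:
    """Classify each measurement against the percentile curves and summarize.

    Requires a complete profile (age, height, baseline weight). Measurements
    outside the model's time range are still classified (extrapolating) but
    flagged ``in_range=False``.
    """
    profile.require("age", "height", "weight_baseline")
    taus = model_set.taus
    if taus != (0.25, 0.5, 0.75):
        raise ConfigurationError(f"tracking expects percentiles (0.25, 0.5, 0.75), got {taus}")
    if len(series) == 0:
        return TrackReport(records=())
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pred = model_set.predict(
            profile.bmi_baseline, profile.age, series.times, allow_extrapolation=True
        )
    lo_t, hi_t = model_set.time_range
    records = []
    for i in range(len(series)):
        t = float(series.times[i])
        w = float(series.weights[i])
        bmi = compute_bmi(w, profile.height)
        p25, p50, p75 = (float(pred[i, j]) for j in range(3))
        records.append(
            TrackRecord(
                time=t,
                weight=w,
                bmi=bmi,
                percent_ewl=percent_ewl(profile, w),
                band=classify_band(bmi, p25, p50, p75),
                in_range=bool(lo_t <= t <= hi_t),
            )
        )
    nadir_bmi, nadir_time = nadir(series, profile.height)
    return TrackReport(
        records=tuple(records),
        nadir_bmi=nadir_bmi,
        nadir_time=nadir_time,
        six_month_ewl=six_month_loss(series, profile),
        current_band=records[-1].band,
    )


def plot_track(
    model_set: ModelSet,
    profile: PatientProfile,
    series: WeightSeries,
    path: str,
    *,
    grid_step: float = 0.5,
) -> None:
    """Static figure: percentile curves with the patient's measurements overlaid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    lo, hi = model_set.time_range
    ts = np.arange(lo, hi + grid_step / 2, grid_step)
    pred = model_set.predict(profile.bmi_baseline, profile.age, ts)
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for j, e in enumerate(model_set.entries):
        ax.plot(ts, pred[:, j], label=f"{int(round(e.tau * 100))}th percentile")
    if len(series):
        bmi = series.weights / profile.height**2
        ax.plot(series.times, bmi, "ko", ms=5, label="observed")
    ax.set_xlabel("months after surgery")
    ax.set_ylabel("BMI (kg/m²)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
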