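"""The cohort container: patient profiles plus longitudinal weight series.

A :class:`Cohort` is the unit of fitting, cleaning and simulation. It holds
two aligned tables — one row per patient (``profiles``) and one row per
weight measurement (``measurements``) — and converts to/from the single
flat CSV layout used on disk (profile columns repeated on every
measurement row).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

from .anthro import PatientProfile, WeightSeries, nadir, six_month_loss
from .exceptions import EmptyInputError, SchemaError

__all__ = ["Cohort", "PROFILE_COLUMNS", "MEASUREMENT_COLUMNS"]

PROFILE_COLUMNS = [
    "patient_id",
    "age",
    "sex",
    "height_m",
    "weight_baseline_kg",
    "bmi_baseline",
]
MEASUREMENT_COLUMNS = ["patient_id", "months_post_op", "weight_kg"]
_OPTIONAL_PROFILE_COLUMNS = ["diabetes"]


@dataclass(frozen=True)
class Cohort:
    """Profiles (one row per patient) and measurements (one row per weight)."""

    profiles: pd.DataFrame
    measurements: pd.DataFrame

    def __post_init__(self) -> None:
        for col in PROFILE_COLUMNS:
            if col not in self.profiles.columns:
                raise SchemaError(f"profiles table is missing column '{col}'")
        for col in MEASUREMENT_COLUMNS:
            if col not in self.measurements.columns:
                raise SchemaError(f"measurements table is missing column '{col}'")
        if self.profiles["patient_id"].duplicated().any():
            raise SchemaError("duplicate patient_id in profiles")
        unknown = set(self.measurements["patient_id"]) - set(self.profiles["patient_id"])
        if unknown:
            raise SchemaError(f"measurements reference unknown patients: {sorted(unknown)[:5]}")

    @property
    def n_patients(self) -> int:
        return int(len(self.profiles))

    @property
    def n_measurements(self) -> int:
        return int(len(self.measurements))

    def profile(self, patient_id: str) -> PatientProfile:
        row = self.profiles.loc[self.profiles["patient_id"] == patient_id]
        if row.empty:
            raise KeyError(f"no patient {patient_id!r}")
        r = row.iloc[0]
        diabetes = r.get("diabetes")
        return PatientProfile(
            age=float(r["age"]),
            height=float(r["height_m"]),
            weight_baseline=float(r["weight_baseline_kg"]),
            bmi_baseline=float(r["bmi_baseline"]),
            sex=None if pd.isna(r.get("sex")) else str(r["sex"]),
            diabetes=None if pd.isna(diabetes) else bool(diabetes),
            patient_id=str(r["patient_id"]),
        )

    def series(self, patient_id: str) -> WeightSeries:
        m = self.measurements.loc[self.measurements["patient_id"] == patient_id]
        return WeightSeries.from_pairs(
            list(zip(m["months_post_op"].astype(float), m["weight_kg"].astype(float))),
            patient_id=str(patient_id),
        )

    def iter_patients(self) -> Iterator[tuple[PatientProfile, WeightSeries]]:
        by_pid = dict(iter(self.measurements.groupby("patient_id", sort=False)))
        for _, r in self.profiles.iterrows():
            pid = r["patient_id"]
            m = by_pid.get(pid)
            pairs = (
                []
                if m is None
                else list(zip(m["months_post_op"].astype(float), m["weight_kg"].astype(float)))
            )
            yield self.profile(pid), WeightSeries.from_pairs(pairs, patient_id=str(pid))

    # flat-table conversion -------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """One row per measurement with the patient's profile columns repeated."""
        cols = PROFILE_COLUMNS + [
            c for c in _OPTIONAL_PROFILE_COLUMNS if c in self.profiles.columns
        ]
        return self.measurements.merge(self.profiles[cols], on="patient_id", how="left")[
            cols + ["months_post_op", "weight_kg"]
        ]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Cohort":
        required = set(PROFILE_COLUMNS + MEASUREMENT_COLUMNS)
        missing = sorted(required - set(df.columns))
        if missing:
            raise SchemaError(f"cohort table is missing columns: {missing}")
        if df.empty:
            raise EmptyInputError("cohort table has no rows")
        prof_cols = PROFILE_COLUMNS + [c for c in _OPTIONAL_PROFILE_COLUMNS if c in df.columns]
        profiles = df[prof_cols].drop_duplicates("patient_id").reset_index(drop=True)
        measurements = df[MEASUREMENT_COLUMNS].reset_index(drop=True)
        return cls(profiles, measurements)

    # fitting / screening views --------------------------------------------

    def regression_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-measurement ``(X, y, patient_ids)`` for trajectory fitting.

        X columns are ``[bmi_baseline, age, months_post_op]``; the response is
        the measurement BMI computed with the baseline height.
        """
        if self.measurements.empty:
            raise EmptyInputError("cohort has no measurements")
        merged = self.measurements.merge(
            self.profiles[["patient_id", "bmi_baseline", "age", "height_m"]],
            on="patient_id",
            how="left",
        )
        X = merged[["bmi_baseline", "age", "months_post_op"]].to_numpy(dtype=float)
        y = (
            merged["weight_kg"].to_numpy(dtype=float)
            / merged["height_m"].to_numpy(dtype=float) ** 2
        )
        return X, y, merged["patient_id"].to_numpy()

    def outcome_table(self) -> pd.DataFrame:
        """Per-patient covariates plus 6-month %EWL and nadir BMI outcomes.

        Sex is encoded female=1/male=0 for screening regressions; diabetes
        True=1/False=0. Patients with no in-window 6-month visit carry NaN.
        """
        rows = []
        for profile, series in self.iter_patients():
            if len(series) == 0:
                continue
            nadir_bmi, nadir_time = nadir(series, profile.height)
            rows.append(
                {
                    "patient_id": profile.patient_id,
                    "bmi_baseline": profile.bmi_baseline,
                    "age": profile.age,
                    "sex": {"female": 1.0, "male": 0.0}.get(profile.sex, float("nan")),
                    "diabetes": float("nan") if profile.diabetes is None else float(profile.diabetes),
                    "six_month_ewl": six_month_loss(series, profile),
                    "nadir_bmi": nadir_bmi,
                    "nadir_time": nadir_time,
                }
            )
        return pd.DataFrame(rows)

    def empirical_ranges(self) -> dict:
        """Observed covariate/time ranges (used as fitted-model validity ranges)."""
        return {
            "bmi_range": (
                float(self.profiles["bmi_baseline"].min()),
                float(self.profiles["bmi_baseline"].max()),
            ),
            "age_range": (float(self.profiles["age"].min()), float(self.profiles["age"].max())),
            "time_range": (0.0, float(self.measurements["months_post_op"].max())),
        }
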