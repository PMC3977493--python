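"""Cohort CSV readers/writers and implausible-measurement cleaning.

The flat cohort CSV has one row per weight measurement with profile columns
repeated: ``patient_id, age, sex, height_m, weight_baseline_kg,
bmi_baseline, months_post_op, weight_kg`` (optional ``diabetes``). Cleaning
removes physiologically implausible records: BMIs outside configurable
bounds, adjacent-measurement BMI changes faster than a maximum rate, and
near-duplicate entries. The thresholds are package choices, prominently
configurable — real EHR weight streams need them, but no canonical values
exist.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import MEASUREMENT_COLUMNS, PROFILE_COLUMNS, Cohort
from .exceptions import EmptyInputError, SchemaError
from .model import DAYS_PER_MONTH

__all__ = [
    "CleaningRules",
    "CleaningLog",
    "read_cohort",
    "write_cohort",
    "clean_weights",
]

WEEKS_PER_MONTH = DAYS_PER_MONTH / 7.0


@dataclass(frozen=True)
class CleaningRules:
    """Thresholds for implausible-measurement removal.

    ``bmi_bounds``: plausible BMI interval (kg/m²). ``max_rate``: maximum
    |ΔBMI| per week between adjacent measurements. ``duplicate_window``:
    measurements within this many months of each other with equal weight
    collapse to the earlier one.
    """

    bmi_bounds: tuple[float, float] = (12.0, 100.0)
    max_rate: float = 1.5
    duplicate_window: float = 0.25

    def __post_init__(self) -> None:
        lo, hi = self.bmi_bounds
        if not lo < hi:
            raise SchemaError(f"bmi_bounds must satisfy low < high, got {self.bmi_bounds}")
        if self.max_rate <= 0:
            raise SchemaError("max_rate must be positive")


@dataclass
class CleaningLog:
    """One entry per removed measurement, citing the rule that fired."""

    entries: list[dict] = field(default_factory=list)

    def add(self, patient_id: str, time: float, weight: float, rule: str) -> None:
        self.entries.append(
            {"patient_id": patient_id, "months_post_op": time, "weight_kg": weight, "rule": rule}
        )

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.entries, columns=["patient_id", "months_post_op", "weight_kg", "rule"]
        )


def read_cohort(path: str | Path) -> Cohort:
    """Read a flat cohort CSV; bad numeric rows are rejected with their indices."""
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path} is empty") from exc
    required = PROFILE_COLUMNS + ["months_post_op", "weight_kg"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort file {path} is missing columns: {missing}")
    if df.empty:
        raise EmptyInputError(f"{path} has a header but no rows")
    numeric = ["age", "height_m", "weight_baseline_kg", "bmi_baseline", "months_post_op", "weight_kg"]
    parsed = df.copy()
    bad_rows: list[int] = []
    for col in numeric:
        vals = pd.to_numeric(parsed[col], errors="coerce")
        bad_rows.extend(parsed.index[vals.isna() & parsed[col].notna()].tolist())
        parsed[col] = vals
    bad_rows = sorted(set(bad_rows))
    if bad_rows:
        import warnings

        warnings.warn(f"rejected {len(bad_rows)} unparseable rows (indices {bad_rows[:10]}...)")
        parsed = parsed.drop(index=bad_rows)
    if "diabetes" in parsed.columns:
        parsed["diabetes"] = pd.to_numeric(parsed["diabetes"], errors="coerce")
    if parsed.empty:
        raise EmptyInputError(f"{path}: no valid rows after rejecting unparseable numerics")
    return Cohort.from_frame(parsed.reset_index(drop=True))


def write_cohort(path: str | Path, cohort: Cohort) -> None:
    """Write the flat cohort CSV (full float precision; byte-stable)."""
    cohort.to_frame().to_csv(path, index=False)


def _rate_violations(times: np.ndarray, bmi: np.ndarray, max_rate: float) -> np.ndarray:
    """Total rate-rule violation (kg/m² per week over the limit) per adjacent pair."""
    if times.size < 2:
        return np.zeros(0)
    dweeks = np.diff(times) * WEEKS_PER_MONTH
    dweeks = np.maximum(dweeks, 1e-6)
    rate = np.abs(np.diff(bmi)) / dweeks
    return np.clip(rate - max_rate, 0.0, None)


def clean_weights(cohort: Cohort, rules: CleaningRules | None = None) -> tuple[Cohort, CleaningLog]:
    """Remove implausible measurements; returns the cleaned cohort and a log.

    Per patient: (1) out-of-bounds BMIs are removed; (2) while any adjacent
    pair changes faster than ``max_rate`` kg/m²/week, the single measurement
    whose removal most reduces the total violation is deleted (earliest such
    measurement on ties) and the series re-checked; (3) measurements with
    equal weight within ``duplicate_window`` months collapse to the earliest.
    Idempotent: cleaning a clean cohort is the identity.
    """
    rules = rules or CleaningRules()
    log = CleaningLog()
    heights = cohort.profiles.set_index("patient_id")["height_m"]
    kept_frames = []
    for pid, grp in cohort.measurements.groupby("patient_id", sort=False):
        h = float(heights[pid])
        grp = grp.sort_values("months_post_op", kind="stable")
        times = grp["months_post_op"].to_numpy(dtype=float)
        weights = grp["weight_kg"].to_numpy(dtype=float)
        bmi = weights / h**2
        # rule 1: bounds
        ok = (bmi >= rules.bmi_bounds[0]) & (bmi <= rules.bmi_bounds[1])
        for i in np.flatnonzero(~ok):
            log.add(pid, times[i], weights[i], "bmi_bounds")
        times, weights, bmi = times[ok], weights[ok], bmi[ok]
        # rule 2: maximum rate of change, greedy removal
        while True:
            viol = _rate_violations(times, bmi, rules.max_rate)
            if not np.any(viol > 0):
                break
            total = viol.sum()
            best_i, best_remaining = None, total
            candidates = np.unique(np.concatenate([np.flatnonzero(viol > 0), np.flatnonzero(viol > 0) + 1]))
            for i in candidates:
                mask = np.ones(times.size, dtype=bool)
                mask[i] = False
                remaining = _rate_violations(times[mask], bmi[mask], rules.max_rate).sum()
                if remaining < best_remaining - 1e-12:
                    best_i, best_remaining = int(i), remaining
            if best_i is None:  # no single removal helps: drop the first offender
                best_i = int(np.flatnonzero(viol > 0)[0] + 1)
            log.add(pid, times[best_i], weights[best_i], "max_rate")
            mask = np.ones(times.size, dtype=bool)
            mask[best_i] = False
            times, weights, bmi = times[mask], weights[mask], bmi[mask]
        # rule 3: duplicate collapse (equal weight within the window)
        keep = np.ones(times.size, dtype=bool)
        last_kept = 0
        for i in range(1, times.size):
            if (
                keep[last_kept]
                and times[i] - times[last_kept] <= rules.duplicate_window
                and weights[i] == weights[last_kept]
            ):
                keep[i] = False
                log.add(pid, times[i], weights[i], "duplicate")
            else:
                last_kept = i
        times, weights = times[keep], weights[keep]
        kept_frames.append(
            pd.DataFrame({"patient_id": pid, "months_post_op": times, "weight_kg": weights})
        )
    measurements = (
        pd.concat(kept_frames, ignore_index=True)
        if kept_frames
        else cohort.measurements.iloc[0:0]
    )
    if measurements.empty:
        import warnings

        warnings.warn("cleaning removed every measurement")
    return Cohort(cohort.profiles, measurements), log
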