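"""Wrist-accelerometer processing: wear/validity rules, average
acceleration and daily MVPA minutes.

A calendar day is valid when it carries >= 16 h of wear.  A recording is
excluded when the post-calibration error exceeds 0.01 g, fewer than 3
valid days were obtained, or any 15-min period of the aggregated 24-h
clock cycle is never covered by wear across the whole (<= 14 day)
recording.  Average acceleration (a total-activity proxy) and time above
the 100 mg moderate-to-vigorous threshold are computed per valid day and
averaged, unweighted, across valid days.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import EpochSeries

__all__ = [
    "MVPA_THRESHOLD_MG",
    "MIN_WEAR_HOURS",
    "MIN_VALID_DAYS",
    "MAX_CALIBRATION_ERROR_G",
    "MAX_RECORDING_DAYS",
    "ValidationResult",
    "ActivityResult",
    "enmo_mg",
    "validate_series",
    "average_acceleration",
    "mvpa_minutes",
    "process_series",
]

MVPA_THRESHOLD_MG = 100.0
MIN_WEAR_HOURS = 16.0
MIN_VALID_DAYS = 3
MAX_CALIBRATION_ERROR_G = 0.01
MAX_RECORDING_DAYS = 14
_QUARTER_HOUR_BINS = 96


@dataclass(frozen=True)
class ValidationResult:
    valid_days: tuple[pd.Timestamp, ...]
    excluded: bool
    reason: str | None = None


@dataclass(frozen=True)
class ActivityResult:
    valid_days: int
    avg_acceleration: float | None  # mg
    mvpa_min_per_day: float | None  # min/day
    excluded: bool
    reason: str | None = None

    def __post_init__(self) -> None:
        if self.mvpa_min_per_day is not None and self.mvpa_min_per_day > 24 * 60:
            raise ValueError("MVPA cannot exceed 1440 min/day")
        if self.avg_acceleration is not None and self.avg_acceleration < 0:
            raise ValueError("average acceleration must be >= 0")


def enmo_mg(xyz_g: np.ndarray) -> np.ndarray:
    """Euclidean norm minus one gravity, floored at zero, in mg.

    ``xyz_g``: (n, 3) tri-axial accelerations in g.  This is the
    conventional epoch magnitude for raw wrist accelerometry; device
    autocalibration is assumed to have been applied upstream.
    """
    xyz = np.asarray(xyz_g, dtype=float)
    if xyz.ndim != 2 or xyz.shape[1] != 3:
        raise ValueError("expected an (n, 3) array of tri-axial accelerations in g")
    return np.maximum(np.linalg.norm(xyz, axis=1) - 1.0, 0.0) * 1000.0


def _frame(series: EpochSeries) -> pd.DataFrame:
    ts = series.timestamps
    df = pd.DataFrame(
        {"magnitude": series.magnitudes, "wear": series.wear},
        index=ts,
    )
    # recordings are capped at 14 days of wear protocol
    days = df.index.normalize().unique().sort_values()
    if len(days) > MAX_RECORDING_DAYS:
        df = df[df.index.normalize().isin(days[:MAX_RECORDING_DAYS])]
    return df


def validate_series(
    series: EpochSeries,
    min_wear_hours: float = MIN_WEAR_HOURS,
    min_valid_days: int = MIN_VALID_DAYS,
    max_calibration_error_g: float = MAX_CALIBRATION_ERROR_G,
) -> ValidationResult:
    """Apply the wear/validity rules to one recording.

    Exclusion depends only on the calibration error, wear flags and day
    count, never on the movement magnitudes.
    """
    if len(series) == 0:
        raise ValueError("empty epoch series")
    df = _frame(series)

    if series.calibration_error > max_calibration_error_g:
        return ValidationResult(
            (), True, f"calibration error {series.calibration_error:g} g > {max_calibration_error_g:g} g"
        )

    day = df.index.normalize()
    wear_s = df["wear"].groupby(day).sum() * series.epoch_length
    valid = wear_s[wear_s >= min_wear_hours * 3600.0]
    valid_days = tuple(valid.index.sort_values())
    if len(valid_days) < min_valid_days:
        return ValidationResult(
            valid_days, True, f"insufficient valid days ({len(valid_days)} < {min_valid_days})"
        )

    # every 15-min period of the 24-h clock cycle must see wear at least
    # once across the whole recording
    worn = df.index[df["wear"].to_numpy()]
    bins = (worn.hour * 4 + worn.minute // 15).unique()
    if len(bins) < _QUARTER_HOUR_BINS:
        missing = sorted(set(range(_QUARTER_HOUR_BINS)) - set(bins.tolist()))
        return ValidationResult(
            valid_days,
            True,
            f"no wear data in {len(missing)} of 96 quarter-hour periods of the 24-h cycle",
        )
    return ValidationResult(valid_days, False, None)


def _day_groups(series: EpochSeries, valid_days: Sequence[pd.Timestamp]):
    df = _frame(series)
    wanted = pd.DatetimeIndex(valid_days)
    if len(wanted) == 0:
        raise ValueError("no valid days supplied")
    day = df.index.normalize()
    for d in wanted:
        sub = df[(day == d) & df["wear"]]
        if sub.empty:
            raise ValueError(f"day {d.date()} listed valid but has no wear epochs")
        yield d, sub


def average_acceleration(series: EpochSeries, valid_days: Sequence[pd.Timestamp]) -> float:
    """Mean wear-epoch magnitude per valid day, averaged across days (mg)."""
    day_means = [sub["magnitude"].mean() for _, sub in _day_groups(series, valid_days)]
    return float(np.mean(day_means))


def mvpa_minutes(
    series: EpochSeries,
    valid_days: Sequence[pd.Timestamp],
    threshold: float = MVPA_THRESHOLD_MG,
) -> float:
    """Daily minutes with wear-epoch magnitude strictly above ``threshold`` mg."""
    if not threshold > 0:
        raise ValueError("MVPA threshold must be positive")
    per_day = [
        (sub["magnitude"] > threshold).sum() * series.epoch_length / 60.0
        for _, sub in _day_groups(series, valid_days)
    ]
    return float(np.mean(per_day))


def process_series(
    series: EpochSeries,
    threshold: float = MVPA_THRESHOLD_MG,
) -> ActivityResult:
    """Validity rules plus both activity summaries for one recording."""
    v = validate_series(series)
    if v.excluded:
        return ActivityResult(len(v.valid_days), None, None, True, v.reason)
    return ActivityResult(
        valid_days=len(v.valid_days),
        avg_acceleration=average_acceleration(series, v.valid_days),
        mvpa_min_per_day=mvpa_minutes(series, v.valid_days, threshold),
        excluded=False,
    )
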