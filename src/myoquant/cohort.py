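"""Domain records: subjects, measurements, slice stacks, Dixon ROIs, epoch series."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ARMS",
    "ASCITES_GRADES",
    "OEDEMA_GRADES",
    "Subject",
    "SubjectMeasurements",
    "SliceStack",
    "DixonROI",
    "EpochSeries",
    "Cohort",
]

ARMS = ("ESLD", "HC")
ASCITES_GRADES = ("none", "mild", "moderate", "severe")
OEDEMA_GRADES = ("none", "mild", "moderate")

#: relative tolerance on inter-slice spacing uniformity
SPACING_RTOL = 1e-6


@dataclass(frozen=True)
class Subject:
    """One participant: demographics plus clinical fluid-overload grades."""

    id: str
    arm: str
    sex: str
    age: float  # years
    height: float  # m
    measured_weight: float  # kg
    ascites_grade: str = "none"
    oedema_grade: str = "none"

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"subject {self.id}: unknown arm {self.arm!r}")
        if self.sex not in ("M", "F"):
            raise ValueError(f"subject {self.id}: sex must be 'M' or 'F'")
        if not self.height > 0:
            raise ValueError(f"subject {self.id}: height must be > 0")
        if not self.measured_weight > 0:
            raise ValueError(f"subject {self.id}: measured_weight must be > 0")
        if self.ascites_grade not in ASCITES_GRADES:
            raise ValueError(f"subject {self.id}: unknown ascites grade {self.ascites_grade!r}")
        if self.oedema_grade not in OEDEMA_GRADES:
            raise ValueError(f"subject {self.id}: unknown oedema grade {self.oedema_grade!r}")
        if self.arm == "HC" and (self.ascites_grade != "none" or self.oedema_grade != "none"):
            raise ValueError(f"subject {self.id}: healthy controls carry no fluid overload")


@dataclass(frozen=True)
class SubjectMeasurements:
    """Measured primitives for one subject.

    mac/tsf: mid-arm circumference (cm) and triceps skinfold (mm);
    vl_thickness_triplicate: three ultrasound repeats (cm);
    us_efov_acsa: extended-field-of-view ultrasound quadriceps ACSA (cm^2);
    torque_trials: up to five isokinetic knee-extension peaks (N*m);
    grip_trials: up to three handgrip attempts (kg);
    chair_stand_time: five-repetition sit-to-stand time (s).
    """

    mac: float
    tsf: float
    vl_thickness_triplicate: tuple[float, float, float]
    pennation_angle: float
    fascicle_length: float
    us_efov_acsa: float
    torque_trials: tuple[float, ...]
    grip_trials: tuple[float, ...]
    chair_stand_time: float

    def __post_init__(self) -> None:
        scalars = {
            "mac": self.mac,
            "tsf": self.tsf,
            "pennation_angle": self.pennation_angle,
            "fascicle_length": self.fascicle_length,
            "us_efov_acsa": self.us_efov_acsa,
            "chair_stand_time": self.chair_stand_time,
        }
        for name, v in scalars.items():
            if not v > 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")
        if not 0 < self.pennation_angle < 45:
            raise ValueError("pennation_angle must lie in (0, 45) degrees")
        for name, trials in (
            ("vl_thickness_triplicate", self.vl_thickness_triplicate),
            ("torque_trials", self.torque_trials),
            ("grip_trials", self.grip_trials),
        ):
            if any(not t > 0 for t in trials):
                raise ValueError(f"{name} values must be strictly positive")


@dataclass(frozen=True)
class SliceStack:
    """Ordered MRI cross-sections of one muscle ROI along the limb axis.

    Positions are cm along the femur axis (origin at the greater
    trochanter, increasing distally); areas are contractile-tissue
    cross-sectional areas in cm^2 with non-contractile regions already
    excluded at segmentation time.
    """

    muscle: str
    positions: tuple[float, ...]
    thickness: float  # cm, uniform slice thickness (= inter-slice spacing)
    areas: tuple[float, ...]
    roi_limits: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.areas):
            raise ValueError("positions and areas must have equal length")
        if len(self.positions) == 0:
            raise ValueError("slice stack must contain at least one slice")
        pos = np.asarray(self.positions, dtype=float)
        if np.any(np.diff(pos) <= 0):
            raise ValueError("slice positions must be strictly increasing")
        if not self.thickness > 0:
            raise ValueError("slice thickness must be positive")
        if any(not a > 0 for a in self.areas):
            raise ValueError("all slice areas must be strictly positive")
        if len(pos) >= 2:
            gaps = np.diff(pos)
            if np.any(np.abs(gaps - gaps[0]) > SPACING_RTOL * max(abs(gaps[0]), 1.0)):
                raise ValueError("inter-slice spacing must be uniform")

    @property
    def n_slices(self) -> int:
        return len(self.positions)

    @property
    def spacing(self) -> float:
        if self.n_slices < 2:
            return self.thickness
        return self.positions[1] - self.positions[0]


@dataclass(frozen=True)
class DixonROI:
    """Mean fat/water signal intensities of a two-point Dixon muscle ROI."""

    si_fat: float
    si_water: float

    def __post_init__(self) -> None:
        if self.si_fat < 0 or self.si_water < 0:
            raise ValueError("signal intensities must be non-negative")
        if not self.si_fat + self.si_water > 0:
            raise ValueError("total Dixon signal must be positive")

    @classmethod
    def from_maps(
        cls,
        fat_map: np.ndarray,
        water_map: np.ndarray,
        mask: np.ndarray | None = None,
    ) -> "DixonROI":
        """Reduce paired fat/water images to ROI mean signal intensities."""
        fat = np.asarray(fat_map, dtype=float)
        water = np.asarray(water_map, dtype=float)
        if fat.shape != water.shape:
            raise ValueError("fat and water maps must share a shape")
        if mask is None:
            mask = np.ones(fat.shape, dtype=bool)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != fat.shape:
            raise ValueError("mask shape must match the maps")
        if not mask.any():
            raise ValueError("ROI mask is empty")
        # negative noise excursions are clipped: signal magnitude images
        return cls(
            si_fat=float(np.clip(fat[mask], 0.0, None).mean()),
            si_water=float(np.clip(water[mask], 0.0, None).mean()),
        )


class EpochSeries:
    """Uniformly sampled accelerometer epochs with wear flags.

    magnitudes are epoch-level ENMO-style movement magnitudes in mg;
    calibration_error is the residual post-autocalibration error in g.
    """

    def __init__(
        self,
        start: pd.Timestamp | str,
        epoch_length: float,
        magnitudes: Sequence[float],
        wear: Sequence[bool] | None = None,
        calibration_error: float = 0.0,
    ) -> None:
        if epoch_length <= 0:
            raise ValueError("epoch_length must be positive seconds")
        self.start = pd.Timestamp(start)
        if self.start is pd.NaT:
            raise ValueError("malformed start timestamp")
        self.epoch_length = float(epoch_length)
        self.magnitudes = np.asarray(magnitudes, dtype=float)
        if self.magnitudes.ndim != 1 or self.magnitudes.size == 0:
            raise ValueError("magnitudes must be a non-empty 1-D sequence")
        if np.any(self.magnitudes < 0):
            raise ValueError("magnitudes must be non-negative")
        if wear is None:
            wear = np.ones(self.magnitudes.size, dtype=bool)
        self.wear = np.asarray(wear, dtype=bool)
        if self.wear.shape != self.magnitudes.shape:
            raise ValueError("wear flags must align with magnitudes")
        if calibration_error < 0:
            raise ValueError("calibration_error must be non-negative")
        self.calibration_error = float(calibration_error)

    def __len__(self) -> int:
        return self.magnitudes.size

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.start + pd.to_timedelta(
            np.arange(self.magnitudes.size) * self.epoch_length, unit="s"
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EpochSeries):
            return NotImplemented
        return (
            self.start == other.start
            and self.epoch_length == other.epoch_length
            and self.calibration_error == other.calibration_error
            and np.array_equal(self.magnitudes, other.magnitudes)
            and np.array_equal(self.wear, other.wear)
        )

    def __repr__(self) -> str:
        return (
            f"EpochSeries(start={self.start.isoformat()}, epoch={self.epoch_length:g}s, "
            f"n={len(self)}, calib={self.calibration_error:g}g)"
        )


@dataclass
class Cohort:
    """A complete two-arm cohort with every per-subject record set.

    ``truth`` holds the generator's per-subject ground-truth draws (latent
    factor and true values of each derived quantity) for calibration
    checks; an empirical cohort read from disk may carry an empty frame.
    """

    subjects: list[Subject]
    measurements: dict[str, SubjectMeasurements]
    slice_stacks: dict[str, dict[str, SliceStack]]
    dixon: dict[str, DixonROI]
    accel: dict[str, EpochSeries]
    truth: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("subject ids must be unique")
        for name, mapping in (
            ("measurements", self.measurements),
            ("slice_stacks", self.slice_stacks),
            ("dixon", self.dixon),
            ("accel", self.accel),
        ):
            missing = [i for i in ids if i not in mapping]
            if missing:
                raise ValueError(f"incomplete cohort: no {name} record for {missing}")

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.subjects]

    def subject(self, subject_id: str) -> Subject:
        for s in self.subjects:
            if s.id == subject_id:
                return s
        raise KeyError(subject_id)

    def arm_ids(self, arm: str) -> list[str]:
        return [s.id for s in self.subjects if s.arm == arm]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        if self.subjects != other.subjects:
            return False
        if self.measurements != other.measurements:
            return False
        if self.slice_stacks != other.slice_stacks:
            return False
        if self.dixon != other.dixon:
            return False
        if self.accel != other.accel:
            return False
        if self.truth.empty and other.truth.empty:
            return True
        try:
            pd.testing.assert_frame_equal(self.truth, other.truth)
        except AssertionError:
            return False
        return True
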