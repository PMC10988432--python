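"""Plain-text cohort serialisation.

Layout under a cohort directory:

    cohort.csv            one row per subject: demographics + measurements
    truth.csv             generator ground truth (optional)
    slices/<id>_<muscle>.csv   position_cm, thickness_cm, area_cm2
    dixon/<id>.csv        si_fat, si_water (ROI mean signal intensities)
    accel/<id>.csv        epoch_start_iso8601, magnitude_mg, wear_flag

Floats are written with 17 significant digits and parsed back with
round-trip precision, so read(write(cohort)) is an exact field-for-field
round trip and repeated writes are byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort, DixonROI, EpochSeries, SliceStack, Subject, SubjectMeasurements

__all__ = ["SchemaError", "write_cohort", "read_cohort"]


class SchemaError(ValueError):
    """A cohort file violates the expected schema."""


_SUBJECT_COLS = [
    "id",
    "arm",
    "sex",
    "age",
    "height_m",
    "measured_weight_kg",
    "ascites_grade",
    "oedema_grade",
]
_MEAS_COLS = [
    "mac_cm",
    "tsf_mm",
    "vl_thickness_cm_1",
    "vl_thickness_cm_2",
    "vl_thickness_cm_3",
    "pennation_deg",
    "fascicle_length_cm",
    "us_efov_acsa_cm2",
    "torque_nm_1",
    "torque_nm_2",
    "torque_nm_3",
    "torque_nm_4",
    "torque_nm_5",
    "grip_kg_1",
    "grip_kg_2",
    "grip_kg_3",
    "chair_stand_s",
    "accel_epoch_s",
    "accel_calibration_error_g",
]

_MUSCLES = ("quadriceps", "VL", "L3")


def write_cohort(cohort: Cohort, directory: str | Path) -> None:
    """Write a cohort as the documented CSV file set."""
    root = Path(directory)
    (root / "slices").mkdir(parents=True, exist_ok=True)
    (root / "dixon").mkdir(exist_ok=True)
    (root / "accel").mkdir(exist_ok=True)

    rows = []
    for s in cohort.subjects:
        m = cohort.measurements[s.id]
        a = cohort.accel[s.id]
        row = {
            "id": s.id,
            "arm": s.arm,
            "sex": s.sex,
            "age": s.age,
            "height_m": s.height,
            "measured_weight_kg": s.measured_weight,
            "ascites_grade": s.ascites_grade,
            "oedema_grade": s.oedema_grade,
            "mac_cm": m.mac,
            "tsf_mm": m.tsf,
            "pennation_deg": m.pennation_angle,
            "fascicle_length_cm": m.fascicle_length,
            "us_efov_acsa_cm2": m.us_efov_acsa,
            "chair_stand_s": m.chair_stand_time,
            "accel_epoch_s": a.epoch_length,
            "accel_calibration_error_g": a.calibration_error,
        }
        for k, v in enumerate(m.vl_thickness_triplicate, 1):
            row[f"vl_thickness_cm_{k}"] = v
        for k in range(1, 6):
            row[f"torque_nm_{k}"] = (
                m.torque_trials[k - 1] if k <= len(m.torque_trials) else np.nan
            )
        for k in range(1, 4):
            row[f"grip_kg_{k}"] = m.grip_trials[k - 1] if k <= len(m.grip_trials) else np.nan
        rows.append(row)
    pd.DataFrame(rows, columns=_SUBJECT_COLS + _MEAS_COLS).to_csv(
        root / "cohort.csv", index=False, float_format="%.17g"
    )

    if not cohort.truth.empty:
        cohort.truth.to_csv(root / "truth.csv", float_format="%.17g")

    for sid, per_muscle in cohort.slice_stacks.items():
        for muscle, stack in per_muscle.items():
            frame = pd.DataFrame(
                {
                    "position_cm": stack.positions,
                    "thickness_cm": [stack.thickness] * stack.n_slices,
                    "area_cm2": stack.areas,
                }
            )
            if stack.roi_limits is not None:
                frame["roi_proximal_cm"] = stack.roi_limits[0]
                frame["roi_distal_cm"] = stack.roi_limits[1]
            frame.to_csv(
                root / "slices" / f"{sid}_{muscle}.csv", index=False, float_format="%.17g"
            )

    for sid, roi in cohort.dixon.items():
        pd.DataFrame({"si_fat": [roi.si_fat], "si_water": [roi.si_water]}).to_csv(
            root / "dixon" / f"{sid}.csv", index=False, float_format="%.17g"
        )

    for sid, series in cohort.accel.items():
        pd.DataFrame(
            {
                "epoch_start_iso8601": series.timestamps.strftime("%Y-%m-%dT%H:%M:%S"),
                "magnitude_mg": series.magnitudes,
                "wear_flag": series.wear.astype(int),
            }
        ).to_csv(root / "accel" / f"{sid}.csv", index=False, float_format="%.17g")


def _require_columns(df: pd.DataFrame, cols: list[str], fname: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{fname}: missing columns {missing}")


def _check_positive(df: pd.DataFrame, col: str, fname: str) -> None:
    bad = df.index[~(df[col] > 0)]
    if len(bad):
        raise SchemaError(
            f"{fname}: row {int(bad[0]) + 2}, field {col!r}: value must be > 0 "
            f"(got {df.loc[bad[0], col]!r})"
        )


def read_cohort(directory: str | Path) -> Cohort:
    """Read a cohort directory, validating the schema.

    Violations raise :class:`SchemaError` naming the file, row and field;
    a subject missing one of its record files is reported by id.
    """
    root = Path(directory)
    fname = "cohort.csv"
    path = root / fname
    if not path.exists():
        raise SchemaError(f"{fname} not found under {root}")
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, _SUBJECT_COLS + _MEAS_COLS, fname)
    for col in ("height_m", "measured_weight_kg", "mac_cm", "chair_stand_s"):
        _check_positive(df, col, fname)

    subjects: list[Subject] = []
    measurements: dict[str, SubjectMeasurements] = {}
    stacks: dict[str, dict[str, SliceStack]] = {}
    dixon: dict[str, DixonROI] = {}
    accel: dict[str, EpochSeries] = {}

    for i, row in df.iterrows():
        sid = str(row["id"])
        try:
            subjects.append(
                Subject(
                    id=sid,
                    arm=str(row["arm"]),
                    sex=str(row["sex"]),
                    age=float(row["age"]),
                    height=float(row["height_m"]),
                    measured_weight=float(row["measured_weight_kg"]),
                    ascites_grade=str(row["ascites_grade"]),
                    oedema_grade=str(row["oedema_grade"]),
                )
            )
            torque = tuple(
                float(row[f"torque_nm_{k}"])
                for k in range(1, 6)
                if pd.notna(row[f"torque_nm_{k}"])
            )
            grip = tuple(
                float(row[f"grip_kg_{k}"]) for k in range(1, 4) if pd.notna(row[f"grip_kg_{k}"])
            )
            measurements[sid] = SubjectMeasurements(
                mac=float(row["mac_cm"]),
                tsf=float(row["tsf_mm"]),
                vl_thickness_triplicate=tuple(
                    float(row[f"vl_thickness_cm_{k}"]) for k in range(1, 4)
                ),
                pennation_angle=float(row["pennation_deg"]),
                fascicle_length=float(row["fascicle_length_cm"]),
                us_efov_acsa=float(row["us_efov_acsa_cm2"]),
                torque_trials=torque,
                grip_trials=grip,
                chair_stand_time=float(row["chair_stand_s"]),
            )
        except ValueError as e:
            raise SchemaError(f"{fname}: row {int(i) + 2}: {e}") from e

        per_muscle: dict[str, SliceStack] = {}
        for muscle in _MUSCLES:
            spath = root / "slices" / f"{sid}_{muscle}.csv"
            if not spath.exists():
                raise SchemaError(f"missing slice file for subject {sid}: {spath.name}")
            sdf = pd.read_csv(spath, float_precision="round_trip")
            _require_columns(sdf, ["position_cm", "thickness_cm", "area_cm2"], spath.name)
            limits = None
            if "roi_proximal_cm" in sdf.columns and "roi_distal_cm" in sdf.columns:
                limits = (
                    float(sdf["roi_proximal_cm"].iloc[0]),
                    float(sdf["roi_distal_cm"].iloc[0]),
                )
            try:
                per_muscle[muscle] = SliceStack(
                    muscle=muscle,
                    positions=tuple(float(p) for p in sdf["position_cm"]),
                    thickness=float(sdf["thickness_cm"].iloc[0]),
                    areas=tuple(float(a) for a in sdf["area_cm2"]),
                    roi_limits=limits,
                )
            except ValueError as e:
                raise SchemaError(f"{spath.name}: {e}") from e
        stacks[sid] = per_muscle

        dpath = root / "dixon" / f"{sid}.csv"
        if not dpath.exists():
            raise SchemaError(f"missing Dixon file for subject {sid}: {dpath.name}")
        ddf = pd.read_csv(dpath, float_precision="round_trip")
        _require_columns(ddf, ["si_fat", "si_water"], dpath.name)
        try:
            dixon[sid] = DixonROI(float(ddf["si_fat"].iloc[0]), float(ddf["si_water"].iloc[0]))
        except ValueError as e:
            raise SchemaError(f"{dpath.name}: {e}") from e

        apath = root / "accel" / f"{sid}.csv"
        if not apath.exists():
            raise SchemaError(f"missing accelerometer file for subject {sid}: {apath.name}")
        adf = pd.read_csv(apath, float_precision="round_trip")
        _require_columns(adf, ["epoch_start_iso8601", "magnitude_mg", "wear_flag"], apath.name)
        try:
            accel[sid] = EpochSeries(
                start=adf["epoch_start_iso8601"].iloc[0],
                epoch_length=float(row["accel_epoch_s"]),
                magnitudes=adf["magnitude_mg"].to_numpy(dtype=float),
                wear=adf["wear_flag"].to_numpy(dtype=bool),
                calibration_error=float(row["accel_calibration_error_g"]),
            )
        except ValueError as e:
            raise SchemaError(f"{apath.name}: {e}") from e

    tpath = root / "truth.csv"
    truth = pd.read_csv(tpath, index_col="id", float_precision="round_trip") if tpath.exists() else pd.DataFrame()
    return Cohort(
        subjects=subjects,
        measurements=measurements,
        slice_stacks=stacks,
        dixon=dixon,
        accel=accel,
        truth=truth,
    )
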