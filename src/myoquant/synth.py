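"""Synthetic two-arm cohort generator.

Each subject receives a latent standard-normal "muscle size" factor; the
size-linked variables (mid-thigh ACSA, quadriceps volume index, VL
thickness, peak torque) are drawn as z = loading*L + sqrt(1-loading^2)*e,
so within-arm correlations equal the loading products.  Raw records are
then synthesised backwards from the drawn true values: serial MRI slice
stacks whose frustum volume and mid-slice area match the subject's true
volume and mid-ACSA; Dixon fat/water signal maps whose masked means
recover the true fat fraction; repeated strength trials whose maximum is
the true peak; and epoch-level accelerometer series whose per-day wear
means and above-threshold minutes match the subject's activity targets.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cohort import Cohort, DixonROI, EpochSeries, SliceStack, Subject, SubjectMeasurements
from .config import (
    ArmParams,
    GeneratorConfig,
    LognormalVar,
    NormalVar,
    default_config,
)

__all__ = ["generate_cohort", "generate_slice_stack"]

# deterministic draw order for the per-arm variable block
_VAR_ORDER = (
    "age",
    "height",
    "weight",
    "mamc",
    "tsf",
    "vl_thickness",
    "pennation",
    "fascicle_length",
    "mid_acsa",
    "quad_volume_index",
    "l3_smi",
    "imat_pct",
    "peak_torque",
    "grip",
    "chair_time",
    "pcsa_eff",
    "avg_acceleration",
    "mvpa",
)

_ASCITES = ("none", "mild", "moderate", "severe")
_OEDEMA = ("none", "mild", "moderate")
_ACCEL_START = pd.Timestamp("2020-01-06 00:00:00")  # a Monday


def _draw_truncated(rng: np.random.Generator, n: int, load: float, latent: np.ndarray, var: NormalVar) -> np.ndarray:
    """Latent-linked truncated-normal draws (rejection on the noise term)."""
    resid = math.sqrt(max(1.0 - load * load, 0.0))
    z = load * latent + resid * rng.standard_normal(n)
    x = var.mean + var.sd * z
    for _ in range(200):
        bad = (x <= var.lower) | (x >= var.upper)
        if not bad.any():
            return x
        z_bad = load * latent[bad] + resid * rng.standard_normal(int(bad.sum()))
        x[bad] = var.mean + var.sd * z_bad
    raise RuntimeError(f"rejection sampling failed for bounds ({var.lower}, {var.upper})")


def _draw_arm(rng: np.random.Generator, n: int, params: ArmParams, latent_scale: float) -> pd.DataFrame:
    """Draw the true-value block for one arm, keyed on a shared latent factor."""
    latent = rng.standard_normal(n)
    cols: dict[str, np.ndarray] = {"latent": latent}
    for name in _VAR_ORDER:
        var = getattr(params, name)
        load = float(np.clip(var.loading * latent_scale, -1.0, 1.0))
        if isinstance(var, NormalVar):
            cols[name] = _draw_truncated(rng, n, load, latent, var)
        elif isinstance(var, LognormalVar):
            mu, sigma = var.mu_sigma
            resid = math.sqrt(max(1.0 - load * load, 0.0))
            z = load * latent + resid * rng.standard_normal(n)
            cols[name] = np.exp(mu + sigma * z)
        else:  # pragma: no cover
            raise TypeError(name)
    return pd.DataFrame(cols)


def _dome(offsets: np.ndarray, width_factor: float) -> np.ndarray:
    """Smooth unimodal profile, 1 at offset 0, decaying toward the ends."""
    dmax = float(np.max(np.abs(offsets)))
    if dmax == 0:
        return np.ones_like(offsets)
    w = width_factor * dmax
    return np.cos(0.5 * math.pi * offsets / w) ** 2


def _frustum(areas: np.ndarray, t: float) -> float:
    a = areas
    return float(((t / 3.0) * (a[:-1] + np.sqrt(a[:-1] * a[1:]) + a[1:])).sum())


def _solve_bracketed(fn, lo: float, hi: float) -> float:
    """Root of fn on [lo, hi]; nearest endpoint when the root lies outside."""
    f_lo, f_hi = fn(lo), fn(hi)
    if f_lo == 0.0:
        return lo
    if f_hi == 0.0:
        return hi
    if f_lo * f_hi > 0:
        return lo if abs(f_lo) < abs(f_hi) else hi
    return float(brentq(fn, lo, hi, xtol=1e-12))


def generate_slice_stack(
    subject: Subject,
    muscle: str,
    rng: np.random.Generator,
    targets: Mapping[str, float],
    config: GeneratorConfig | None = None,
) -> SliceStack:
    """Synthesise one muscle slice stack consistent with a subject's true values.

    ``targets`` carries the subject's ground-truth draws (quad_volume_index,
    mid_acsa, vl_volume, l3_csa as applicable).  Quadriceps stacks place
    6-8 slices at uniform 4 cm spacing across the restricted thigh ROI
    with one slice exactly at 50% femur length; the unimodal area profile
    is shaped so the frustum volume and the mid-slice area both match the
    subject's true values.  VL stacks span the full muscle; L3 stacks are
    a single 1 cm slice.
    """
    cfg = config or default_config()
    t = cfg.slice_spacing_cm
    femur_cm = cfg.femur_height_ratio * subject.height * 100.0
    mid = 0.5 * femur_cm

    if muscle == "quadriceps":
        n = int(rng.integers(6, 9))
        offsets = (np.arange(n) - n // 2) * t
        positions = mid + offsets
        a_mid = float(targets["mid_acsa"])
        v_target = float(targets["quad_volume_index"]) * subject.height**2

        # one-parameter unimodal profiles pinned to the mid-slice area:
        # below the flat-cylinder limit a_mid*L a mid-peaked dome whose
        # sharpness sets the volume; above it a Gaussian profile whose
        # peak shifts proximally of the 50%-femur slice (the mid slice
        # then sits on the descending limb, so its area stays a_mid
        # while the stack holds more volume)
        dmax = float(np.max(np.abs(offsets)))
        v_flat = _frustum(np.full(n, a_mid), t)
        if v_target < 0.999 * v_flat:
            cosine = np.cos(0.5 * math.pi * offsets / (1.05 * dmax))

            def profile(p: float) -> np.ndarray:
                return np.maximum(cosine ** (2.0 * p), 1e-9)

            def vol_err(p: float) -> float:
                return _frustum(a_mid * profile(p), t) - v_target

            areas = a_mid * profile(_solve_bracketed(vol_err, 1e-6, 50.0))
        else:
            s = 0.75 * dmax

            def profile(delta: float) -> np.ndarray:
                return np.maximum(
                    np.exp((delta**2 - (offsets + delta) ** 2) / (2.0 * s**2)), 1e-9
                )

            def vol_err(delta: float) -> float:
                return _frustum(a_mid * profile(delta), t) - v_target

            areas = a_mid * profile(_solve_bracketed(vol_err, 0.0, 3.0 * dmax))
        prox = positions[0] - 0.5 * t
        distal = positions[-1] + 0.5 * t
        return SliceStack(
            muscle="quadriceps",
            positions=tuple(float(p) for p in positions),
            thickness=t,
            areas=tuple(float(a) for a in areas),
            roi_limits=(float(prox), float(distal)),
        )

    if muscle == "VL":
        n = int(rng.integers(7, 10))
        offsets = (np.arange(n) - n // 2) * t
        positions = mid + offsets
        shape = _dome(offsets, width_factor=2.0)
        v_target = float(targets["vl_volume"])
        scale = v_target / _frustum(shape, t)
        return SliceStack(
            muscle="VL",
            positions=tuple(float(p) for p in positions),
            thickness=t,
            areas=tuple(float(a) for a in scale * shape),
            roi_limits=(float(positions[0]), float(positions[-1])),
        )

    if muscle == "L3":
        return SliceStack(
            muscle="L3",
            positions=(0.0,),
            thickness=cfg.l3_slice_thickness_cm,
            areas=(float(targets["l3_csa"]),),
        )

    raise ValueError(f"unknown muscle label {muscle!r}")


def _dixon_roi(rng: np.random.Generator, fat_fraction: float, cfg: GeneratorConfig) -> DixonROI:
    """Noisy paired fat/water maps under a circular mask, reduced to ROI means."""
    ny, nx = cfg.dixon_map_shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= (0.45 * min(ny, nx)) ** 2
    fat = rng.normal(fat_fraction * cfg.dixon_s0, cfg.dixon_noise_sd, size=(ny, nx))
    water = rng.normal((1.0 - fat_fraction) * cfg.dixon_s0, cfg.dixon_noise_sd, size=(ny, nx))
    return DixonROI.from_maps(fat, water, mask)


def _trials(rng: np.random.Generator, peak: float, n: int) -> tuple[float, ...]:
    """n trials whose maximum equals the drawn peak value."""
    others = peak * rng.uniform(0.80, 0.98, size=n - 1)
    vals = np.concatenate([[peak], others])
    rng.shuffle(vals)
    return tuple(float(v) for v in vals)


def _epoch_series(
    rng: np.random.Generator,
    avg_target: float,
    mvpa_target: float,
    cfg: GeneratorConfig,
) -> EpochSeries:
    """Daily epoch magnitudes hitting the subject's activity targets.

    Each day receives ``k`` above-threshold "bout" epochs (k * epoch/60 ~
    the subject's MVPA minutes) with gamma-distributed excess over the
    100 mg threshold, and below-threshold background epochs whose mean is
    solved so the day's wear-epoch mean matches the subject's average
    acceleration.
    """
    prof = cfg.accel
    n_day = 86400 // prof.epoch_s
    wear_epochs_day = int(round(prof.wear_hours_per_day * 3600 / prof.epoch_s))
    mags_all, wear_all = [], []
    for day in range(prof.days):
        a_day = max(avg_target * (1.0 + prof.day_cv * rng.standard_normal()), 1.0)
        m_day = max(mvpa_target * (1.0 + 1.5 * prof.day_cv * rng.standard_normal()), 0.0)
        k = int(round(m_day * 60.0 / prof.epoch_s))
        k = min(k, wear_epochs_day - 1)
        budget = a_day * wear_epochs_day
        # keep the bout total inside the day's magnitude budget
        if k > 0 and k * 105.0 > 0.85 * budget:
            k = max(int(0.85 * budget / 105.0), 0)
        if k > 0:
            active = 100.0 + rng.gamma(prof.active_excess_shape, prof.active_excess_scale, size=k)
            excess = active.sum() - 100.0 * k
            cap = 0.85 * budget - 100.0 * k
            if excess > cap > 0:
                active = 100.0 + (active - 100.0) * (cap / excess)
            active_sum = float(active.sum())
        else:
            active = np.empty(0)
            active_sum = 0.0
        n_bg = wear_epochs_day - k
        bg_mean = max((budget - active_sum) / n_bg, 0.5)
        bg = np.minimum(rng.gamma(5.0, bg_mean / 5.0, size=n_bg), 99.0)
        day_mags = np.concatenate([active, bg])
        rng.shuffle(day_mags)
        wear = np.ones(n_day, dtype=bool)
        mags = np.zeros(n_day)
        if wear_epochs_day < n_day:
            # rotate the non-wear block across days so every quarter-hour
            # clock bin is covered at least once over the recording
            off = (day * 977) % n_day
            nonwear = (np.arange(n_day - wear_epochs_day) + off) % n_day
            wear[nonwear] = False
        mags[wear] = day_mags
        mags_all.append(mags)
        wear_all.append(wear)
    return EpochSeries(
        start=_ACCEL_START,
        epoch_length=float(prof.epoch_s),
        magnitudes=np.concatenate(mags_all),
        wear=np.concatenate(wear_all),
        calibration_error=prof.calibration_error_g,
    )


def generate_cohort(config: GeneratorConfig | None = None, seed: int | None = None) -> Cohort:
    """Generate the synthetic two-arm cohort.

    Deterministic for identical (config, seed); ``seed`` overrides
    ``config.seed`` when given.
    """
    cfg = config or default_config()
    if seed is None:
        seed = cfg.seed
    if not isinstance(seed, (int, np.integer)) or isinstance(seed, bool):
        raise TypeError("seed must be an integer")
    rng = np.random.default_rng(int(seed))

    subjects: list[Subject] = []
    measurements: dict[str, SubjectMeasurements] = {}
    stacks: dict[str, dict[str, SliceStack]] = {}
    dixon: dict[str, DixonROI] = {}
    accel: dict[str, EpochSeries] = {}
    truth_rows = []

    for arm, n, params in (("ESLD", cfg.n_esld, cfg.esld), ("HC", cfg.n_hc, cfg.hc)):
        block = _draw_arm(rng, n, params, cfg.latent_size_loading)
        sexes = np.where(rng.random(n) < params.p_male, "M", "F")
        ascites = rng.choice(_ASCITES, size=n, p=params.fluid.ascites)
        oedema = rng.choice(_OEDEMA, size=n, p=params.fluid.oedema)
        for i in range(n):
            row = block.iloc[i]
            sid = f"{arm}{i + 1:03d}"
            subj = Subject(
                id=sid,
                arm=arm,
                sex=str(sexes[i]),
                age=float(row["age"]),
                height=float(row["height"]),
                measured_weight=float(row["weight"]),
                ascites_grade=str(ascites[i]),
                oedema_grade=str(oedema[i]),
            )
            subjects.append(subj)

            mac = float(row["mamc"]) + math.pi * float(row["tsf"]) / 10.0
            vl_trip = tuple(
                float(v)
                for v in row["vl_thickness"] + rng.normal(0.0, cfg.vl_triplicate_sd, size=3)
            )
            us_acsa = float(row["mid_acsa"]) * max(1.0 + cfg.us_cv * rng.standard_normal(), 0.5)
            measurements[sid] = SubjectMeasurements(
                mac=mac,
                tsf=float(row["tsf"]),
                vl_thickness_triplicate=vl_trip,
                pennation_angle=float(row["pennation"]),
                fascicle_length=float(row["fascicle_length"]),
                us_efov_acsa=us_acsa,
                torque_trials=_trials(rng, float(row["peak_torque"]), 5),
                grip_trials=_trials(rng, float(row["grip"]), 3),
                chair_stand_time=float(row["chair_time"]),
            )

            vl_volume = (
                float(row["pcsa_eff"])
                / math.cos(math.radians(float(row["pennation"])))
                * float(row["fascicle_length"])
            )
            targets = {
                "mid_acsa": float(row["mid_acsa"]),
                "quad_volume_index": float(row["quad_volume_index"]),
                "vl_volume": vl_volume,
                "l3_csa": float(row["l3_smi"]) * subj.height**2,
            }
            stacks[sid] = {
                m: generate_slice_stack(subj, m, rng, targets, cfg)
                for m in ("quadriceps", "VL", "L3")
            }
            dixon[sid] = _dixon_roi(rng, float(row["imat_pct"]) / 100.0, cfg)
            accel[sid] = _epoch_series(
                rng, float(row["avg_acceleration"]), float(row["mvpa"]), cfg
            )
            truth_rows.append({"id": sid, "arm": arm, "vl_volume": vl_volume, **row.to_dict()})

    truth = pd.DataFrame(truth_rows).set_index("id")
    return Cohort(
        subjects=subjects,
        measurements=measurements,
        slice_stacks=stacks,
        dixon=dixon,
        accel=accel,
        truth=truth,
    )
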