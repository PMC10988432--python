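"""End-to-end derivation and reporting.

``derive_measures`` reduces every subject's raw records to the full
phenotype panel (anthropometry, MRI morphometry, strength/function,
activity); ``group_report`` and ``correlation_report`` then apply the
normality-gated two-group statistics across the panel.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .accelerometry import process_series
from .anthropometry import derive_anthropometry
from .cohort import Cohort
from .config import GeneratorConfig, default_config
from .morphometry import dixon_imat, frustum_volume, l3_smi, mid_acsa, pcsa_eff, volume_index
from .stats import compare_groups, correlate
from .strength import peak_of_trials, specific_force

__all__ = [
    "REPORT_VARIABLES",
    "CORRELATION_PAIRS",
    "derive_measures",
    "group_report",
    "correlation_report",
    "report_markdown",
]

#: panel compared between arms, in report order
REPORT_VARIABLES = [
    "age",
    "height",
    "weight",
    "dry_weight",
    "bmi",
    "dry_bmi",
    "mamc",
    "vl_thickness",
    "us_acsa",
    "mri_mid_acsa",
    "quad_volume_index",
    "l3_smi",
    "imat_pct",
    "pennation",
    "fascicle_length",
    "pcsa_eff",
    "peak_torque",
    "grip",
    "chair_time",
    "specific_force",
    "avg_acceleration",
    "mvpa",
]

#: within-ESLD imaging agreement and mass-strength pairs
CORRELATION_PAIRS = [
    ("vl_thickness", "mri_mid_acsa"),
    ("vl_thickness", "quad_volume_index"),
    ("vl_thickness", "l3_smi"),
    ("us_acsa", "mri_mid_acsa"),
    ("us_acsa", "quad_volume_index"),
    ("us_acsa", "l3_smi"),
    ("mri_mid_acsa", "peak_torque"),
    ("quad_volume_index", "peak_torque"),
]


def derive_measures(cohort: Cohort, config: GeneratorConfig | None = None) -> pd.DataFrame:
    """Per-subject derived phenotype panel, indexed by subject id.

    ``config`` supplies the femur-length convention used to locate the
    50%-femur slice; the generator default applies when omitted.
    """
    cfg = config or default_config()
    rows = []
    for subj in cohort.subjects:
        m = cohort.measurements[subj.id]
        anth = derive_anthropometry(
            m.mac, m.tsf, subj.measured_weight, subj.height, subj.ascites_grade, subj.oedema_grade
        )

        quad = cohort.slice_stacks[subj.id]["quadriceps"]
        vl = cohort.slice_stacks[subj.id]["VL"]
        l3 = cohort.slice_stacks[subj.id]["L3"]
        quad_vol = frustum_volume(quad)
        femur_cm = cfg.femur_height_ratio * subj.height * 100.0
        acsa = mid_acsa(quad, 0.5 * femur_cm)
        imat = dixon_imat(cohort.dixon[subj.id])
        vl_vol = frustum_volume(vl)
        pcsa, eff = pcsa_eff(vl_vol, m.fascicle_length, m.pennation_angle)

        torque = peak_of_trials(m.torque_trials, 5)
        grip = peak_of_trials(m.grip_trials, 3)
        activity = process_series(cohort.accel[subj.id])

        rows.append(
            {
                "id": subj.id,
                "arm": subj.arm,
                "sex": subj.sex,
                "age": subj.age,
                "height": subj.height,
                "weight": subj.measured_weight,
                "dry_weight": anth.dry_weight,
                "bmi": anth.bmi,
                "dry_bmi": anth.dry_bmi,
                "mamc": anth.mamc,
                "vl_thickness": float(np.mean(m.vl_thickness_triplicate)),
                "us_acsa": m.us_efov_acsa,
                "mri_mid_acsa": acsa,
                "quad_volume": quad_vol,
                "quad_volume_index": volume_index(quad_vol, subj.height),
                "l3_smi": l3_smi(l3.areas[0], subj.height),
                "imat_pct": imat,
                "pennation": m.pennation_angle,
                "fascicle_length": m.fascicle_length,
                "vl_volume": vl_vol,
                "pcsa": pcsa,
                "pcsa_eff": eff,
                "peak_torque": torque,
                "grip": grip,
                "chair_time": m.chair_stand_time,
                "specific_force": specific_force(torque, acsa, imat),
                "accel_excluded": activity.excluded,
                "accel_exclusion_reason": activity.reason,
                "accel_valid_days": activity.valid_days,
                "avg_acceleration": activity.avg_acceleration,
                "mvpa": activity.mvpa_min_per_day,
            }
        )
    return pd.DataFrame(rows).set_index("id")


def group_report(
    derived: pd.DataFrame,
    variables: list[str] | None = None,
    alpha: float = 0.05,
    force_test: str = "auto",
) -> pd.DataFrame:
    """Arm-wise comparison table (one row per variable)."""
    variables = variables or REPORT_VARIABLES
    esld = derived[derived["arm"] == "ESLD"]
    hc = derived[derived["arm"] == "HC"]
    rows = []
    for var in variables:
        a = esld[var].dropna().to_numpy(dtype=float)
        b = hc[var].dropna().to_numpy(dtype=float)
        c = compare_groups(a, b, variable=var, alpha=alpha, force_test=force_test)
        rows.append(
            {
                "variable": var,
                "n_esld": c.n_a,
                "n_hc": c.n_b,
                "esld_centre": c.summary_a[0],
                "esld_spread": c.summary_a[1],
                "hc_centre": c.summary_b[0],
                "hc_spread": c.summary_b[1],
                "summary_style": c.summary_style,
                "test_used": c.test_used,
                "statistic": c.statistic,
                "p_value": c.p_value,
                "cohens_d": c.cohens_d,
                "percent_diff": c.percent_diff,
                "significant": c.significant,
            }
        )
    return pd.DataFrame(rows).set_index("variable")


def correlation_report(
    derived: pd.DataFrame,
    pairs: list[tuple[str, str]] | None = None,
    arm: str = "ESLD",
) -> pd.DataFrame:
    """Within-arm correlations for the configured variable pairs."""
    pairs = pairs or CORRELATION_PAIRS
    sub = derived[derived["arm"] == arm]
    rows = []
    for x, y in pairs:
        paired = sub[[x, y]].dropna()
        r, p, method = correlate(paired[x], paired[y])
        rows.append({"x": x, "y": y, "n": len(paired), "r": r, "p_value": p, "method": method})
    return pd.DataFrame(rows)


def report_markdown(comparisons: pd.DataFrame, correlations: pd.DataFrame) -> str:
    """Plain-markdown report mirroring the comparison and correlation panels."""
    lines = [
        "# Muscle phenotype group comparison (ESLD vs HC)",
        "",
        "| variable | ESLD | HC | test | p | d | %diff |",
        "|---|---|---|---|---|---|---|",
    ]
    for var, row in comparisons.iterrows():
        sep = "±" if row["summary_style"] == "mean_sd" else "IQR "
        fmt = (
            lambda c, s: f"{c:.1f} ± {s:.1f}"
            if row["summary_style"] == "mean_sd"
            else f"{c:.1f} ({s:.1f})"
        )
        lines.append(
            f"| {var} | {fmt(row['esld_centre'], row['esld_spread'])} "
            f"| {fmt(row['hc_centre'], row['hc_spread'])} "
            f"| {row['test_used']} | {row['p_value']:.4g} "
            f"| {row['cohens_d']:.2f} | {row['percent_diff']:+.1f}% |"
        )
    lines += [
        "",
        "## Within-ESLD correlations",
        "",
        "| x | y | n | r | p | method |",
        "|---|---|---|---|---|---|",
    ]
    for _, row in correlations.iterrows():
        lines.append(
            f"| {row['x']} | {row['y']} | {row['n']} | {row['r']:.2f} "
            f"| {row['p_value']:.4g} | {row['method']} |"
        )
    return "\n".join(lines) + "\n"
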