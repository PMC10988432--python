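"""MRI morphometry: frustum muscle volumes, normalised indices, Dixon fat
fraction and physiological cross-sectional area.

Muscle volume is reconstructed from sparse serial cross-sections by
summing truncated-cone (frustum) segments between consecutive slices:

    MV = sum_n (t/3) * (A_n + sqrt(A_n * A_{n+1}) + A_{n+1})

with t the uniform inter-slice spacing.  The frustum form is exact for
any linearly tapering radius, reduces to the cylinder t*A for constant
area, and each segment is bracketed by t*min(A) and t*max(A).  A
trapezoidal alternative (t * (A_n + A_{n+1})/2) is available for
sensitivity analyses.

The two-point Dixon fat fraction is 100 * SI_fat / (SI_fat + SI_water),
a scale-free myosteatosis measure in [0, 100]%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cohort import DixonROI, SliceStack

__all__ = [
    "MorphometryResult",
    "restrict_roi",
    "frustum_volume",
    "volume_index",
    "l3_smi",
    "mid_acsa",
    "dixon_imat",
    "pcsa_eff",
]


@dataclass(frozen=True)
class MorphometryResult:
    """Per-subject MRI-derived morphometry."""

    quad_volume: float  # cm^3
    quad_volume_index: float  # cm^3/m^2
    mid_acsa: float  # cm^2
    l3_smi: float  # cm^2/m^2
    imat_pct: float  # %
    vl_volume: float  # cm^3
    pcsa: float  # cm^2
    pcsa_eff: float  # cm^2

    def __post_init__(self) -> None:
        if not 0.0 <= self.imat_pct <= 100.0:
            raise ValueError("imat_pct must lie in [0, 100]")
        if self.pcsa_eff > self.pcsa * (1 + 1e-12):
            raise ValueError("effective PCSA cannot exceed PCSA")
        for name in ("quad_volume", "quad_volume_index", "mid_acsa", "l3_smi", "vl_volume", "pcsa"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


def restrict_roi(stack: SliceStack, proximal_landmark: float, patella_proximal: float) -> SliceStack:
    """Restrict a quadriceps stack to the analysis region of interest.

    The restricted ROI runs from the proximal landmark (appearance of the
    lesser trochanter) to 20% above the proximal aspect of the patella,
    omitting the error-prone proximal and distal muscle extremes:
    distal limit = patella - 0.20 * (patella - proximal landmark).
    """
    if not proximal_landmark < patella_proximal:
        raise ValueError("proximal landmark must lie above the patella landmark")
    lo, hi = stack.positions[0], stack.positions[-1]
    distal_limit = patella_proximal - 0.20 * (patella_proximal - proximal_landmark)
    if distal_limit < lo or proximal_landmark > hi:
        raise ValueError(
            f"landmark window ({proximal_landmark:g}, {distal_limit:g}) cm falls outside "
            f"the imaged extent [{lo:g}, {hi:g}] cm"
        )
    keep = [
        i
        for i, p in enumerate(stack.positions)
        if proximal_landmark <= p <= distal_limit
    ]
    if len(keep) < 2:
        raise ValueError("fewer than 2 slices survive the restricted ROI")
    return SliceStack(
        muscle=stack.muscle,
        positions=tuple(stack.positions[i] for i in keep),
        thickness=stack.thickness,
        areas=tuple(stack.areas[i] for i in keep),
        roi_limits=(proximal_landmark, distal_limit),
    )


def frustum_volume(stack: SliceStack, method: str = "frustum") -> float:
    """Muscle volume (cm^3) from serial cross-sections.

    method="frustum" sums truncated-cone segments (default);
    method="trapezoid" uses the arithmetic-mean area per segment.
    The result is invariant under reversing slice order.
    """
    if stack.n_slices < 2:
        raise ValueError("volume estimation requires at least 2 slices")
    a = np.asarray(stack.areas, dtype=float)
    t = stack.spacing
    if method == "frustum":
        seg = (t / 3.0) * (a[:-1] + np.sqrt(a[:-1] * a[1:]) + a[1:])
    elif method == "trapezoid":
        seg = t * (a[:-1] + a[1:]) / 2.0
    else:
        raise ValueError(f"unknown volume method {method!r}")
    return float(seg.sum())


def volume_index(volume: float, height: float) -> float:
    """Muscle volume normalised to stature squared, cm^3/m^2."""
    if not volume > 0:
        raise ValueError("volume must be positive")
    if not height > 0:
        raise ValueError("height must be positive")
    return volume / height**2


def l3_smi(l3_csa: float, height: float) -> float:
    """L3 skeletal muscle index: summed L3-level muscle CSA / height^2 (cm^2/m^2)."""
    if not l3_csa > 0:
        raise ValueError("L3 muscle CSA must be positive")
    if not height > 0:
        raise ValueError("height must be positive")
    return l3_csa / height**2


def mid_acsa(stack: SliceStack, mid_position: float) -> float:
    """Quadriceps ACSA (cm^2) at the slice nearest 50% femur length.

    ``mid_position`` is the 50%-femur landmark in the stack's coordinate
    frame (cm distal to the greater trochanter).
    """
    pos = np.asarray(stack.positions, dtype=float)
    i = int(np.argmin(np.abs(pos - mid_position)))
    return float(stack.areas[i])


def dixon_imat(roi: DixonROI) -> float:
    """Intermuscular adipose tissue percentage from a two-point Dixon ROI.

    IMAT% = 100 * SI_fat / (SI_fat + SI_water); invariant to rescaling
    both channels by any positive constant, and 0/100 only at zero
    fat/water signal respectively.
    """
    total = roi.si_fat + roi.si_water
    if not total > 0:
        raise ValueError("zero total Dixon signal in ROI")
    return 100.0 * roi.si_fat / total


def pcsa_eff(vl_volume: float, fascicle_length: float, pennation: float) -> tuple[float, float]:
    """VL physiological cross-sectional area and its pennation-corrected form.

    PCSA = muscle volume / fascicle length indexes total in-parallel
    contractile material; PCSA_eff = PCSA * cos(pennation) accounts for
    the fraction of fascicle force transmitted along the tendon line.
    Returns (pcsa, pcsa_eff) in cm^2.
    """
    if not vl_volume > 0:
        raise ValueError("VL volume must be positive")
    if not fascicle_length > 0:
        raise ValueError("fascicle length must be positive")
    if not 0.0 <= pennation < 90.0:
        raise ValueError("pennation angle must lie in [0, 90) degrees")
    pcsa = vl_volume / fascicle_length
    return pcsa, pcsa * math.cos(math.radians(pennation))
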