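"""Anthropometric derived measures: MAMC, dry weight, BMI.

Mid-arm muscle circumference corrects the mid-arm circumference for the
triceps skinfold (MAMC = MAC - pi * TSF/10, TSF in mm); dry weight
subtracts graded fluid percentages for ascites and peripheral oedema
from the measured weight, the convention used to de-confound body mass
in decompensated liver disease.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .config import ASCITES_CORRECTION, OEDEMA_CORRECTION

__all__ = [
    "AnthropometryResult",
    "compute_mamc",
    "compute_dry_weight",
    "compute_bmi",
    "derive_anthropometry",
]


@dataclass(frozen=True)
class AnthropometryResult:
    mamc: float  # cm
    dry_weight: float  # kg
    bmi: float  # kg/m^2
    dry_bmi: float  # kg/m^2


def compute_mamc(mac: float, tsf: float) -> float:
    """Mid-arm muscle circumference (cm) from MAC (cm) and TSF (mm).

    MAMC = MAC - pi * TSF/10; the /10 converts the skinfold calliper
    reading from mm to cm.
    """
    if not mac > 0:
        raise ValueError("mid-arm circumference must be positive")
    if tsf < 0:
        raise ValueError("triceps skinfold must be non-negative")
    mamc = mac - math.pi * tsf / 10.0
    if not mamc > 0:
        raise ValueError(
            f"inconsistent anthropometry: MAC {mac} cm with TSF {tsf} mm "
            "implies a non-positive muscle circumference"
        )
    return mamc


def compute_dry_weight(weight: float, ascites_grade: str, oedema_grade: str) -> float:
    """Fluid-corrected (dry) body weight in kg.

    Subtracts the clinical-examination fluid percentages: ascites
    mild/moderate/severe 5/10/15% and oedema mild/moderate 5/10%,
    combined additively.
    """
    if not weight > 0:
        raise ValueError("weight must be positive")
    try:
        p_ascites = ASCITES_CORRECTION[ascites_grade]
    except KeyError:
        raise ValueError(f"unknown ascites grade {ascites_grade!r}") from None
    try:
        p_oedema = OEDEMA_CORRECTION[oedema_grade]
    except KeyError:
        raise ValueError(f"unknown oedema grade {oedema_grade!r}") from None
    return weight * (1.0 - p_ascites - p_oedema)


def compute_bmi(weight: float, height: float) -> float:
    """Body mass index, kg/m^2."""
    if not height > 0:
        raise ValueError("height must be positive")
    if not weight > 0:
        raise ValueError("weight must be positive")
    return weight / height**2


def derive_anthropometry(
    mac: float,
    tsf: float,
    weight: float,
    height: float,
    ascites_grade: str = "none",
    oedema_grade: str = "none",
) -> AnthropometryResult:
    """All anthropometric derived measures for one subject."""
    dry = compute_dry_weight(weight, ascites_grade, oedema_grade)
    return AnthropometryResult(
        mamc=compute_mamc(mac, tsf),
        dry_weight=dry,
        bmi=compute_bmi(weight, height),
        dry_bmi=compute_bmi(dry, height),
    )
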