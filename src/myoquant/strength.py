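"""Strength and physical-function reductions: peak-of-trials, chair-stand
timing, and IMAT-corrected specific force."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "StrengthResult",
    "ShortTrialWarning",
    "peak_of_trials",
    "specific_force",
    "chair_stand_time",
]


class ShortTrialWarning(UserWarning):
    """Fewer trials completed than the protocol prescribes."""


@dataclass(frozen=True)
class StrengthResult:
    peak_torque: float  # N*m
    peak_grip: float  # kg
    chair_time: float  # s
    specific_force: float  # N*m/cm^2

    def __post_init__(self) -> None:
        if not self.specific_force > 0:
            raise ValueError("specific_force must be strictly positive")


def peak_of_trials(trials: Sequence[float], expected_n: int) -> float:
    """Highest value across repeated maximal attempts.

    Emits :class:`ShortTrialWarning` when fewer than ``expected_n``
    trials were completed (e.g. fatigue-limited protocols); the peak of
    the completed trials is still returned.
    """
    if len(trials) == 0:
        raise ValueError("no trials recorded")
    if any(t < 0 for t in trials):
        raise ValueError("trial values must be non-negative")
    if len(trials) > expected_n:
        raise ValueError(f"{len(trials)} trials recorded but only {expected_n} expected")
    if len(trials) < expected_n:
        warnings.warn(
            f"only {len(trials)}/{expected_n} trials completed; peak taken over those",
            ShortTrialWarning,
            stacklevel=2,
        )
    return float(max(trials))


def specific_force(peak_torque: float, quad_acsa: float, imat_pct: float) -> float:
    """Torque per unit contractile area, N*m/cm^2.

    The denominator scales the quadriceps ACSA by its non-fat fraction
    (1 - IMAT%/100) so only contractile tissue is counted:

        specific force = torque / (ACSA * (1 - IMAT%/100))
    """
    if not peak_torque > 0:
        raise ValueError("peak torque must be positive")
    if not quad_acsa > 0:
        raise ValueError("quadriceps ACSA must be positive")
    if not 0.0 <= imat_pct < 100.0:
        raise ValueError(
            "IMAT% must lie in [0, 100); 100% leaves no contractile tissue"
        )
    return peak_torque / (quad_acsa * (1.0 - imat_pct / 100.0))


def chair_stand_time(stand_events: Sequence[float], start: float) -> float:
    """Time (s) to complete five full sit-to-stand repetitions.

    ``stand_events`` are the five stand-completion timestamps; the result
    is the last completion minus the start signal.
    """
    if len(stand_events) != 5:
        raise ValueError(f"expected exactly 5 stand completions, got {len(stand_events)}")
    times = list(stand_events)
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError("stand completion timestamps must be strictly increasing")
    if times[0] <= start:
        raise ValueError("first stand completion must follow the start signal")
    return float(times[-1] - start)
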