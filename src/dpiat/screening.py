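"""Scoring rules for the developmental-prosopagnosia screening battery.

Covers the self-report prosopagnosia index (PI20: 20 five-point Likert
items, five reverse-scored, with mild/moderate/severe bands), the face
perception sorting task scored as summed positional deviation (0 perfect,
18 per-trial maximum, 144 over the 8 upright trials), the famous-faces test
adjusted for celebrities unknown to the participant, the autism-quotient
exclusion cut-off, and the diagnostic rule itself: impairment beyond 2 SD
from the control mean on at least two of the three objective face tasks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .exceptions import ConfigurationError, ValidationError
from .iat_io import NormativeSample

__all__ = [
    "AQ_CUTOFF",
    "PI20_REVERSE_ITEMS",
    "PI20Response",
    "ScreeningProfile",
    "pi20_score",
    "pi20_band",
    "cfpt_trial_score",
    "fft_adjusted_percent",
    "aq_excluded",
    "apply_aq_exclusion",
    "dp_classify",
]

#: Autism-quotient exclusion threshold (inclusive: a score of 32 excludes).
AQ_CUTOFF = 32

#: Standard reverse-scored PI20 item positions (1-based).
PI20_REVERSE_ITEMS = frozenset({3, 8, 11, 15, 19})

CFMT_MAX = 72
CFPT_MAX = 144
FFT_ITEMS = 60

_BANDS = (("severe", 85), ("moderate", 75), ("mild", 65))


@dataclass(frozen=True)
class PI20Response:
    """Twenty Likert responses (1..5) plus the reverse-scored positions."""

    items: tuple[int, ...]
    reverse_indices: frozenset[int] = PI20_REVERSE_ITEMS

    def __post_init__(self) -> None:
        if len(self.items) != 20:
            raise ValidationError(f"PI20 needs exactly 20 items, got {len(self.items)}")
        if len(self.reverse_indices) != 5:
            raise ValidationError("PI20 has exactly 5 reverse-scored items")
        if not all(1 <= i <= 20 for i in self.reverse_indices):
            raise ValidationError("reverse item positions must lie in 1..20")
        for pos, v in enumerate(self.items, start=1):
            if not (isinstance(v, int) and 1 <= v <= 5):
                raise ValidationError(f"item {pos}: response {v!r} outside 1..5")


@dataclass(frozen=True)
class ScreeningProfile:
    """One participant's battery scores (FFT already adjusted, in percent)."""

    cfmt: int
    cfpt: float
    fft: float
    pi20_total: int
    aq: int

    def __post_init__(self) -> None:
        if not 0 <= self.cfmt <= CFMT_MAX:
            raise ValidationError(f"cfmt {self.cfmt} outside 0..{CFMT_MAX}")
        if not 0 <= self.cfpt <= CFPT_MAX:
            raise ValidationError(f"cfpt {self.cfpt} outside 0..{CFPT_MAX}")
        if not 0 <= self.fft <= 100:
            raise ValidationError(f"fft {self.fft} outside 0..100")
        if not 20 <= self.pi20_total <= 100:
            raise ValidationError(f"pi20_total {self.pi20_total} outside 20..100")
        if self.aq < 0:
            raise ValidationError(f"aq {self.aq} must be >= 0")


def pi20_band(total: int) -> str:
    for name, lo in _BANDS:
        if total >= lo:
            return name
    return "none"


def pi20_score(resp: PI20Response) -> tuple[int, str]:
    """Total (reverse items mapped v -> 6 - v) and its severity band.

    Bands: mild 65-74, moderate 75-84, severe 85-100, "none" below 65.
    """
    total = sum(
        (6 - v) if pos in resp.reverse_indices else v
        for pos, v in enumerate(resp.items, start=1)
    )
    return total, pi20_band(total)


def cfpt_trial_score(arrangement: Sequence, correct: Sequence) -> int:
    """Deviation score for one sorting trial: sum over faces of the absolute
    distance between produced and correct position. 0 = perfect; the maximum
    over arrangements of 6 items is 18 (full reversal)."""
    if len(arrangement) != len(correct) or set(arrangement) != set(correct) \
            or len(set(arrangement)) != len(arrangement):
        raise ValidationError("arrangement and correct must be permutations of the same items")
    pos = {item: i for i, item in enumerate(arrangement)}
    return sum(abs(pos[item] - i) for i, item in enumerate(correct))


def fft_adjusted_percent(correct: int, unknown: int, total_items: int = FFT_ITEMS) -> float:
    """Percent correct over the celebrities the participant actually knew."""
    if unknown < 0 or unknown >= total_items:
        raise ValidationError(
            f"unknown must be in 0..{total_items - 1} (all-unknown leaves no denominator)"
        )
    if not 0 <= correct <= total_items - unknown:
        raise ValidationError(
            f"correct {correct} outside 0..{total_items - unknown} after removing unknowns"
        )
    return 100.0 * correct / (total_items - unknown)


def aq_excluded(aq: int) -> bool:
    """True when the autism-quotient score meets the exclusion cut-off (>= 32)."""
    if aq < 0:
        raise ValidationError(f"aq {aq} must be >= 0")
    return aq >= AQ_CUTOFF


def apply_aq_exclusion(roster: pd.DataFrame) -> pd.DataFrame:
    """Drop roster rows at or above the AQ cut-off; index is reset."""
    if "aq" not in roster.columns:
        raise ConfigurationError("roster has no 'aq' column")
    return roster.loc[roster["aq"] < AQ_CUTOFF].reset_index(drop=True)


def dp_classify(
    profile: ScreeningProfile,
    task_norms: Mapping[str, NormativeSample],
) -> tuple[set[str], bool]:
    """Apply the 2-SD / two-task diagnostic rule.

    A task counts as impaired when the score lies beyond two control SDs in
    the deficit direction: below mean - 2*SD for cfmt and fft (higher =
    better), above mean + 2*SD for cfpt (0 is perfect, higher = worse).
    DP classification requires impairment on at least two of the three.
    """
    required = ("cfmt", "cfpt", "fft")
    missing = [k for k in required if k not in task_norms]
    if missing:
        raise ConfigurationError(f"missing norms for task(s): {missing}")
    impaired: set[str] = set()
    for task in required:
        norms = task_norms[task]
        score = getattr(profile, task)
        if task == "cfpt":
            if score > norms.mean + 2 * norms.sd:
                impaired.add(task)
        elif score < norms.mean - 2 * norms.sd:
            impaired.add(task)
    return impaired, len(impaired) >= 2
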