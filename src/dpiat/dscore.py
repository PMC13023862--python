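"""Improved IAT D-score algorithm, in two error-handling variants.

The D-score standardizes the latency cost of the incongruent face-trait
pairing: for each of the two test-block pairs (the 20-trial pair and the
40-trial pair) the incongruent-minus-congruent difference in block mean
latency is divided by one pooled SD over all trials of the pair, and the two
quotients are averaged. Positive D = faster responding under the congruent
pairing.

Two variants differ only in error-trial treatment:

``reference``
    Block means are first computed over correct trials only; each error
    trial's latency is then replaced by its block's correct-trial mean plus a
    fixed 600 ms penalty before block averaging.

``error_penalty``
    Every trial contributes its full latency from stimulus onset to the
    final (corrected) response — errors carry their own built-in time
    penalty, no replacement.

Trial-level exclusion removes latencies above 10,000 ms; participant-level
exclusion flags sessions in which more than 10% of (post-removal) analysis
trials are faster than 300 ms. The pooled SD is the n-1 sample SD of the
variant-adjusted latencies of all retained trials in the block pair, and a
zero pooled SD raises rather than returning an infinite quotient.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .exceptions import DegenerateDataError, StructureError, ValidationError
from .iat_io import ANALYSIS_BLOCKS, NormativeSample, SessionData, TrialRecord

__all__ = [
    "SLOW_CUTOFF_MS",
    "FAST_CUTOFF_MS",
    "FAST_FRACTION_LIMIT",
    "ERROR_PENALTY_MS",
    "DScoreResult",
    "filter_slow_trials",
    "check_fast_exclusion",
    "compute_d",
    "score_cohort",
]

SLOW_CUTOFF_MS = 10_000.0   # trials strictly above are discarded
FAST_CUTOFF_MS = 300.0      # trials strictly below count as anticipatory
FAST_FRACTION_LIMIT = 0.10  # participant excluded when fraction strictly above
ERROR_PENALTY_MS = 600.0    # fixed penalty of the reference variant

Variant = Literal["reference", "error_penalty"]
#: Test-block pairs entering the two quotients: the 20-trial pair and the
#: 40-trial pair. Block numbers are design labels; the quotient sign is
#: derived from the pairing labels on the trials, not from block order.
BLOCK_PAIRS: tuple[tuple[int, int], ...] = ((3, 6), (4, 7))


@dataclass(frozen=True)
class DScoreResult:
    """D with its two quotients, pooled SDs and exclusion diagnostics."""

    participant_id: str
    d: float
    quotient_36: float
    quotient_47: float
    pooled_sd_36: float
    pooled_sd_47: float
    block_means: dict[int, float]
    n_trials_removed_slow: int
    fast_trial_fraction: float
    excluded: bool
    variant: Variant


def filter_slow_trials(session: SessionData) -> tuple[SessionData, int]:
    """Drop trials with latency strictly above 10,000 ms."""
    kept = [t for t in session.trials if t.latency_ms <= SLOW_CUTOFF_MS]
    return session.with_trials(kept), len(session.trials) - len(kept)


def check_fast_exclusion(session: SessionData) -> tuple[float, bool]:
    """Fraction of trials faster than 300 ms, and whether it exceeds 10%.

    The comparison is strict on both sides: a 300 ms trial is not fast, and a
    fraction of exactly 0.10 does not exclude.
    """
    if not session.trials:
        raise ValidationError(
            f"participant {session.participant_id!r}: no trials to screen"
        )
    n_fast = sum(t.latency_ms < FAST_CUTOFF_MS for t in session.trials)
    fraction = n_fast / len(session.trials)
    return fraction, fraction > FAST_FRACTION_LIMIT


def _variant_latencies(trials: Sequence[TrialRecord], variant: Variant,
                       participant_id: str, block: int) -> np.ndarray:
    """Latency vector for one block after variant-specific error handling."""
    lat = np.array([t.latency_ms for t in trials], dtype=float)
    if variant == "error_penalty":
        return lat
    correct = np.array([t.first_response_correct for t in trials], dtype=bool)
    if not correct.any():
        raise DegenerateDataError(
            f"participant {participant_id!r}: block {block} has no correct "
            "trials; the reference variant needs a correct-latency mean"
        )
    first = np.array([t.first_latency_ms for t in trials], dtype=float)
    out = first.copy()
    out[~correct] = first[correct].mean() + ERROR_PENALTY_MS
    return out


def _pair_sign(trials_by_block: dict[int, list[TrialRecord]],
               lo: int, hi: int) -> float:
    """+1 when block ``hi`` carries the incongruent pairing (the standard
    labelling), -1 when the labels are swapped."""
    hi_pairings = {t.pairing for t in trials_by_block[hi]}
    lo_pairings = {t.pairing for t in trials_by_block[lo]}
    if hi_pairings == {"incongruent"} and lo_pairings == {"congruent"}:
        return 1.0
    if hi_pairings == {"congruent"} and lo_pairings == {"incongruent"}:
        return -1.0
    raise ValidationError(
        f"blocks {lo}/{hi} do not carry one congruent and one incongruent "
        f"pairing (got {sorted(lo_pairings)} / {sorted(hi_pairings)})"
    )


def compute_d(session: SessionData, variant: Variant = "error_penalty") -> DScoreResult:
    """Score one session.

    Applies the trial-level slow filter, computes the fast-trial exclusion
    flag over the four analysis blocks, then forms the two standardized
    quotients and their average. The result is returned even for excluded
    sessions (with ``excluded=True``) so cohorts can report rather than drop.
    """
    if variant not in ("reference", "error_penalty"):
        raise ValidationError(f"unknown variant {variant!r}")

    analysis = session.with_trials(session.trials_in_blocks(ANALYSIS_BLOCKS))
    if not analysis.trials:
        raise StructureError(
            f"participant {session.participant_id!r}: no analysis-block trials"
        )
    analysis, n_removed = filter_slow_trials(analysis)
    fast_fraction, excluded = check_fast_exclusion(analysis)

    by_block: dict[int, list[TrialRecord]] = {}
    for t in analysis.trials:
        by_block.setdefault(t.block, []).append(t)
    for b in ANALYSIS_BLOCKS:
        if len(by_block.get(b, [])) < 2:
            raise StructureError(
                f"participant {session.participant_id!r}: block {b} has fewer "
                "than 2 usable trials"
            )

    adjusted = {
        b: _variant_latencies(by_block[b], variant, session.participant_id, b)
        for b in ANALYSIS_BLOCKS
    }
    block_means = {b: float(adjusted[b].mean()) for b in ANALYSIS_BLOCKS}

    quotients, pooled_sds = [], []
    for lo, hi in BLOCK_PAIRS:
        pooled = np.concatenate([adjusted[lo], adjusted[hi]])
        sd = float(pooled.std(ddof=1))
        if sd == 0.0:
            raise DegenerateDataError(
                f"participant {session.participant_id!r}: zero pooled SD for "
                f"blocks {lo}/{hi}"
            )
        sign = _pair_sign(by_block, lo, hi)
        quotients.append(sign * (block_means[hi] - block_means[lo]) / sd)
        pooled_sds.append(sd)

    return DScoreResult(
        participant_id=session.participant_id,
        d=float(np.mean(quotients)),
        quotient_36=quotients[0],
        quotient_47=quotients[1],
        pooled_sd_36=pooled_sds[0],
        pooled_sd_47=pooled_sds[1],
        block_means=block_means,
        n_trials_removed_slow=n_removed,
        fast_trial_fraction=fast_fraction,
        excluded=excluded,
        variant=variant,
    )


def score_cohort(
    sessions: Sequence[SessionData],
    variant: Variant = "error_penalty",
    norms_label: str = "simulated controls",
) -> tuple[list[DScoreResult], NormativeSample]:
    """Score every session and summarize the retained D-scores.

    Excluded sessions stay in the result list (flagged) but do not enter the
    normative summary, whose SD is the n-1 sample SD.
    """
    results = [compute_d(s, variant) for s in sessions]
    retained = [r.d for r in results if not r.excluded]
    if len(retained) < 2:
        raise ValidationError(
            f"cohort has {len(retained)} non-excluded session(s); need >= 2"
        )
    arr = np.asarray(retained)
    norms = NormativeSample(
        mean=float(arr.mean()), sd=float(arr.std(ddof=1)),
        n=len(retained), label=norms_label,
    )
    return results, norms
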