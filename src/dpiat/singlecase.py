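"""Crawford-Garthwaite single-case inference.

The modified t-test compares one case's score against a normative sample of
modest size, treating the controls as a sample rather than a population:

    t = (x - M) / (S * sqrt((N + 1) / N)),  df = N - 1

where (M, S, N) summarize the control distribution. This keeps Type I error
controlled where the naive z-score is anticonservative for small N. The
percentile rank — the estimated proportion of the control population scoring
below the case — is the Student-t CDF of t at N - 1 df (the point estimate
of abnormality; no interval on the percentile is computed here).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from scipy import stats

from .exceptions import ValidationError
from .iat_io import NormativeSample

__all__ = ["SingleCaseResult", "crawford_t", "batch_case_table", "count_below_norm"]


@dataclass(frozen=True)
class SingleCaseResult:
    case_id: str
    case_score: float
    t: float
    df: int
    p_one_tailed: float
    p_two_tailed: float
    percentile: float
    norms_label: str = ""


def crawford_t(case_score: float, norms: NormativeSample,
               case_id: str = "") -> SingleCaseResult:
    """Modified t-test of one case against a (mean, SD, N) control summary.

    ``p_one_tailed`` is the tail probability in the direction of the observed
    deviation (deficit direction when t < 0); ``p_two_tailed`` doubles it.
    """
    if not math.isfinite(case_score):
        raise ValidationError("case_score must be finite")
    t = (case_score - norms.mean) / (norms.sd * math.sqrt((norms.n + 1) / norms.n))
    df = norms.n - 1
    p_one = float(stats.t.sf(abs(t), df))
    return SingleCaseResult(
        case_id=case_id,
        case_score=case_score,
        t=t,
        df=df,
        p_one_tailed=p_one,
        p_two_tailed=2.0 * p_one,
        percentile=float(100.0 * stats.t.cdf(t, df)),
        norms_label=norms.label,
    )


def batch_case_table(cases: Sequence[tuple[str, float]],
                     norms: NormativeSample) -> list[SingleCaseResult]:
    """One modified-t result per (id, score) case, order preserved."""
    if not cases:
        raise ValidationError("batch_case_table: empty case list")
    return [crawford_t(score, norms, case_id=str(cid)) for cid, score in cases]


def count_below_norm(results: Sequence[SingleCaseResult], alpha: float = 0.05) -> int:
    """Number of cases significantly *below* the norm (one-tailed, deficit
    direction) at the given alpha."""
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    return sum(1 for r in results if r.t < 0 and r.p_one_tailed < alpha)
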