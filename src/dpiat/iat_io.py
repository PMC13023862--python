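"""Domain types and plain-text I/O for trial-level IAT data.

The trial schema is a strict, self-defined CSV dialect (online experiment
platforms export wildly different layouts, so one canonical schema is fixed
here): one row per trial, header required, booleans serialized as
``true``/``false``, latencies in milliseconds. Case tables are tab-separated
with the column layout conventional for single-case reports (participant,
D-score, modified t, p, percentile). Normative-sample summaries are small
YAML key-value files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .exceptions import SchemaError, ValidationError

__all__ = [
    "TrialRecord",
    "SessionData",
    "NormativeSample",
    "BLOCK_TRIAL_COUNTS",
    "BLOCK_FUNCTION",
    "BLOCK_PAIRING",
    "ANALYSIS_BLOCKS",
    "TRIAL_COLUMNS",
    "validate_session",
    "read_sessions",
    "write_sessions",
    "read_norms",
    "write_norms",
    "write_case_table",
    "read_roster",
    "write_roster",
]

# Seven-block design: five 20-trial blocks and two 40-trial combined test
# blocks.  Blocks 3/4 carry the congruent pairing, 6/7 the incongruent one;
# counterbalancing changes presentation order only, never these labels.
BLOCK_TRIAL_COUNTS: dict[int, int] = {1: 20, 2: 20, 3: 20, 4: 40, 5: 20, 6: 20, 7: 40}
BLOCK_FUNCTION: dict[int, str] = {
    1: "practice", 2: "practice", 3: "test", 4: "test",
    5: "practice", 6: "test", 7: "test",
}
BLOCK_PAIRING: dict[int, str] = {
    1: "single_category", 2: "single_category", 5: "single_category",
    3: "congruent", 4: "congruent", 6: "incongruent", 7: "incongruent",
}
#: Blocks entering the D-score (the four combined test blocks).
ANALYSIS_BLOCKS: tuple[int, ...] = (3, 4, 6, 7)

ORDERS = ("congruent_first", "incongruent_first")
PAIRINGS = ("congruent", "incongruent", "single_category")
STIMULUS_KINDS = ("face", "word")

TRIAL_COLUMNS = [
    "participant_id", "age", "order", "block", "trial_index",
    "block_function", "pairing", "stimulus_kind", "first_response_correct",
    "first_latency_ms", "latency_ms",
]


@dataclass(frozen=True)
class TrialRecord:
    """One stimulus-response event.

    ``latency_ms`` runs from stimulus onset to the *final correct* response;
    ``first_latency_ms`` to the first keypress. The two coincide on correct
    trials and ``latency_ms >= first_latency_ms`` on error trials (the
    participant had to correct before proceeding).
    """

    participant_id: str
    block: int
    trial_index: int
    block_function: str
    pairing: str
    stimulus_kind: str
    first_response_correct: bool
    first_latency_ms: float
    latency_ms: float

    def __post_init__(self) -> None:
        if not 1 <= self.block <= 7:
            raise ValidationError(
                f"participant {self.participant_id!r}: block {self.block} outside 1..7"
            )
        if self.trial_index < 1:
            raise ValidationError(
                f"participant {self.participant_id!r}: trial_index {self.trial_index} < 1"
            )
        if self.block_function not in ("practice", "test"):
            raise ValidationError(f"unknown block_function {self.block_function!r}")
        if self.pairing not in PAIRINGS:
            raise ValidationError(f"unknown pairing {self.pairing!r}")
        if self.stimulus_kind not in STIMULUS_KINDS:
            raise ValidationError(f"unknown stimulus_kind {self.stimulus_kind!r}")
        if self.first_latency_ms <= 0 or self.latency_ms <= 0:
            raise ValidationError(
                f"participant {self.participant_id!r}: non-positive latency"
            )
        if self.first_response_correct:
            if self.latency_ms != self.first_latency_ms:
                raise ValidationError(
                    f"participant {self.participant_id!r} block {self.block} trial "
                    f"{self.trial_index}: correct trial with latency_ms != first_latency_ms"
                )
        elif self.latency_ms < self.first_latency_ms:
            raise ValidationError(
                f"participant {self.participant_id!r} block {self.block} trial "
                f"{self.trial_index}: corrected latency below first-keypress latency"
            )


@dataclass
class SessionData:
    """Ordered trials for one participant plus counterbalance order."""

    participant_id: str
    order: str
    trials: list[TrialRecord] = field(default_factory=list)
    age: int | None = None

    def __post_init__(self) -> None:
        if self.order not in ORDERS:
            raise ValidationError(
                f"participant {self.participant_id!r}: order must be one of {ORDERS}"
            )
        if self.age is not None and self.age <= 0:
            raise ValidationError(f"participant {self.participant_id!r}: age must be positive")

    def trials_in_blocks(self, blocks: Iterable[int]) -> list[TrialRecord]:
        wanted = set(blocks)
        return [t for t in self.trials if t.block in wanted]

    def with_trials(self, trials: Sequence[TrialRecord]) -> "SessionData":
        return replace(self, trials=list(trials))

    def canonical(self) -> "SessionData":
        """Copy with trials in canonical (block, trial_index) order — the
        order :func:`read_sessions` returns; presentation order is implied
        by ``order``."""
        return self.with_trials(
            sorted(self.trials, key=lambda t: (t.block, t.trial_index))
        )


@dataclass(frozen=True)
class NormativeSample:
    """Summary (mean, SD, N) of a control D-score distribution."""

    mean: float
    sd: float
    n: int
    label: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.mean):
            raise ValidationError("normative mean must be finite")
        if not (self.sd > 0):
            raise ValidationError(f"normative sd must be > 0, got {self.sd}")
        if self.n < 2:
            raise ValidationError(f"normative n must be >= 2, got {self.n}")


def validate_session(session: SessionData) -> None:
    """Check a full session against the seven-block design.

    Raises :class:`ValidationError` naming the participant when block trial
    counts deviate from the canonical design (20 trials in blocks 1,2,3,5,6;
    40 in blocks 4 and 7) or a block label/function is inconsistent.
    """
    counts: dict[int, int] = {b: 0 for b in BLOCK_TRIAL_COUNTS}
    for t in session.trials:
        counts[t.block] += 1
        if t.block_function != BLOCK_FUNCTION[t.block]:
            raise ValidationError(
                f"participant {session.participant_id!r}: block {t.block} labelled "
                f"{t.block_function!r}, expected {BLOCK_FUNCTION[t.block]!r}"
            )
    if counts != BLOCK_TRIAL_COUNTS:
        raise ValidationError(
            f"participant {session.participant_id!r}: block trial counts {counts} "
            f"do not match the design {BLOCK_TRIAL_COUNTS}"
        )


# ---------------------------------------------------------------------------
# trial CSV

def _sessions_to_frame(sessions: Sequence[SessionData]) -> pd.DataFrame:
    rows = []
    for s in sessions:
        for t in s.trials:
            rows.append(
                {
                    "participant_id": s.participant_id,
                    "age": "" if s.age is None else s.age,
                    "order": s.order,
                    "block": t.block,
                    "trial_index": t.trial_index,
                    "block_function": t.block_function,
                    "pairing": t.pairing,
                    "stimulus_kind": t.stimulus_kind,
                    "first_response_correct": "true" if t.first_response_correct else "false",
                    "first_latency_ms": repr(t.first_latency_ms),
                    "latency_ms": repr(t.latency_ms),
                }
            )
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def write_sessions(sessions: Sequence[SessionData], path: str | Path) -> None:
    """Write sessions as the canonical trial CSV (full float precision)."""
    _sessions_to_frame(sessions).to_csv(path, index=False)


def read_sessions(path: str | Path) -> list[SessionData]:
    """Read a trial CSV back into validated sessions.

    Sessions are grouped by ``participant_id`` in file order; trials within a
    session are ordered by ``(block, trial_index)``. Every record invariant is
    re-validated; violations raise with the participant and row named.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")

    sessions: dict[str, SessionData] = {}
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        pid = row.participant_id
        flag = row.first_response_correct.strip().lower()
        if flag not in ("true", "false"):
            raise ValidationError(
                f"{path} row {row_no}: first_response_correct must be true/false, got {flag!r}"
            )
        try:
            trial = TrialRecord(
                participant_id=pid,
                block=int(row.block),
                trial_index=int(row.trial_index),
                block_function=row.block_function,
                pairing=row.pairing,
                stimulus_kind=row.stimulus_kind,
                first_response_correct=flag == "true",
                first_latency_ms=float(row.first_latency_ms),
                latency_ms=float(row.latency_ms),
            )
        except ValidationError as exc:
            raise ValidationError(f"{path} row {row_no}: {exc}") from None
        if pid not in sessions:
            sessions[pid] = SessionData(
                participant_id=pid,
                order=row.order,
                age=int(row.age) if row.age != "" else None,
            )
        sessions[pid].trials.append(trial)

    out = list(sessions.values())
    for s in out:
        s.trials.sort(key=lambda t: (t.block, t.trial_index))
    return out


# ---------------------------------------------------------------------------
# normative-sample YAML

def write_norms(norms: NormativeSample, path: str | Path) -> None:
    payload = {"mean": float(norms.mean), "sd": float(norms.sd),
               "n": int(norms.n), "label": norms.label}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_norms(path: str | Path) -> NormativeSample:
    """Read a ``mean/sd/n[/label]`` YAML summary; invariants enforced."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: expected a key-value mapping")
    missing = [k for k in ("mean", "sd", "n") if k not in raw]
    if missing:
        raise SchemaError(f"{path}: missing key(s) {missing}")
    return NormativeSample(
        mean=float(raw["mean"]), sd=float(raw["sd"]), n=int(raw["n"]),
        label=str(raw.get("label", "")),
    )


# ---------------------------------------------------------------------------
# case table (single-case report, tab-separated)

def write_case_table(results: Sequence, path: str | Path) -> None:
    """Write single-case results as a five-column TSV.

    Columns: participant, d, t, p, percentile — D, t and (two-tailed) p at 3
    decimals, percentile at 1, matching the precision conventional for
    published single-case tables.
    """
    if not results:
        raise ValidationError("write_case_table: empty result list")
    lines = ["participant\td\tt\tp\tpercentile"]
    for r in results:
        lines.append(
            f"{r.case_id}\t{r.case_score:.3f}\t{r.t:.3f}"
            f"\t{r.p_two_tailed:.3f}\t{r.percentile:.1f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# screening roster CSV

ROSTER_COLUMNS = ["participant_id", "age", "cfmt", "cfpt", "fft", "pi20", "aq"]


def write_roster(roster: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in ROSTER_COLUMNS if c not in roster.columns]
    if missing:
        raise SchemaError(f"roster is missing column(s) {missing}")
    roster.loc[:, ROSTER_COLUMNS].to_csv(path, index=False)


def read_roster(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ROSTER_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df
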