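"""Shared fixtures: constructed sessions with known latencies, packaged
reference data, and a derandomized hypothesis profile."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from dpiat.datasets import load_combined_control_norms, load_dp_case_dscores
from dpiat.iat_io import BLOCK_FUNCTION, BLOCK_PAIRING, SessionData, TrialRecord

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_session(blocks, participant_id="p1", order="congruent_first"):
    """Build a session from ``{block: [entry, ...]}``.

    An entry is a latency (correct trial) or a ``(first, final)`` tuple
    (error trial: first keypress wrong, final latency is the corrected one).
    """
    trials = []
    for b in sorted(blocks):
        for i, e in enumerate(blocks[b], start=1):
            if isinstance(e, tuple):
                first, final = float(e[0]), float(e[1])
                correct = False
            else:
                first = final = float(e)
                correct = True
            trials.append(
                TrialRecord(
                    participant_id=participant_id,
                    block=b,
                    trial_index=i,
                    block_function=BLOCK_FUNCTION[b],
                    pairing=BLOCK_PAIRING[b],
                    stimulus_kind="face" if i % 2 else "word",
                    first_response_correct=correct,
                    first_latency_ms=first,
                    latency_ms=final,
                )
            )
    return SessionData(participant_id=participant_id, order=order, trials=trials)


@pytest.fixture(scope="session")
def combined_norms():
    return load_combined_control_norms()


@pytest.fixture(scope="session")
def dp_cases():
    return load_dp_case_dscores()
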