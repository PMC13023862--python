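#!/usr/bin/env python
"""Simulate the normative IAT cohort.

Generates 180 seven-block sessions under the default (calibrated) study
conditions, checks the design structure and counterbalancing, and writes the
trial-level CSV to scratch/ (it is a few MB; downstream steps re-read it).
"""

from pathlib import Path

from dpiat.iat_io import validate_session, write_sessions
from dpiat.simulate import SimulationParams, generate_cohort

SCRATCH = Path(__file__).resolve().parents[1] / "scratch"


def main() -> None:
    params = SimulationParams(seed=0)
    cohort = generate_cohort(params)
    for s in cohort:
        validate_session(s)
    n_cong = sum(s.order == "congruent_first" for s in cohort)
    SCRATCH.mkdir(exist_ok=True)
    out = SCRATCH / "trials.csv"
    write_sessions(cohort, out)
    print(f"simulated {len(cohort)} structurally valid sessions "
          f"({n_cong} congruent-first, {len(cohort) - n_cong} incongruent-first)")
    print(f"congruency effect: {params.congruency_effect_ms} ms at the median; "
          f"error rate {params.error_rate:.0%}")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
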