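#!/usr/bin/env python
"""Single-case analysis of the 36 DP case D-scores.

Compares each packaged case D-score against the combined control norms with
the Crawford-Garthwaite modified t-test, writes the case table to results/,
and reports the deficit count and the descriptively elevated case."""

from pathlib import Path

from dpiat.datasets import load_combined_control_norms, load_dp_case_dscores
from dpiat.pipeline import PipelineConfig, run_singlecase
from dpiat.singlecase import batch_case_table, count_below_norm

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    df = run_singlecase(PipelineConfig(output_dir=ROOT / "results"))
    norms = load_combined_control_norms()
    results = batch_case_table(load_dp_case_dscores(), norms)
    n_below = count_below_norm(results, alpha=0.05)
    top = max(results, key=lambda r: r.case_score)
    print(f"{len(df)} cases compared against norms "
          f"(M = {norms.mean}, SD = {norms.sd}, N = {norms.n})")
    print(f"cases significantly below the norm (one-tailed p < .05): {n_below}")
    print(f"highest case: participant {top.case_id}, D = {top.case_score:.3f}, "
          f"t({top.df}) = {top.t:.3f}, percentile {top.percentile:.1f}")


if __name__ == "__main__":
    main()
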