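#!/usr/bin/env python
"""Score the simulated cohort into D-scores.

Reads the trial CSV from scratch/, scores it under both error-handling
variants, writes the per-participant table and the cohort normative summary
to results/, and reports how the simulated norms compare with the published
control summary (M = 0.082, SD = 0.405, N = 180)."""

from pathlib import Path

from dpiat.iat_io import read_sessions, write_norms
from dpiat.pipeline import PipelineConfig, run_score

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    trials = ROOT / "scratch" / "trials.csv"
    if not trials.exists():
        raise SystemExit("run analysis/01_simulate_cohort.py first")
    results_dir = ROOT / "results"

    df = run_score(PipelineConfig(trials_path=trials, d_variant="error_penalty",
                                  output_dir=results_dir))
    retained = df.loc[~df["excluded"], "d"]
    print(f"error-penalty variant: {len(df)} scored, {len(retained)} retained; "
          f"mean D = {retained.mean():.4f}, SD = {retained.std(ddof=1):.4f}")
    print("published control summary for comparison: M = 0.082, SD = 0.405, N = 180")

    # reference variant on the same sessions, for the variant contrast
    sessions = read_sessions(trials)
    from dpiat.dscore import score_cohort
    _, ref_norms = score_cohort(sessions, "reference")
    write_norms(ref_norms, results_dir / "cohort_norms_reference.yaml")
    print(f"reference variant: mean D = {ref_norms.mean:.4f}, SD = {ref_norms.sd:.4f}")


if __name__ == "__main__":
    main()
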