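"""End-to-end orchestration: simulate or load trials, score, run group and
single-case inference, apply screening exclusions.

Each ``run_*`` function is a thin, deterministic driver over the library:
it resolves inputs from a :class:`PipelineConfig`, executes one stage, logs
every exclusion decision (participant id + rule) to the ``dpiat`` logger,
and writes plain-text outputs. Human-facing tables are rendered at fixed
decimals (3/3/3/1 for the case table); a full-precision machine-readable
sidecar accompanies each.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import datasets, iat_io
from .dscore import Variant, score_cohort
from .exceptions import ConfigurationError, ValidationError
from .groupstats import (
    DEFAULT_PRIOR_SCALE,
    jzs_bf10,
    one_sample_test,
    sequential_bf,
)
from .iat_io import NormativeSample
from .simulate import SimulationParams, generate_cohort, generate_screening_roster
from .singlecase import batch_case_table, count_below_norm

log = logging.getLogger("dpiat")

__all__ = [
    "PipelineConfig",
    "run_simulate",
    "run_score",
    "run_singlecase",
    "run_group",
    "run_screen",
]


@dataclass
class PipelineConfig:
    """Inputs and knobs for one pipeline run.

    Exactly one of ``trials_path`` / ``sim_params`` feeds the scoring stage;
    case-level stages read ``cases_path``/``norms_path`` or fall back to the
    packaged fixtures.
    """

    trials_path: Path | None = None
    cases_path: Path | None = None
    norms_path: Path | None = None
    roster_path: Path | None = None
    sim_params: SimulationParams | None = None
    d_variant: Variant = "error_penalty"
    alpha: float = 0.05
    ci_level: float = 0.95
    bayes_prior_scale: float = DEFAULT_PRIOR_SCALE
    output_dir: Path = field(default_factory=lambda: Path("results"))
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigurationError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0 < self.ci_level < 1:
            raise ConfigurationError(f"ci_level must be in (0, 1), got {self.ci_level}")
        self.output_dir = Path(self.output_dir)

    def _outdir(self) -> Path:
        self.output_dir.mkdir(parents=True, exist_ok=True)
        return self.output_dir


def _load_sessions(config: PipelineConfig) -> list[iat_io.SessionData]:
    if (config.trials_path is None) == (config.sim_params is None):
        raise ConfigurationError(
            "exactly one of trials_path / sim_params must be set"
        )
    if config.trials_path is not None:
        return iat_io.read_sessions(config.trials_path)
    params = dataclasses.replace(config.sim_params, seed=config.seed)
    return generate_cohort(params)


def _load_norms(config: PipelineConfig) -> NormativeSample:
    if config.norms_path is not None:
        return iat_io.read_norms(config.norms_path)
    return datasets.load_combined_control_norms()


def _load_cases(config: PipelineConfig) -> list[tuple[str, float]]:
    if config.cases_path is None:
        return datasets.load_dp_case_dscores()
    df = pd.read_csv(config.cases_path, sep=None, engine="python",
                     dtype={"participant": str})
    for col in ("participant", "d"):
        if col not in df.columns:
            raise ConfigurationError(f"{config.cases_path}: missing column {col!r}")
    return list(zip(df["participant"], df["d"].astype(float)))


def run_simulate(config: PipelineConfig) -> Path:
    """Generate a cohort and write the trial CSV; returns its path."""
    if config.sim_params is None:
        raise ConfigurationError("run_simulate needs sim_params")
    params = dataclasses.replace(config.sim_params, seed=config.seed)
    sessions = generate_cohort(params)
    out = config._outdir() / "trials.csv"
    iat_io.write_sessions(sessions, out)
    log.info("simulated %d sessions -> %s", len(sessions), out)
    return out


def run_score(config: PipelineConfig) -> pd.DataFrame:
    """Score a cohort; writes per-participant rows and a norms summary."""
    sessions = _load_sessions(config)
    results, norms = score_cohort(sessions, config.d_variant)
    for r in results:
        if r.excluded:
            log.info(
                "participant %s excluded: fast-trial fraction %.3f > 0.10",
                r.participant_id, r.fast_trial_fraction,
            )
        if r.n_trials_removed_slow:
            log.info(
                "participant %s: removed %d trial(s) above 10,000 ms",
                r.participant_id, r.n_trials_removed_slow,
            )
    df = pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in results],
            "d": [r.d for r in results],
            "quotient_36": [r.quotient_36 for r in results],
            "quotient_47": [r.quotient_47 for r in results],
            "pooled_sd_36": [r.pooled_sd_36 for r in results],
            "pooled_sd_47": [r.pooled_sd_47 for r in results],
            "n_trials_removed_slow": [r.n_trials_removed_slow for r in results],
            "fast_trial_fraction": [r.fast_trial_fraction for r in results],
            "excluded": [r.excluded for r in results],
            "variant": [r.variant for r in results],
        }
    )
    outdir = config._outdir()
    df.to_csv(outdir / "scored_cohort.csv", index=False)
    iat_io.write_norms(norms, outdir / "cohort_norms.yaml")
    log.info(
        "scored %d sessions (%d retained): mean D = %.4f, SD = %.4f",
        len(results), norms.n, norms.mean, norms.sd,
    )
    return df


def run_singlecase(config: PipelineConfig) -> pd.DataFrame:
    """Single-case table for every case against the norms.

    Writes the fixed-decimals TSV plus a full-precision CSV sidecar and logs
    the count of cases significantly below the norm at ``config.alpha``.
    """
    norms = _load_norms(config)
    cases = _load_cases(config)
    results = batch_case_table(cases, norms)
    outdir = config._outdir()
    iat_io.write_case_table(results, outdir / "case_table.tsv")
    full = pd.DataFrame([dataclasses.asdict(r) for r in results])
    full.to_csv(outdir / "case_table_full.csv", index=False)
    n_below = count_below_norm(results, config.alpha)
    log.info(
        "%d of %d cases significantly below the norm (one-tailed alpha=%g)",
        n_below, len(results), config.alpha,
    )
    return full


def run_group(config: PipelineConfig) -> dict:
    """Group-level report: one-sample t vs 0, Cohen's d, CI, BF10 and the
    sequential Bayes-factor trajectory (written as CSV)."""
    cases = _load_cases(config)
    values = [d for _, d in cases]
    if len(values) < 2:
        raise ValidationError(f"need >= 2 case scores, got {len(values)}")
    test = one_sample_test(values, mu0=0.0, ci_level=config.ci_level)
    bayes = jzs_bf10(test.t, test.n, config.bayes_prior_scale)
    seq = sequential_bf(values, config.bayes_prior_scale)
    outdir = config._outdir()
    pd.DataFrame(seq, columns=["k", "bf10"]).to_csv(
        outdir / "sequential_bf.csv", index=False
    )
    report = {
        "n": test.n,
        "mean_d": test.mean,
        "sd": test.sd,
        "t": test.t,
        "df": test.df,
        "p_two_tailed": test.p_two_tailed,
        "cohens_d": test.cohens_d,
        "ci_level": test.ci_level,
        "ci_low": test.ci_low,
        "ci_high": test.ci_high,
        "bf10": bayes.bf10,
        "prior_scale": bayes.prior_scale,
    }
    lines = [f"{k}: {v:.6g}" if isinstance(v, float) else f"{k}: {v}"
             for k, v in report.items()]
    (outdir / "group_report.txt").write_text("\n".join(lines) + "\n")
    log.info("group: t(%d) = %.3f, d = %.3f, BF10 = %.3f",
             test.df, test.t, test.cohens_d, bayes.bf10)
    return report


def run_screen(config: PipelineConfig) -> pd.DataFrame:
    """Apply the AQ exclusion to a roster (given path or a simulated one)."""
    from .screening import AQ_CUTOFF, apply_aq_exclusion

    if config.roster_path is not None:
        roster = iat_io.read_roster(config.roster_path)
    else:
        roster = generate_screening_roster(n=51, n_high_aq=15, seed=config.seed)
    retained = apply_aq_exclusion(roster)
    for pid in roster.loc[roster["aq"] >= AQ_CUTOFF, "participant_id"]:
        log.info("participant %s excluded: AQ >= %d", pid, AQ_CUTOFF)
    outdir = config._outdir()
    iat_io.write_roster(retained, outdir / "roster_retained.csv")
    log.info("screening: %d of %d rows retained", len(retained), len(roster))
    return retained
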