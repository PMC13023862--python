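"""D-score algorithm: hand-computed oracles, exclusion rules, invariances,
and equivalence with an independent straight-line transcription of the
twelve scoring steps."""

import statistics

import numpy as np
import pytest

from conftest import make_session
from dpiat.dscore import (
    check_fast_exclusion,
    compute_d,
    filter_slow_trials,
    score_cohort,
)
from dpiat.exceptions import DegenerateDataError, StructureError, ValidationError
from dpiat.iat_io import SessionData, TrialRecord
from dpiat.simulate import SimulationParams, generate_cohort, generate_session


def twelve_step_d(session, variant):
    """Independent transcription of the scoring algorithm, one step per
    statement, using the stdlib only (no shared code with compute_d)."""
    trials = [t for t in session.trials if t.block in (3, 4, 6, 7)]      # step 1
    trials = [t for t in trials if t.latency_ms <= 10_000]               # step 2a
    n_fast = sum(1 for t in trials if t.latency_ms < 300)                # step 2b
    excluded = n_fast / len(trials) > 0.10
    blocks = {b: [t for t in trials if t.block == b] for b in (3, 4, 6, 7)}
    correct_mean = {                                                     # step 5
        b: statistics.mean(
            t.first_latency_ms for t in ts if t.first_response_correct
        )
        for b, ts in blocks.items()
    }
    vals = {}
    for b, ts in blocks.items():                                         # step 7
        out = []
        for t in ts:
            if variant == "reference":
                out.append(
                    t.first_latency_ms if t.first_response_correct
                    else correct_mean[b] + 600.0
                )
            else:
                out.append(t.latency_ms)
        vals[b] = out
    sd1 = statistics.stdev(vals[3] + vals[6])                            # step 6
    sd2 = statistics.stdev(vals[4] + vals[7])
    m = {b: statistics.mean(v) for b, v in vals.items()}                 # step 9
    q1 = (m[6] - m[3]) / sd1                                             # steps 10-11
    q2 = (m[7] - m[4]) / sd2
    return (q1 + q2) / 2.0, excluded                                     # step 12


def two_level_session(lo=700.0, hi=900.0):
    return make_session({3: [lo] * 20, 4: [lo] * 40, 6: [hi] * 20, 7: [hi] * 40})


class TestSlowAndFastFilters:
    def test_slow_trial_removed_strictly_above_cutoff(self):
        s = make_session({3: [500.0, 12_000.0, 600.0]})
        filtered, removed = filter_slow_trials(s)
        assert removed == 1
        assert all(t.latency_ms <= 10_000 for t in filtered.trials)

    def test_boundary_latency_retained(self):
        s = make_session({3: [9_999.0] * 5 + [10_000.0]})
        filtered, removed = filter_slow_trials(s)
        assert removed == 0
        assert len(filtered.trials) == 6

    @pytest.mark.parametrize("k", [0, 3, 7])
    def test_injected_slow_trials_are_counted(self, k):
        lats = [800.0] * 30 + [10_001.0] * k
        _, removed = filter_slow_trials(make_session({4: lats}))
        assert removed == k

    def test_fast_fraction_at_exactly_ten_percent_is_retained(self):
        s = make_session({3: [250.0] * 8 + [800.0] * 72})
        fraction, excluded = check_fast_exclusion(s)
        assert fraction == pytest.approx(0.10)
        assert not excluded

    def test_fast_fraction_above_ten_percent_excludes(self):
        s = make_session({3: [250.0] * 10 + [800.0] * 70})
        fraction, excluded = check_fast_exclusion(s)
        assert fraction == pytest.approx(0.125)
        assert excluded

    def test_no_fast_trials(self):
        fraction, excluded = check_fast_exclusion(make_session({3: [800.0] * 20}))
        assert fraction == 0.0 and not excluded

    def test_empty_session_rejected(self):
        with pytest.raises(ValidationError):
            check_fast_exclusion(SessionData("p", "congruent_first", []))

    def test_300ms_trial_is_not_fast(self):
        fraction, _ = check_fast_exclusion(make_session({3: [300.0] * 10}))
        assert fraction == 0.0


class TestComputeD:
    def test_hand_computed_two_level_example(self):
        """20 trials at 700 vs 900 (and 40 vs 40): pooled SDs 101.27/100.63,
        quotients 1.975/1.987, D about 1.981."""
        r = compute_d(two_level_session(), variant="error_penalty")
        assert r.pooled_sd_36 == pytest.approx(101.2739, abs=1e-3)
        assert r.pooled_sd_47 == pytest.approx(100.6309, abs=1e-3)
        assert r.quotient_36 == pytest.approx(1.9748, abs=1e-3)
        assert r.quotient_47 == pytest.approx(1.9875, abs=1e-3)
        assert r.d == pytest.approx(1.9812, abs=1e-3)
        assert r.d == pytest.approx((r.quotient_36 + r.quotient_47) / 2)

    def test_equal_block_multisets_give_zero(self):
        lat20 = [650.0, 700.0, 750.0, 800.0] * 5
        lat40 = lat20 * 2
        s = make_session({3: lat20, 6: list(reversed(lat20)),
                          4: lat40, 7: list(reversed(lat40))})
        assert compute_d(s).d == pytest.approx(0.0, abs=1e-12)

    def test_variants_identical_without_errors(self):
        s = generate_session(SimulationParams(error_rate=0.0, seed=7), 0)
        ref = compute_d(s, "reference")
        pen = compute_d(s, "error_penalty")
        assert ref.d == pytest.approx(pen.d, abs=1e-12)

    def test_reference_variant_replaces_errors_with_mean_plus_600(self):
        # one error in block 3; correct-trial mean there is 700
        s = make_session({
            3: [700.0] * 19 + [(900.0, 1400.0)],
            4: [700.0] * 40, 6: [900.0] * 20, 7: [900.0] * 40,
        })
        r = compute_d(s, "reference")
        expected_b3 = (19 * 700.0 + (700.0 + 600.0)) / 20
        assert r.block_means[3] == pytest.approx(expected_b3)
        pen = compute_d(s, "error_penalty")
        expected_b3_pen = (19 * 700.0 + 1400.0) / 20
        assert pen.block_means[3] == pytest.approx(expected_b3_pen)
        assert r.d != pytest.approx(pen.d)

    def test_variant_difference_sign_follows_error_load(self):
        """Errors loaded onto the congruent pair make the error-penalty D
        larger (congruent blocks slower raises the incongruent advantage
        less than the +600 replacement does here, and vice versa)."""
        base = {4: [700.0] * 40, 6: [900.0] * 20, 7: [900.0] * 40}
        errors_congruent = make_session(
            {3: [700.0] * 15 + [(700.0, 2500.0)] * 5, **base})
        ref = compute_d(errors_congruent, "reference")
        pen = compute_d(errors_congruent, "error_penalty")
        # corrected latencies (2500) exceed correct-mean + 600 (1300), so the
        # congruent block mean is higher under error_penalty: D shrinks
        assert pen.d < ref.d

    def test_excluded_flag_from_fast_fraction(self):
        s = make_session({
            3: [250.0] * 14 + [700.0] * 6,
            4: [700.0] * 40, 6: [900.0] * 20, 7: [900.0] * 40,
        })
        r = compute_d(s)
        assert r.excluded and r.fast_trial_fraction == pytest.approx(14 / 120)

    def test_zero_pooled_sd_raises(self):
        s = make_session({3: [700.0] * 20, 6: [700.0] * 20,
                          4: [700.0] * 40, 7: [900.0] * 40})
        with pytest.raises(DegenerateDataError):
            compute_d(s)

    def test_missing_block_raises(self):
        s = make_session({3: [700.0] * 20, 4: [700.0] * 40, 6: [900.0] * 20})
        with pytest.raises(StructureError):
            compute_d(s)

    def test_slow_removal_feeds_fast_fraction_denominator(self):
        """Slow trials are removed before the fast fraction is computed."""
        s = make_session({
            3: [250.0] * 2 + [700.0] * 8 + [11_000.0] * 10,
            4: [700.0] * 4, 6: [900.0] * 4, 7: [900.0] * 4,
        })
        r = compute_d(s)
        assert r.n_trials_removed_slow == 10
        # 22 trials survive the slow filter across the four blocks
        assert r.fast_trial_fraction == pytest.approx(2 / 22)
        assert not r.excluded


class TestInvariances:
    def _sim_sessions(self, n=5, **kw):
        params = SimulationParams(n_participants=n, seed=11, **kw)
        return generate_cohort(params)

    def _shift(self, session, c):
        trials = [
            TrialRecord(
                t.participant_id, t.block, t.trial_index, t.block_function,
                t.pairing, t.stimulus_kind, t.first_response_correct,
                t.first_latency_ms + c, t.latency_ms + c,
            )
            for t in session.trials
        ]
        return session.with_trials(trials)

    def _scale(self, session, k):
        trials = [
            TrialRecord(
                t.participant_id, t.block, t.trial_index, t.block_function,
                t.pairing, t.stimulus_kind, t.first_response_correct,
                t.first_latency_ms * k, t.latency_ms * k,
            )
            for t in session.trials
        ]
        return session.with_trials(trials)

    def _swap_pairs(self, session):
        """Relabel congruent<->incongruent by exchanging blocks 3<->6, 4<->7."""
        swap = {3: 6, 6: 3, 4: 7, 7: 4}
        trials = [
            TrialRecord(
                t.participant_id, swap.get(t.block, t.block), t.trial_index,
                t.block_function,
                {"congruent": "incongruent", "incongruent": "congruent"}.get(
                    t.pairing, t.pairing),
                t.stimulus_kind, t.first_response_correct,
                t.first_latency_ms, t.latency_ms,
            )
            for t in session.trials
        ]
        return session.with_trials(trials)

    @pytest.mark.parametrize("variant", ["reference", "error_penalty"])
    def test_antisymmetry_under_pair_relabelling(self, variant):
        for s in self._sim_sessions():
            d = compute_d(s, variant).d
            d_sw = compute_d(self._swap_pairs(s), variant).d
            assert d_sw == pytest.approx(-d, abs=1e-12)

    @pytest.mark.parametrize("variant", ["reference", "error_penalty"])
    def test_shift_invariance(self, variant):
        for s in self._sim_sessions(error_rate=0.1):
            d = compute_d(s, variant).d
            assert compute_d(self._shift(s, 500.0), variant).d == pytest.approx(d, abs=1e-9)

    @pytest.mark.parametrize("variant", ["reference", "error_penalty"])
    def test_scale_invariance_of_error_penalty(self, variant):
        # scaling is exactly invariant when no fixed additive constant enters,
        # i.e. for the error-penalty variant always and for the reference
        # variant on error-free data
        for s in self._sim_sessions(error_rate=0.0):
            d = compute_d(s, variant).d
            assert compute_d(self._scale(s, 2.5), variant).d == pytest.approx(d, abs=1e-9)

    @pytest.mark.parametrize("variant", ["reference", "error_penalty"])
    def test_matches_independent_twelve_step_transcription(self, variant):
        for s in self._sim_sessions(n=6, error_rate=0.08):
            expected_d, expected_excl = twelve_step_d(s, variant)
            r = compute_d(s, variant)
            assert r.d == pytest.approx(expected_d, abs=1e-10)
            assert r.excluded == expected_excl


class TestScoreCohort:
    def test_mean_of_norms_matches_mean_of_scores(self):
        sessions = generate_cohort(SimulationParams(n_participants=8, seed=3))
        results, norms = score_cohort(sessions)
        ds = [r.d for r in results if not r.excluded]
        assert norms.mean == pytest.approx(np.mean(ds))
        assert norms.sd == pytest.approx(np.std(ds, ddof=1))
        assert norms.n == len(ds)

    def test_excluded_sessions_flagged_not_dropped(self):
        clean = generate_cohort(SimulationParams(n_participants=9, seed=5))
        noisy = generate_session(
            SimulationParams(fast_responder_rate=0.4, n_participants=1, seed=99), 0)
        results, norms = score_cohort(clean + [noisy])
        assert len(results) == 10
        assert sum(r.excluded for r in results) == 1
        assert norms.n == 9

    def test_null_cohort_mean_is_near_zero(self):
        params = SimulationParams(
            congruency_effect_ms=0.0, error_rate=0.0, n_participants=180, seed=21)
        _, norms = score_cohort(generate_cohort(params))
        assert abs(norms.mean) < 3 * norms.sd / np.sqrt(norms.n)

    def test_too_few_retained_raises(self):
        params = SimulationParams(fast_responder_rate=0.5, n_participants=3, seed=2)
        with pytest.raises(ValidationError):
            score_cohort(generate_cohort(params))
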