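"""Learning signals: running P(Stop), per-trial updates, RT change, RPE, QC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sstlearn import (RPEModelParams, RunConfig, apply_burn_in,
                      cohort_accounting, compute_signals, delta_pstop,
                      delta_rt, pstop_series, qc_filter_runs, rpe,
                      simulate_run)
from sstlearn.task_sim import (BehavioralRun, CORRECT_GO, CORRECT_STOP,
                               FAILED_STOP, GO, STOP, TrialRecord)


def brute_force_pstop(types):
    """Oracle: recompute proportions at every trial from scratch."""
    before, after = [], []
    for k in range(1, len(types) + 1):
        prior = types[: k - 1]
        before.append(sum(t == STOP for t in prior) / (k - 1) if k > 1 else 0.0)
        upto = types[:k]
        after.append(sum(t == STOP for t in upto) / k)
    return np.array(before), np.array(after)


class TestPstop:
    def test_all_go_is_zero_everywhere(self):
        assert np.all(pstop_series([GO] * 10) == 0.0)
        assert np.all(delta_pstop([GO] * 10)[1:] == 0.0)

    def test_counting_example(self):
        est = pstop_series([STOP, GO, GO, STOP, GO])
        assert est[4] == pytest.approx(2 / 4)

    def test_no_prior_stop_before_trial_two(self):
        assert pstop_series([GO, STOP]).tolist() == [0.0, 0.0]

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pstop_series([])

    def test_update_arithmetic_example(self):
        # stop at trial 10 with exactly 1 prior stop: 2/10 - 1/9
        types = [STOP] + [GO] * 8 + [STOP]
        assert delta_pstop(types)[9] == pytest.approx(2 / 10 - 1 / 9)

    def test_update_shrinks_with_trial_number(self):
        types = [GO, STOP] * 60
        d = np.abs(delta_pstop(types))
        assert d[99] < d[9]

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from([GO, STOP]), min_size=1, max_size=60))
    def test_matches_brute_force_and_telescopes(self, types):
        before, after = brute_force_pstop(types)
        est = pstop_series(types)
        d = delta_pstop(types)
        np.testing.assert_allclose(est, before, atol=1e-12)
        np.testing.assert_allclose(d, after - before, atol=1e-12)
        # telescoping: summed updates equal final-minus-initial estimate
        assert d.sum() == pytest.approx(after[-1] - before[0])
        assert np.all((est >= 0) & (est <= 1))

    def test_update_sign_follows_trial_type(self):
        types = [STOP, GO, STOP, GO, GO, STOP]
        d = delta_pstop(types)
        for k in range(2, len(types)):  # both types seen by then
            assert (d[k] > 0) == (types[k] == STOP)


def _manual_run(records):
    cfg = RunConfig()
    return BehavioralRun("s", 1, cfg, list(records))


class TestDeltaRT:
    def test_post_minus_pre_sign_convention(self):
        run = _manual_run([
            TrialRecord(1, GO, 0.0, rt=0.400),
            TrialRecord(2, STOP, 4.0, ssd=0.25, outcome=CORRECT_STOP),
            TrialRecord(3, GO, 8.0, rt=0.450),
        ])
        assert delta_rt(run, 2) == pytest.approx(+0.050)

    def test_zero_when_flanks_equal(self):
        run = _manual_run([
            TrialRecord(1, GO, 0.0, rt=0.4),
            TrialRecord(2, STOP, 4.0, ssd=0.25, outcome=CORRECT_STOP),
            TrialRecord(3, GO, 8.0, rt=0.4),
        ])
        assert delta_rt(run, 2) == 0.0

    def test_boundary_stop_has_no_value(self):
        run = _manual_run([
            TrialRecord(1, GO, 0.0, rt=0.4),
            TrialRecord(2, STOP, 4.0, ssd=0.25, outcome=CORRECT_STOP),
        ])
        assert delta_rt(run, 2) is None

    def test_search_skips_invalid_flanks(self):
        # omission and a second stop trial between the flanking go responses
        run = _manual_run([
            TrialRecord(1, GO, 0.0, rt=0.300),
            TrialRecord(2, GO, 4.0, outcome="go_omission"),
            TrialRecord(3, STOP, 8.0, ssd=0.25, outcome=CORRECT_STOP),
            TrialRecord(4, STOP, 12.0, ssd=0.25, outcome=CORRECT_STOP),
            TrialRecord(5, GO, 16.0, rt=0.500),
        ])
        assert delta_rt(run, 3) == pytest.approx(0.200)

    def test_go_trial_rejected(self):
        run = _manual_run([TrialRecord(1, GO, 0.0, rt=0.4)])
        with pytest.raises(ValueError):
            delta_rt(run, 1)

    def test_slowing_constant_recovered(self, default_config):
        # simulated +s slowing after failed stops shows up in mean delta_rt
        s = 0.100
        cfg = default_config.replace(post_error_slowing=s)
        vals = []
        for seed in range(80):
            run = simulate_run(f"x{seed}", 1, cfg, seed=seed)
            for t in run.trials:
                if t.outcome == FAILED_STOP:
                    d = delta_rt(run, t.index)
                    if d is not None:
                        vals.append(d)
        # flank search occasionally passes over the slowed trial, biasing the
        # mean slightly toward zero; allow for that plus MC error
        assert np.mean(vals) == pytest.approx(s, abs=0.025)


class TestRPE:
    def test_zero_inputs_give_zero(self):
        assert rpe(0.0, 0.0, RPEModelParams(epsilon_sd=0.0)) == 0.0

    def test_identity_on_one_term(self):
        p = RPEModelParams(beta1=1.0, beta2=0.0, epsilon_sd=0.0)
        assert rpe(0.1, 99.0, p) == pytest.approx(0.1)

    def test_deterministic_without_noise(self):
        p = RPEModelParams(beta1=2.0, beta2=-1.0, epsilon_sd=0.0)
        assert rpe(0.05, 0.03, p, np.random.default_rng(0)) == pytest.approx(0.07)

    def test_nonfinite_inputs_rejected(self):
        with pytest.raises(ValueError):
            rpe(np.nan, 0.0, RPEModelParams())

    def test_valence_pattern_across_cohort(self, default_config):
        # positive after correct stops, negative after failed stops, once the
        # early large-update trials are excluded
        frames = []
        for seed in range(40):
            run = simulate_run(f"v{seed}", 1, default_config, seed=seed)
            frames.append(compute_signals(run, rng=seed))
        big = pd.concat(frames)
        post = apply_burn_in(big[big.trial_type == STOP])
        means = post.groupby("stop_failure")["rpe"].mean()
        assert means[0.0] > 0
        assert means[1.0] < 0


class TestQC:
    def _run_with_accuracy(self, acc, n_stop=20):
        n_correct = round(acc * n_stop)
        recs = []
        for i in range(n_stop):
            if i < n_correct:
                recs.append(TrialRecord(i + 1, STOP, 4.0 * i, ssd=0.25,
                                        outcome=CORRECT_STOP))
            else:
                recs.append(TrialRecord(i + 1, STOP, 4.0 * i, ssd=0.25,
                                        rt=0.4, outcome=FAILED_STOP))
        return _manual_run(recs)

    @pytest.mark.parametrize("acc, kept", [
        (0.15, False),   # below the 20% floor
        (0.20, True),    # boundary retained: exclusion is strict
        (0.50, True),
        (0.80, True),
        (0.85, False),   # above the 80% ceiling
    ])
    def test_retention_band(self, acc, kept):
        runs, report = qc_filter_runs([self._run_with_accuracy(acc)])
        assert (len(runs) == 1) == kept
        if not kept:
            assert report.iloc[0]["reason"] in ("low_stop_accuracy",
                                                "high_stop_accuracy")

    def test_run_without_stop_trials_flagged(self):
        run = _manual_run([TrialRecord(1, GO, 0.0, rt=0.4)])
        kept, report = qc_filter_runs([run])
        assert not kept
        assert report.iloc[0]["reason"] == "no_stop_trials"


class TestBurnInAndLedger:
    def test_burn_in_removes_first_25(self, one_run_signals):
        out = apply_burn_in(one_run_signals, 25)
        assert len(out) == 128 - 25
        assert out["trial"].min() == 26

    def test_burn_in_zero_is_identity(self, one_run_signals):
        assert apply_burn_in(one_run_signals, 0).equals(one_run_signals)

    def test_signals_unchanged_by_filtering(self, one_run_signals):
        filtered = apply_burn_in(one_run_signals, 25)
        row = filtered[filtered.trial == 30].iloc[0]
        raw = one_run_signals[one_run_signals.trial == 30].iloc[0]
        assert row["pstop_est"] == raw["pstop_est"]
        assert row["delta_pstop"] == raw["delta_pstop"]

    def test_burn_in_larger_than_run_warns(self, one_run_signals):
        with pytest.warns(UserWarning):
            out = apply_burn_in(one_run_signals, 500)
        assert out.empty

    def test_ledger_arithmetic(self):
        ledger = cohort_accounting(275, [("procedure", 20), ("missing", 4),
                                         ("quality", 34)])
        assert ledger.final == 217
        frame = ledger.to_frame()
        assert frame["remaining"].tolist() == [275, 255, 251, 217]

    def test_empty_ledger_is_identity(self):
        assert cohort_accounting(10, []).final == 10

    def test_impossible_ledger_rejected(self):
        with pytest.raises(ValueError):
            cohort_accounting(10, [("too_many", 11)])
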