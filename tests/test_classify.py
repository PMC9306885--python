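"""Outcome assignment, MAD statistics and PVT lapse labelling."""

import numpy as np
import pandas as pd
import pytest

from vigilpupil import classify, schedule
from vigilpupil.classify import (
    assign_outcomes,
    label_lapses,
    mad,
    pvt_trial_table,
    reciprocal_rt,
)
from vigilpupil.synthetic import ResponseLog


def toy_schedule(target_times_ms, duration_ms=60_000, tick=500):
    """Build a schedule with targets at the given tick-aligned times."""
    events = []
    targets = set(target_times_ms)
    for t in range(0, duration_ms, tick):
        if t in targets:
            events.append(schedule.StimulusEvent(t, "target", 0))
        else:
            events.append(schedule.StimulusEvent(t, "neutral"))
    return schedule.StimulusSchedule(events=events, duration_ms=duration_ms,
                                     tick_period_ms=tick)


class TestMad:
    def test_hand_computed_example(self):
        values = [400, 450, 500, 550, 600]
        assert mad(values, scale_constant=1.0) == 50.0
        assert mad(values) == pytest.approx(74.13)

    def test_constant_sequence_zero(self):
        assert mad([7.0] * 10) == 0.0

    def test_affine_equivariance(self, rng):
        x = rng.normal(size=101)
        assert mad(x + 42.0) == pytest.approx(mad(x))
        assert mad(3.0 * x) == pytest.approx(3.0 * mad(x))

    def test_empty_rejected(self):
        with pytest.raises(classify.ClassifyError):
            mad([])


class TestAssignOutcomes:
    def test_hand_traced_example(self):
        """Targets at 10 s and 20 s; presses at 10.6, 15.0 and 27.0 s with a
        [225, 1156] ms window give HIT / FA (out of window) / FA (> 6 s)."""
        sched = toy_schedule([10_000, 20_000])
        responses = ResponseLog(np.array([10_600.0, 15_000.0, 27_000.0]))
        table = assign_outcomes(sched, responses, hit_window_ms=(225.0, 1156.0))
        rec = table.records
        t1 = rec[rec.event_time_ms == 10_000].iloc[0]
        assert t1.outcome == "HIT" and t1.rt_ms == 600.0
        t2 = rec[rec.event_time_ms == 20_000].iloc[0]
        assert t2.outcome == "MISS"
        fas = rec[rec.outcome == "FA"]
        assert len(fas) == 2
        # each FA bound to the nearest elapsed neutral event
        assert set(fas.assigned_press_ms) == {15_000.0, 27_000.0}
        assert (fas.event_time_ms <= fas.assigned_press_ms).all()

    def test_empty_response_log(self):
        sched = toy_schedule([10_000, 20_000])
        table = assign_outcomes(sched, ResponseLog(np.array([])))
        counts = table.counts()
        assert counts["MISS"] == 2
        assert counts["CR"] == len(sched.events) - 2
        assert "HIT" not in counts and "FA" not in counts

    def test_degenerate_constant_rt_all_hits(self):
        """Identical 600 ms RTs: MAD 0 widens the window to +/-1 ms and every
        target is a hit."""
        times = [5000, 15_000, 25_000, 35_000]
        sched = toy_schedule(times)
        responses = ResponseLog(np.array([t + 600.0 for t in times]))
        table = assign_outcomes(sched, responses)
        assert table.counts()["HIT"] == 4
        lo, hi = table.hit_window_ms
        assert (lo, hi) == (599.0, 601.0)

    def test_press_before_any_target_is_fa(self):
        sched = toy_schedule([30_000])
        table = assign_outcomes(sched, ResponseLog(np.array([4000.0, 30_500.0])),
                                hit_window_ms=(225.0, 1156.0))
        rec = table.records
        assert rec[rec.event_time_ms == 30_000].iloc[0].outcome == "HIT"
        assert (rec.outcome == "FA").sum() == 1

    def test_surplus_press_on_hit_target_becomes_fa(self):
        sched = toy_schedule([10_000])
        responses = ResponseLog(np.array([10_600.0, 10_700.0]))
        table = assign_outcomes(sched, responses, hit_window_ms=(225.0, 1156.0))
        counts = table.counts()
        assert counts["HIT"] == 1 and counts["FA"] == 1

    @pytest.mark.parametrize("seed", range(20))
    def test_conservation_laws(self, seed):
        """#HIT+#MISS = targets, #FA+#CR = neutrals, #HIT+#FA = presses."""
        rng = np.random.default_rng(seed)
        sched = toy_schedule([6000, 14_000, 22_000, 30_000, 40_000], 50_000)
        n_press = int(rng.integers(0, 12))
        presses = np.sort(rng.uniform(500, 49_500, size=n_press))
        presses = presses[np.r_[True, np.diff(presses) > 1] if n_press else []]
        table = assign_outcomes(sched, ResponseLog(presses),
                                hit_window_ms=(225.0, 1156.0))
        c = table.counts()
        assert c.get("HIT", 0) + c.get("MISS", 0) == 5
        assert c.get("FA", 0) + c.get("CR", 0) == len(sched.neutral_times_ms)
        assert c.get("HIT", 0) + c.get("FA", 0) == presses.size

    @pytest.mark.parametrize("seed", range(200))
    def test_matches_bruteforce_enumerator(self, seed):
        """Rule-by-rule brute-force re-derivation agrees on random small
        sessions (the oracle walks presses with explicit loops)."""
        rng = np.random.default_rng(seed)
        target_times = sorted(
            rng.choice(np.arange(4, 36) * 500, size=3, replace=False)
        )
        sched = toy_schedule([int(t) for t in target_times], 20_000)
        n_press = int(rng.integers(0, 7))
        presses = np.sort(rng.uniform(100, 19_900, size=n_press))
        if presses.size > 1:
            presses = presses[np.r_[True, np.diff(presses) > 1]]
        window = (225.0, 1156.0)
        table = assign_outcomes(sched, ResponseLog(presses),
                                min_gap_ms=6000.0, hit_window_ms=window)

        # --- independent oracle -------------------------------------------
        targets = [float(t) for t in sched.target_times_ms]
        neutrals = [float(t) for t in sched.neutral_times_ms]
        hit_on = {}
        fa_presses = []
        for p in presses:
            prev = [t for t in targets if t <= p]
            rt = p - prev[-1] if prev else None
            if (
                rt is not None and rt <= 6000.0
                and window[0] <= rt <= window[1]
                and prev[-1] not in hit_on
            ):
                hit_on[prev[-1]] = (p, rt)
            else:
                fa_presses.append(p)
        rec = table.records
        for t in targets:
            row = rec[rec.event_time_ms == t].iloc[0]
            if t in hit_on:
                assert row.outcome == "HIT"
                assert row.rt_ms == pytest.approx(hit_on[t][1])
            else:
                assert row.outcome == "MISS"
        assert (rec.outcome == "FA").sum() == len(fa_presses)
        for p in fa_presses:
            row = rec[rec.assigned_press_ms == p]
            assert len(row) == 1
            # bound at or before the press except the leading-edge fallback
            elapsed = [t for t in neutrals if t <= p]
            if elapsed:
                assert row.iloc[0].event_time_ms <= p

    def test_widening_k_never_decreases_hits(self):
        rng = np.random.default_rng(5)
        sched = toy_schedule([6000, 16_000, 26_000, 36_000, 46_000], 55_000)
        presses = np.sort(
            np.concatenate([
                sched.target_times_ms + rng.uniform(300, 900, 5),
                rng.uniform(1000, 54_000, 3),
            ])
        )
        hits = [
            assign_outcomes(sched, ResponseLog(presses), k=k).counts().get("HIT", 0)
            for k in (0.5, 1.0, 2.0, 4.0)
        ]
        assert hits == sorted(hits)


class TestLapses:
    def test_hand_computed_example(self):
        rts = [400, 410, 420, 430, 1000]
        lapse, threshold = label_lapses(rts)
        assert threshold == pytest.approx(420 + 2 * 14.826)
        assert lapse.tolist() == [False, False, False, False, True]

    def test_constant_rts_no_lapses(self):
        lapse, _ = label_lapses([500.0] * 20)
        assert not lapse.any()

    def test_too_few_trials_rejected(self):
        with pytest.raises(classify.ClassifyError):
            label_lapses([400, 500])

    def test_cohort_thresholds_near_mixture_boundary(self):
        """Across a synthetic PVT cohort the average threshold sits between
        the non-lapse bulk and the lapse component (generator: 420/960 ms)."""
        from vigilpupil.synthetic import ObserverParams, simulate_pvt_behavior
        sched = schedule.generate_pvt_schedule(seed=31)
        obs = ObserverParams()
        thresholds = []
        for seed in range(23):
            _, truth = simulate_pvt_behavior(sched, obs, seed=seed)
            _, thr = label_lapses(truth.rt_ms)
            thresholds.append(thr)
        assert 450 < np.mean(thresholds) < 750


class TestReciprocalRt:
    @pytest.mark.parametrize("rt,expected", [(500.0, 2.0), (1000.0, 1.0),
                                             (420.0, 1000.0 / 420.0)])
    def test_values(self, rt, expected):
        assert reciprocal_rt(rt) == pytest.approx(expected)

    def test_non_positive_rejected(self):
        with pytest.raises(classify.ClassifyError):
            reciprocal_rt(0.0)


class TestPvtTrialTable:
    def test_blocks_and_trial_groups(self):
        rts = np.full(270, 400.0) + np.arange(270)  # strictly increasing
        table, _ = pvt_trial_table(rts)
        assert (table.groupby("block").size() == 90).all()
        assert (table.groupby(["block", "trial_group"]).size() == 18).all()
        assert table.trial_group.between(1, 5).all()
        np.testing.assert_allclose(table.recip_rt_per_s, 1000.0 / table.rt_ms)
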