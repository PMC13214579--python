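import numpy as np
import pytest
from hypothesis import given, strategies as st

import damsleep.sleep as sl
from damsleep.sleep import (
    activity_metrics,
    eduction,
    ld_day_slices,
    p_doze,
    p_wake,
    score_sleep,
    sleep_indicator,
    sleep_latency,
    sleep_metrics,
    sleep_timecourse,
)


def rle_sleep_oracle(counts, min_len=5):
    """Brute-force run-length scan for zero runs >= min_len."""
    bouts, start = [], None
    for i, c in enumerate(counts):
        if c == 0 and start is None:
            start = i
        elif c != 0 and start is not None:
            if i - start >= min_len:
                bouts.append((start, i - start))
            start = None
    if start is not None and len(counts) - start >= min_len:
        bouts.append((start, len(counts) - start))
    return bouts


def day_series(make_series, day_counts, night_counts=None):
    if night_counts is None:
        night_counts = np.ones(720, dtype=int)
    return make_series(np.concatenate([day_counts, night_counts]))


class TestScoreSleep:
    def test_five_minute_threshold_boundary(self, make_series):
        counts = np.ones(1440, dtype=int)
        counts[:5] = 0
        bouts = score_sleep(make_series(counts))
        assert len(bouts) == 1
        assert bouts[0].start_index == 0 and bouts[0].length_min == 5
        assert bouts[0].phase_of_onset == "day"

    def test_runs_shorter_than_five_ignored(self, make_series):
        counts = np.ones(1440, dtype=int)
        counts[0:4] = 0
        counts[5:9] = 0
        assert score_sleep(make_series(counts)) == []

    def test_coarse_bins_rejected(self, make_series):
        s = make_series(np.zeros(48), bin_width=30)
        with pytest.raises(ValueError, match="1-min"):
            score_sleep(s)

    @given(st.lists(st.integers(0, 1), min_size=1, max_size=600))
    def test_matches_rle_oracle(self, bits):
        import datetime as dt
        from damsleep.damio import ActivitySeries, LightSchedule, annotate_photoperiod

        counts = np.concatenate([bits, np.ones(1440 - len(bits), dtype=int)])
        s = annotate_photoperiod(
            ActivitySeries(fly_id="f", monitor_id="m", channel=1,
                           group_label="g", bin_width=1,
                           t0=dt.datetime(2024, 1, 1, 8), counts=counts),
            LightSchedule(lights_on=dt.time(8, 0)),
        )
        got = [(b.start_index, b.length_min) for b in score_sleep(s)]
        assert got == rle_sleep_oracle(counts)

    def test_bout_maximality(self, make_series):
        rng = np.random.default_rng(3)
        counts = (rng.random(1440) < 0.5).astype(int)
        s = make_series(counts)
        bouts = score_sleep(s)
        for b in bouts:
            lo, hi = b.start_index, b.start_index + b.length_min
            assert (counts[lo:hi] == 0).all()
            if lo > 0:
                assert counts[lo - 1] != 0
            if hi < len(counts):
                assert counts[hi] != 0


class TestActivityMetrics:
    def test_fully_active_phase(self, make_series):
        s = make_series(np.ones(1440, dtype=int))
        n_ep, minutes = activity_metrics(s, "day")
        assert minutes == 720.0
        # one maximal run starting at ZT0, attributed to the day phase
        assert n_ep == 1.0
        n_ep_night, minutes_night = activity_metrics(s, "night")
        assert minutes_night == 720.0 and n_ep_night == 0.0

    def test_alternating_pattern(self, make_series):
        counts = np.tile([1, 0], 720)
        s = make_series(counts)
        n_ep, minutes = activity_metrics(s, "day")
        assert n_ep == 360.0 and minutes == 360.0

    def test_matches_rle_oracle_on_random_input(self, make_series):
        rng = np.random.default_rng(11)
        counts = (rng.random(1440) < 0.6).astype(int)
        s = make_series(counts)
        # oracle: runs of nonzero counts, onset attribution per phase
        runs = rle_sleep_oracle(1 - counts, min_len=1)
        for phase, (lo, hi) in (("day", (0, 720)), ("night", (720, 1440))):
            n_ep, minutes = activity_metrics(s, phase)
            exp_ep = sum(1 for s0, _ in runs if lo <= s0 < hi)
            exp_min = int(counts[lo:hi].sum())
            assert n_ep == exp_ep
            assert minutes == exp_min


class TestSleepLatency:
    def test_bout_at_lights_off_gives_zero(self, make_series):
        counts = np.ones(1440, dtype=int)
        counts[720:740] = 0
        s = make_series(counts)
        lat, cens = sleep_latency(score_sleep(s), s, "lights_off")
        assert list(lat) == [0.0] and not cens[0]

    def test_no_night_sleep_censored_at_720(self, make_series):
        counts = np.ones(1440, dtype=int)
        counts[10:100] = 0  # day sleep only
        s = make_series(counts)
        lat, cens = sleep_latency(score_sleep(s), s, "lights_off")
        assert list(lat) == [720.0] and cens[0]
        lat_day, cens_day = sleep_latency(score_sleep(s), s, "lights_on")
        assert list(lat_day) == [10.0] and not cens_day[0]

    def test_matches_linear_scan_on_simulated_days(self, sim_fly):
        bouts = score_sleep(sim_fly)
        days = ld_day_slices(sim_fly)
        lat, _ = sleep_latency(bouts, sim_fly, "lights_on")
        for (ds, de), got in zip(days, lat):
            onsets = [b.start_index for b in bouts if ds <= b.start_index < ds + 720]
            expected = (onsets[0] - ds) if onsets else 720.0
            assert got == expected


class TestTransitionProbabilities:
    def test_alternating_gives_one(self, make_series):
        s = make_series(np.tile([1, 0], 720))
        assert p_doze(s, "day") == 1.0
        assert p_wake(s, "day") == 1.0

    def test_constant_activity_gives_zero_doze(self, make_series):
        s = make_series(np.ones(1440, dtype=int))
        assert p_doze(s, "day") == 0.0
        assert np.isnan(p_wake(s, "day"))  # no inactive minute: undefined

    def test_constant_inactivity_gives_zero_wake(self, make_series):
        s = make_series(np.zeros(1440, dtype=int))
        assert p_wake(s, "night") == 0.0
        assert np.isnan(p_doze(s, "night"))

    def test_numerator_is_integer_transition_count(self, sim_fly):
        # P(Doze) * eligible active minutes == integer count by construction
        days = ld_day_slices(sim_fly)
        mask = sl._phase_mask(sim_fly, "day")
        active = sim_fly.counts != 0
        den = sum(
            int((mask[ds : de - 1] & mask[ds + 1 : de] & active[ds : de - 1]).sum())
            for ds, de in days
        )
        val = p_doze(sim_fly, "day", days)
        assert abs(val * den - round(val * den)) < 1e-9

    @pytest.mark.parametrize("pd_true,pw_true", [(0.3, 0.1), (0.15, 0.25)])
    def test_markov_parameter_recovery(self, pd_true, pw_true):
        import datetime as dt
        from damsleep.damio import LightSchedule
        from damsleep.synthetic import GroupSpec, simulate_fly

        sched = LightSchedule(lights_on=dt.time(8, 0))
        spec = GroupSpec(
            label="g", p_doze_mesor=pd_true, p_doze_amp=0.0,
            p_wake_mesor=pw_true, p_wake_amp=0.0,
            fragmentation_multiplier=1.0, startle_boost=0.0,
        )
        hits = 0
        n_seeds = 30
        for seed in range(n_seeds):
            fly = simulate_fly(spec, sched, 2, 1000 + seed)
            days = ld_day_slices(fly)
            mask = sl._phase_mask(fly, "day")
            active = fly.counts != 0
            den = sum(
                int((mask[ds:de - 1] & mask[ds + 1:de] & active[ds:de - 1]).sum())
                for ds, de in days
            )
            se = np.sqrt(pd_true * (1 - pd_true) / den)
            hits += abs(p_doze(fly, "day", days) - pd_true) < 3 * se
        assert hits >= int(0.9 * n_seeds)


class TestSleepMetrics:
    def test_hand_constructed_day(self, make_series):
        counts = np.ones(1440, dtype=int)
        counts[100:110] = 0  # 10-min bout
        counts[300:320] = 0  # 20-min bout
        m = sleep_metrics(make_series(counts))
        assert m["day"].n_episodes == 2.0
        assert m["day"].total_sleep_min == 30.0
        assert m["day"].mean_bout_min == 15.0
        assert m["night"].total_sleep_min == 0.0
        assert m["day"].latency_min == 100.0

    def test_day_night_totals_sum_to_24h_total(self, sim_fly):
        m = sleep_metrics(sim_fly)
        days = ld_day_slices(sim_fly)
        ind = sleep_indicator(sim_fly)
        total = sum(ind[ds:de].sum() for ds, de in days) / len(days)
        assert m["day"].total_sleep_min + m["night"].total_sleep_min == pytest.approx(total)

    def test_matches_independent_per_day_computation(self, sim_fly):
        m = sleep_metrics(sim_fly)
        days = ld_day_slices(sim_fly)
        ind = sleep_indicator(sim_fly)
        mask = sl._phase_mask(sim_fly, "day")
        per_day = [int((ind[ds:de] & mask[ds:de]).sum()) for ds, de in days]
        assert m["day"].total_sleep_min == pytest.approx(np.mean(per_day))

    def test_phase_conservation(self, sim_fly):
        """sleep + active minutes + sub-threshold immobility = 720 per phase."""
        days = ld_day_slices(sim_fly)
        ind = sleep_indicator(sim_fly)
        active = (sim_fly.counts != 0).astype(int)
        m = sleep_metrics(sim_fly)
        for phase in ("day", "night"):
            mask = sl._phase_mask(sim_fly, phase)
            _, act_min = activity_metrics(sim_fly, phase)
            sub = np.mean([
                int(((1 - active[ds:de]) & (1 - ind[ds:de]) & mask[ds:de]).sum())
                for ds, de in days
            ])
            assert m[phase].total_sleep_min + act_min + sub == pytest.approx(720.0)

    def test_no_complete_day_is_hard_error(self, make_series):
        with pytest.raises(ValueError, match="complete LD day"):
            sleep_metrics(make_series(np.ones(100, dtype=int)))


class TestProfiles:
    def test_identical_flies_have_zero_sem(self, make_series):
        counts = np.tile([2, 0], 720)
        flies = [make_series(counts, fly_id=f"f{i}", channel=i + 1) for i in range(3)]
        prof = eduction(flies)
        assert np.allclose(prof.sem, 0.0)
        assert prof.n_flies == 3

    def test_single_fly_profile_equals_rebinned_counts(self, make_series):
        rng = np.random.default_rng(5)
        counts = rng.poisson(2, 1440)
        prof = eduction([make_series(counts)])
        expected = counts.reshape(48, 30).sum(axis=1)
        assert np.allclose(prof.mean, expected)
        assert len(prof.bin_zt) == 48

    def test_two_fly_mean_and_sem_by_hand(self, make_series):
        a = make_series(np.full(1440, 1))
        b = make_series(np.full(1440, 3), fly_id="f2", channel=2)
        prof = eduction([a, b])
        assert np.allclose(prof.mean, 60.0)  # (30 + 90) / 2 per 30-min bin
        assert np.allclose(prof.sem, np.std([30, 90], ddof=1) / np.sqrt(2))

    def test_fully_asleep_fly_timecourse_is_30_everywhere(self, make_series):
        prof = sleep_timecourse([make_series(np.zeros(1440, dtype=int))])
        assert np.allclose(prof.mean, 30.0)

    def test_fully_awake_fly_timecourse_is_zero(self, make_series):
        prof = sleep_timecourse([make_series(np.ones(1440, dtype=int))])
        assert np.allclose(prof.mean, 0.0)

    def test_timecourse_sums_to_daily_sleep_total(self, sim_fly):
        prof = sleep_timecourse([sim_fly])
        m = sleep_metrics(sim_fly)
        daily_total = m["day"].total_sleep_min + m["night"].total_sleep_min
        assert prof.mean.sum() == pytest.approx(daily_total)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            eduction([])
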