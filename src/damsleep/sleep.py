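"""Sleep-bout scoring and sleep/activity architecture metrics.

Sleep in the fly is operationally defined as five or more consecutive
minutes with zero beam crossings.  This module scores maximal immobility
runs against that threshold, and derives the per-fly, per-phase metrics
used in sleep phenotyping: episode counts, total and mean episode
durations, sleep latency after each light transition, and the two
transition-probability statistics P(Doze) (probability an active minute
is followed by an inactive one; sleep pressure) and P(Wake) (probability
an inactive minute is followed by an active one; sleep depth).

Conventions
-----------
* Day phase is ZT in [0, 12), night is [12, 24); ZT0 = lights-on.
* A bout is counted as an *episode* in the phase where it starts; its
  *minutes* are split across phases at the ZT12/ZT24 boundaries, so
  episode counts stay integral while minutes are conserved.
* Only complete entrained (LD) days are analysed; partial first/last
  days are dropped.  Metrics are averaged across the analysed days.
* P(Doze)/P(Wake) pool transition counts across days within a phase
  before dividing (unbiased when active-minute counts differ between
  days); minute pairs that straddle a phase boundary are excluded from
  both phases so light-driven startle cannot leak into night statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from damsleep.damio import ActivitySeries, GapError

Phase = Literal["day", "night"]

__all__ = [
    "SleepBout",
    "SleepMetrics",
    "EductionProfile",
    "ld_day_slices",
    "dd_day_slices",
    "score_sleep",
    "sleep_indicator",
    "activity_metrics",
    "sleep_latency",
    "p_doze",
    "p_wake",
    "sleep_metrics",
    "eduction",
    "sleep_timecourse",
]

MIN_SLEEP_MIN = 5  # the 5-min immobility rule


@dataclass(frozen=True)
class SleepBout:
    """A maximal run of >= 5 zero-count minutes."""

    start_index: int
    length_min: int
    phase_of_onset: Phase


@dataclass
class SleepMetrics:
    """Per-fly, per-phase sleep summary averaged over complete LD days.

    ``latency_min`` averages censored phases at 720 min (flagged via
    ``n_latency_censored``); ``latency_uncensored_min`` averages only
    days where the fly slept in the phase (NaN if it never did).
    """

    fly_id: str
    phase: Phase
    n_episodes: float
    total_sleep_min: float
    mean_bout_min: float
    latency_min: float
    latency_uncensored_min: float
    n_latency_censored: int
    p_doze: float
    p_wake: float
    n_days_averaged: int


@dataclass
class EductionProfile:
    """Group-average daily activity (or sleep) profile on a ZT grid."""

    group_label: str
    bin_zt: np.ndarray  # left edge of each ZT bin, hours
    mean: np.ndarray
    sem: np.ndarray
    n_flies: int


def _require_minute_bins(series: ActivitySeries) -> None:
    if series.bin_width != 1:
        raise ValueError(
            f"{series.fly_id}: sleep scoring requires 1-min bins, "
            f"got {series.bin_width}-min"
        )


def _require_annotated(series: ActivitySeries) -> None:
    if series.zt is None or series.light is None:
        raise ValueError(
            f"{series.fly_id}: series must be photoperiod-annotated first"
        )


def _day_starts(series: ActivitySeries) -> np.ndarray:
    """Indices where a new ZT day begins (ZT wraps from ~24 to ~0)."""
    zt = series.zt
    starts = np.nonzero(np.diff(zt) < 0)[0] + 1
    if zt[0] < series.bin_width / 60.0:
        starts = np.concatenate([[0], starts])
    return starts


def _complete_days(
    series: ActivitySeries, *, lights_state: int | None
) -> list[tuple[int, int]]:
    _require_annotated(series)
    per_day = 1440 // series.bin_width
    stop = series.valid_until
    out: list[tuple[int, int]] = []
    for s in _day_starts(series):
        e = s + per_day
        if e > stop or series.has_gap_in(s, e):
            continue
        if lights_state is not None and series.light[s] != lights_state:
            continue
        out.append((int(s), int(e)))
    return out


def ld_day_slices(series: ActivitySeries) -> list[tuple[int, int]]:
    """(start, stop) index pairs of complete entrained (LD) days.

    A complete day spans exactly 24 h from a ZT0 bin, lies within the
    valid (pre-death) window, contains no dropped-row gap, and has the
    lights actually on at ZT0 (which excludes constant-darkness days).
    """
    return _complete_days(series, lights_state=1)


def dd_day_slices(series: ActivitySeries) -> list[tuple[int, int]]:
    """(start, stop) index pairs of complete constant-darkness days."""
    return _complete_days(series, lights_state=0)


def _zero_runs(x: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of zeros as (start, length) pairs."""
    if len(x) == 0:
        return []
    z = np.concatenate([[0], (x == 0).astype(np.int8), [0]])
    d = np.diff(z)
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    return [(int(s), int(e - s)) for s, e in zip(starts, ends)]


def _phase_at(series: ActivitySeries, idx: int) -> Phase:
    return "day" if series.zt[idx] < 12.0 else "night"


def score_sleep(
    series: ActivitySeries,
    start: int = 0,
    stop: int | None = None,
) -> list[SleepBout]:
    """Score sleep bouts: maximal zero-count runs of >= 5 min.

    Bouts are maximal within ``[start, stop)`` (default: the full valid
    window), so no two bouts are adjacent and extending any bout by one
    bin would include an active bin or leave the window.
    """
    _require_minute_bins(series)
    _require_annotated(series)
    if stop is None:
        stop = series.valid_until
    series.require_gap_free(start, stop)
    bouts = []
    for s, length in _zero_runs(series.counts[start:stop]):
        if length >= MIN_SLEEP_MIN:
            onset = start + s
            bouts.append(
                SleepBout(
                    start_index=onset,
                    length_min=length,
                    phase_of_onset=_phase_at(series, onset),
                )
            )
    return bouts


def sleep_indicator(
    series: ActivitySeries,
    bouts: Sequence[SleepBout] | None = None,
) -> np.ndarray:
    """Per-minute 0/1 sleep state: 1 iff the minute lies in a scored bout.

    The first four minutes of any immobility run are awake by the strict
    5-min rule.
    """
    if bouts is None:
        bouts = score_sleep(series)
    ind = np.zeros(len(series), dtype=np.int8)
    for b in bouts:
        ind[b.start_index : b.start_index + b.length_min] = 1
    return ind


def _phase_mask(series: ActivitySeries, phase: Phase) -> np.ndarray:
    day = series.zt < 12.0
    return day if phase == "day" else ~day


def _runs_per_day_phase(
    series: ActivitySeries,
    runs: list[tuple[int, int]],
    days: list[tuple[int, int]],
    phase: Phase,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-day (episode count, in-phase minutes, mean onset-bout length).

    Episodes are attributed to the day and phase of their onset; minutes
    are split at phase boundaries by overlap with the phase mask.
    """
    mask = _phase_mask(series, phase)
    n_ep = np.zeros(len(days))
    minutes = np.zeros(len(days))
    mean_len = np.full(len(days), np.nan)
    for di, (ds, de) in enumerate(days):
        lens = []
        for rs, rl in runs:
            re = rs + rl
            if re <= ds or rs >= de:
                continue
            # minutes inside this day and phase
            lo, hi = max(rs, ds), min(re, de)
            minutes[di] += int(mask[lo:hi].sum())
            if ds <= rs < de and _phase_at(series, rs) == phase:
                n_ep[di] += 1
                lens.append(rl)
        if lens:
            mean_len[di] = float(np.mean(lens))
    return n_ep, minutes, mean_len


def activity_metrics(
    series: ActivitySeries, phase: Phase
) -> tuple[float, float]:
    """Activity episodes and total active minutes per 12-h phase.

    Activity episodes are maximal runs of bins with count > 0, attributed
    and split across phases with the same onset/overlap convention as
    sleep bouts, then averaged over complete LD days.
    """
    _require_minute_bins(series)
    days = ld_day_slices(series)
    if not days:
        raise ValueError(f"{series.fly_id}: no complete LD day to analyse")
    lo, hi = days[0][0], days[-1][1]
    series.require_gap_free(lo, hi)
    active = (series.counts != 0).astype(np.int8)
    runs = [
        (lo + s, length)
        for s, length in _zero_runs(1 - active[lo:hi])
    ]
    n_ep, minutes, _ = _runs_per_day_phase(series, runs, days, phase)
    return float(n_ep.mean()), float(minutes.mean())


def sleep_latency(
    bouts: Sequence[SleepBout],
    series: ActivitySeries,
    transition: Literal["lights_on", "lights_off"],
) -> tuple[np.ndarray, np.ndarray]:
    """Minutes from each light transition to the first sleep-bout onset.

    For every complete LD day, latency is measured from the transition
    bin to the onset of the first bout starting at-or-after it and
    before the next transition.  Phases with no such bout contribute
    latency 720 min and are flagged censored.

    Returns
    -------
    (latencies, censored) : per-day arrays, minutes and bool flags.
    """
    days = ld_day_slices(series)
    half = 720 // series.bin_width
    onsets = np.array(sorted(b.start_index for b in bouts), dtype=np.int64)
    lat, cens = [], []
    for ds, de in days:
        t = ds if transition == "lights_on" else ds + half
        t_next = t + half
        pos = np.searchsorted(onsets, t, side="left")
        if pos < len(onsets) and onsets[pos] < t_next:
            lat.append(float(onsets[pos] - t) * series.bin_width)
            cens.append(False)
        else:
            lat.append(720.0)
            cens.append(True)
    return np.asarray(lat), np.asarray(cens)


def _transition_prob(
    series: ActivitySeries,
    phase: Phase,
    days: list[tuple[int, int]],
    from_active: bool,
) -> float:
    """Pooled P(state change | current state) over within-phase minute pairs."""
    _require_minute_bins(series)
    mask = _phase_mask(series, phase)
    active = series.counts != 0
    num = 0
    den = 0
    for ds, de in days:
        cur = slice(ds, de - 1)
        nxt = slice(ds + 1, de)
        eligible = mask[cur] & mask[nxt]
        if from_active:
            eligible = eligible & active[cur]
            num += int((eligible & ~active[nxt]).sum())
        else:
            eligible = eligible & ~active[cur]
            num += int((eligible & active[nxt]).sum())
        den += int(eligible.sum())
    if den == 0:
        return math.nan
    return num / den


def p_doze(
    series: ActivitySeries,
    phase: Phase,
    days: list[tuple[int, int]] | None = None,
) -> float:
    """P(Doze): probability an active minute is followed by an inactive one.

    Transition counts are pooled across the analysed days (default: all
    complete LD days) within the phase.  NaN when the fly has no eligible
    active minute in the phase.
    """
    if days is None:
        days = ld_day_slices(series)
    return _transition_prob(series, phase, days, from_active=True)


def p_wake(
    series: ActivitySeries,
    phase: Phase,
    days: list[tuple[int, int]] | None = None,
) -> float:
    """P(Wake): probability an inactive minute is followed by an active one."""
    if days is None:
        days = ld_day_slices(series)
    return _transition_prob(series, phase, days, from_active=False)


def sleep_metrics(series: ActivitySeries) -> dict[Phase, SleepMetrics]:
    """All per-phase sleep metrics for one fly, averaged over complete LD days."""
    _require_minute_bins(series)
    days = ld_day_slices(series)
    if not days:
        raise ValueError(f"{series.fly_id}: no complete LD day to analyse")
    lo, hi = days[0][0], days[-1][1]
    bouts = score_sleep(series, lo, hi)
    runs = [(b.start_index, b.length_min) for b in bouts]
    out: dict[Phase, SleepMetrics] = {}
    for phase in ("day", "night"):
        n_ep, minutes, mean_len = _runs_per_day_phase(series, runs, days, phase)
        transition = "lights_on" if phase == "day" else "lights_off"
        lat, cens = sleep_latency(bouts, series, transition)
        with np.errstate(invalid="ignore"):
            mean_bout = (
                float(np.nanmean(mean_len))
                if not np.all(np.isnan(mean_len))
                else math.nan
            )
            lat_unc = (
                float(lat[~cens].mean()) if (~cens).any() else math.nan
            )
        out[phase] = SleepMetrics(
            fly_id=series.fly_id,
            phase=phase,
            n_episodes=float(n_ep.mean()),
            total_sleep_min=float(minutes.mean()),
            mean_bout_min=mean_bout,
            latency_min=float(lat.mean()),
            latency_uncensored_min=lat_unc,
            n_latency_censored=int(cens.sum()),
            p_doze=p_doze(series, phase, days),
            p_wake=p_wake(series, phase, days),
            n_days_averaged=len(days),
        )
    return out


def _fold_profile(
    series_list: Sequence[ActivitySeries],
    values_fn,
    bin_minutes: int,
    group_label: str | None,
) -> EductionProfile:
    """Mean +/- SEM across flies of day-folded per-ZT-bin sums.

    ``values_fn(series) -> per-minute array`` supplies what is folded
    (raw counts for eduction, the sleep indicator for the time-course).
    Within each fly, days are averaged first; the SEM is across flies.
    """
    if not series_list:
        raise ValueError("eduction requires at least one series")
    if 1440 % bin_minutes:
        raise ValueError("ZT bin width must divide 1440 minutes")
    n_bins = 1440 // bin_minutes
    per_fly = []
    for s in series_list:
        _require_minute_bins(s)
        days = ld_day_slices(s)
        if not days:
            continue
        values = values_fn(s)
        acc = np.zeros(n_bins)
        for ds, de in days:
            idx = np.minimum(
                (s.zt[ds:de] * 60 / bin_minutes).astype(np.int64), n_bins - 1
            )
            np.add.at(acc, idx, values[ds:de])
        per_fly.append(acc / len(days))
    if not per_fly:
        raise ValueError("no series with a complete LD day")
    arr = np.vstack(per_fly)
    mean = arr.mean(axis=0)
    n = arr.shape[0]
    sem = arr.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(n_bins)
    if group_label is None:
        group_label = series_list[0].group_label
    return EductionProfile(
        group_label=group_label,
        bin_zt=np.arange(n_bins) * (bin_minutes / 60.0),
        mean=mean,
        sem=sem,
        n_flies=n,
    )


def eduction(
    series_list: Sequence[ActivitySeries],
    bin_minutes: int = 30,
    group_label: str | None = None,
) -> EductionProfile:
    """Average daily activity profile (counts per ZT bin, mean +/- SEM).

    Recordings are folded at 24 h on the Zeitgeber grid; days are
    averaged within fly, then the mean and SEM are taken across flies.
    """
    return _fold_profile(
        series_list, lambda s: s.counts.astype(float), bin_minutes, group_label
    )


def sleep_timecourse(
    series_list: Sequence[ActivitySeries],
    bin_minutes: int = 30,
    group_label: str | None = None,
) -> EductionProfile:
    """Minutes asleep per ZT bin (mean +/- SEM across flies), in [0, bin]."""
    return _fold_profile(
        series_list,
        lambda s: sleep_indicator(s).astype(float),
        bin_minutes,
        group_label,
    )
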