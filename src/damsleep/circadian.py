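"""Chi-square periodogram rhythm analysis and related circadian measures.

The chi-square periodogram tests a time series for periodicity at each
candidate period P (in bins) by folding the record into K complete
cycles of length P and comparing the variance of the P column means to
the total variance:

    Qp = K * N * sum_h (M_h - Mbar)^2 / sum_i (X_i - Mbar)^2

with N = K*P bins used, M_h the column means and Mbar the grand mean.
Under the null of no periodicity Qp is asymptotically chi-square with
P - 1 degrees of freedom; a perfectly P-periodic series attains the
maximum Qp = N, which anchors the *robustness* statistic Qp/N in [0, 1].

A fly is called rhythmic when the peak Qp clears the chi-square
significance line; *power* is the height of the peak above that line,
and the free-running period is the test period at the peak (reported
only for rhythmic flies).  Morning anticipation in entrained conditions
is scored as the percentage of the activity in the 6 h before lights-on
that falls in the final 3 h.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from damsleep.damio import ActivitySeries
from damsleep.sleep import EductionProfile, dd_day_slices, ld_day_slices

__all__ = [
    "Periodogram",
    "RhythmResult",
    "AnticipationScore",
    "dd_window",
    "chi_square_periodogram",
    "classify_rhythmicity",
    "anticipation_score",
    "anticipation_from_eduction",
    "actogram_matrix",
]


@dataclass
class Periodogram:
    """Qp spectrum over a grid of test periods, with significance line."""

    test_periods: np.ndarray  # hours
    qp: np.ndarray
    df: np.ndarray  # P - 1, in bins
    chi2_line: np.ndarray
    n_bins_used: np.ndarray
    alpha: float
    degenerate: bool = False  # zero-variance input


@dataclass
class RhythmResult:
    """Binary rhythmicity call with period, power and robustness.

    ``period_hours`` is NaN for arrhythmic flies (they are excluded from
    period statistics); power and robustness are reported for every
    non-degenerate fly.
    """

    fly_id: str
    rhythmic: bool
    period_hours: float
    power: float
    robustness: float
    alpha: float
    degenerate: bool = False


@dataclass
class AnticipationScore:
    fly_id: str
    score_percent: float  # NaN if the 6-h window had zero activity
    n_days: int


def dd_window(
    series: ActivitySeries,
    n_days: int = 7,
    skip_hours: float = 24.0,
) -> tuple[int, int]:
    """Free-running analysis window: complete DD days after a settling skip.

    The first ``skip_hours`` after the LD-to-DD transition are skipped to
    avoid transient masking effects, then the first ``n_days`` complete
    DD days are taken.  Raises when fewer are available.
    """
    if series.light is None:
        raise ValueError(f"{series.fly_id}: series must be annotated")
    lit = np.nonzero(series.light[: series.valid_until])[0]
    transition = int(lit[-1]) + 1 if lit.size else 0
    skip = transition + int(round(skip_hours * 60 / series.bin_width))
    days = [d for d in dd_day_slices(series) if d[0] >= skip]
    if len(days) < n_days:
        raise ValueError(
            f"{series.fly_id}: only {len(days)} complete DD days after the "
            f"settling period, need {n_days}"
        )
    start = days[0][0]
    stop = days[n_days - 1][1]
    series.require_gap_free(start, stop)
    return start, stop


def _qp_spectrum(
    values: np.ndarray,
    periods_bins: np.ndarray,
    alpha: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    qp = np.empty(len(periods_bins))
    n_used = np.empty(len(periods_bins), dtype=np.int64)
    for i, p in enumerate(periods_bins):
        k = len(values) // p
        n = k * p
        x = values[:n]
        mbar = x.mean()
        col_means = x.reshape(k, p).mean(axis=0)
        denom = ((x - mbar) ** 2).sum()
        if denom == 0.0:
            qp[i] = math.nan
        else:
            qp[i] = k * n * ((col_means - mbar) ** 2).sum() / denom
        n_used[i] = n
    df = periods_bins - 1
    line = sps.chi2.ppf(1.0 - alpha, df)
    return qp, df.astype(np.int64), line, n_used


def chi_square_periodogram(
    series: ActivitySeries | np.ndarray,
    window: tuple[int, int] | None = None,
    bin_minutes: int = 30,
    period_range_hours: tuple[float, float] = (16.0, 32.0),
    alpha: float = 0.05,
) -> Periodogram:
    """Chi-square periodogram of a gap-free window of activity.

    Parameters
    ----------
    series : annotated series (any bin width dividing ``bin_minutes``)
        or a plain count array already at ``bin_minutes`` resolution.
    window : (start, stop) bin indices into the series; defaults to the
        whole valid window.  Must be gap-free and at least twice the
        longest test period.
    bin_minutes : analysis bin width; the test-period grid advances in
        steps of one bin.
    period_range_hours : inclusive range of candidate periods.
    alpha : significance level for the per-period chi-square line.
    """
    if isinstance(series, ActivitySeries):
        if bin_minutes % series.bin_width:
            raise ValueError(
                f"analysis bin {bin_minutes} min incompatible with "
                f"{series.bin_width}-min data"
            )
        start, stop = window if window is not None else (0, series.valid_until)
        series.require_gap_free(start, stop)
        k = bin_minutes // series.bin_width
        raw = series.counts[start:stop]
        n_new = len(raw) // k
        values = raw[: n_new * k].reshape(n_new, k).sum(axis=1).astype(float)
    else:
        values = np.asarray(series, dtype=float)
        if window is not None:
            values = values[window[0] : window[1]]

    lo = int(math.ceil(period_range_hours[0] * 60 / bin_minutes))
    hi = int(math.floor(period_range_hours[1] * 60 / bin_minutes))
    periods_bins = np.arange(lo, hi + 1)
    if len(values) < 2 * hi:
        raise ValueError(
            f"window of {len(values)} bins is shorter than two cycles of "
            f"the longest test period ({hi} bins)"
        )
    qp, df, line, n_used = _qp_spectrum(values, periods_bins, alpha)
    return Periodogram(
        test_periods=periods_bins * (bin_minutes / 60.0),
        qp=qp,
        df=df,
        chi2_line=line,
        n_bins_used=n_used,
        alpha=alpha,
        degenerate=bool(np.isnan(qp).all()),
    )


def classify_rhythmicity(
    pg: Periodogram,
    fly_id: str = "",
    correct_multiplicity: bool = True,
) -> RhythmResult:
    """Binary rhythmicity call from the periodogram peak.

    The peak is the test period maximising Qp minus the per-period
    chi-square significance line.  By default the binary call compares
    the peak Qp against a *family-wise* threshold (Sidak-corrected over
    the test-period grid at the periodogram's alpha): with ~30 candidate
    periods, an uncorrected per-period test calls the majority of null
    (flat-profile) flies rhythmic, which would make the binary outcome
    uninterpretable.  Set ``correct_multiplicity=False`` for the
    classical uncorrected call.

    Power (peak Qp minus the uncorrected per-period line) and robustness
    (peak Qp / N) are reported for all flies; the period only for
    rhythmic ones.
    """
    if pg.degenerate:
        return RhythmResult(
            fly_id=fly_id,
            rhythmic=False,
            period_hours=math.nan,
            power=math.nan,
            robustness=math.nan,
            alpha=pg.alpha,
            degenerate=True,
        )
    excess = pg.qp - pg.chi2_line
    peak = int(np.nanargmax(excess))
    if correct_multiplicity:
        per_period_alpha = 1.0 - (1.0 - pg.alpha) ** (1.0 / len(pg.test_periods))
        call_line = sps.chi2.ppf(1.0 - per_period_alpha, pg.df[peak])
    else:
        call_line = pg.chi2_line[peak]
    rhythmic = bool(pg.qp[peak] > call_line)
    return RhythmResult(
        fly_id=fly_id,
        rhythmic=rhythmic,
        period_hours=float(pg.test_periods[peak]) if rhythmic else math.nan,
        power=float(excess[peak]),
        robustness=float(pg.qp[peak] / pg.n_bins_used[peak]),
        alpha=pg.alpha,
    )


def anticipation_score(
    series: ActivitySeries,
    window_total_hours: float = 6.0,
    window_late_hours: float = 3.0,
) -> AnticipationScore:
    """Morning-anticipation phase score for one fly in entrained days.

    100 times the fraction of the activity in the ``window_total_hours``
    before lights-on that occurred in the final ``window_late_hours``,
    counts summed over all complete LD days.  NaN (flagged) when the
    fly produced no counts in the full window.
    """
    days = ld_day_slices(series)
    if not days:
        raise ValueError(f"{series.fly_id}: no complete LD day to analyse")
    total = 0.0
    late = 0.0
    for ds, de in days:
        zt = series.zt[ds:de]
        c = series.counts[ds:de]
        in_total = zt >= 24.0 - window_total_hours
        in_late = zt >= 24.0 - window_late_hours
        total += float(c[in_total].sum())
        late += float(c[in_late].sum())
    score = 100.0 * late / total if total > 0 else math.nan
    return AnticipationScore(
        fly_id=series.fly_id, score_percent=score, n_days=len(days)
    )


def anticipation_from_eduction(
    profile: EductionProfile,
    window_total_hours: float = 6.0,
    window_late_hours: float = 3.0,
) -> float:
    """Group-level anticipation score computed from an eduction profile."""
    zt = profile.bin_zt
    in_total = zt >= 24.0 - window_total_hours
    in_late = zt >= 24.0 - window_late_hours
    total = float(profile.mean[in_total].sum())
    late = float(profile.mean[in_late].sum())
    return 100.0 * late / total if total > 0 else math.nan


def actogram_matrix(
    series: ActivitySeries,
    bin_minutes: int = 10,
    double_plot: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Day-by-day activity raster for actogram plotting.

    Rows are consecutive complete ZT days.  With ``double_plot`` each
    row concatenates day *d* and day *d+1* (576 bins at 10-min
    resolution; the right half of the last row is zero-padded), which
    makes phase drift across midnight visually continuous.

    Returns
    -------
    (matrix, light_mask) : float and int8 arrays of identical shape;
    the mask is 1 where the schedule had lights on.
    """
    if series.zt is None or series.light is None:
        raise ValueError(f"{series.fly_id}: series must be annotated")
    if bin_minutes % series.bin_width or 1440 % bin_minutes:
        raise ValueError("actogram bin must divide 24 h and be a multiple "
                         "of the data bin width")
    k = bin_minutes // series.bin_width
    per_day = 1440 // bin_minutes
    starts = np.nonzero(np.diff(series.zt) < 0)[0] + 1
    if series.zt[0] < series.bin_width / 60.0:
        starts = np.concatenate([[0], starts])
    day_rows = []
    light_rows = []
    n_day_bins = per_day * k
    for s in starts:
        e = s + n_day_bins
        if e > series.valid_until or series.has_gap_in(int(s), int(e)):
            continue
        day_rows.append(
            series.counts[s:e].reshape(per_day, k).sum(axis=1).astype(float)
        )
        light_rows.append(series.light[s:e:k].astype(np.int8))
    if not day_rows:
        raise ValueError(f"{series.fly_id}: no complete day for actogram")
    act = np.vstack(day_rows)
    lig = np.vstack(light_rows)
    if not double_plot:
        return act, lig
    n = act.shape[0]
    right_act = np.vstack([act[1:], np.zeros((1, per_day))])
    right_lig = np.vstack([lig[1:], np.zeros((1, per_day), dtype=np.int8)])
    return np.hstack([act, right_act]), np.hstack([lig, right_lig])
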