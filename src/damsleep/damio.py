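"""Reading, writing and annotating TriKinetics DAM monitor recordings.

The on-disk dialect is the tab-delimited text emitted by DAMSystem
software: one row per reading with a running index, date (``"1 Jan 24"``),
time (``"HH:MM:SS"``), a status code (1 = valid), five unused metadata
fields, a light-sensor field, and 32 channel counts.  Rows whose status
code is not 1 are dropped and the resulting hole in the timeline is
recorded as an explicit :class:`Gap`; downstream analyses that assume a
contiguous timeline refuse windows that contain a gap rather than
silently imputing counts.

Light annotation always comes from the configured :class:`LightSchedule`,
never from the monitor's light sensor (kept as advisory metadata only):
in constant darkness the Zeitgeber clock must keep running on the
entrained phase, which only a schedule can provide.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

N_CHANNELS = 32
#: column layout: index, date, time, status, 5 unused, light sensor, 32 counts
_N_FIELDS = 10 + N_CHANNELS

__all__ = [
    "ActivitySeries",
    "LightSchedule",
    "Gap",
    "GapError",
    "read_dam_file",
    "write_dam_file",
    "rebin",
    "annotate_photoperiod",
    "detect_death",
    "series_to_frame",
]


class GapError(ValueError):
    """An analysis window intersects a dropped-row gap in the recording."""


@dataclass(frozen=True)
class Gap:
    """A hole in the timeline left by dropped (bad-status) rows.

    ``index`` is the position in the compacted ``counts`` array *before*
    which the missing bins would sit; ``n_bins`` is how many bins are
    missing; ``start`` is the timestamp of the first missing bin.
    """

    index: int
    n_bins: int
    start: _dt.datetime


@dataclass
class LightSchedule:
    """An entraining light schedule: LD cycles optionally followed by DD.

    Parameters
    ----------
    lights_on : datetime.time
        Clock time of lights-on; defines ZT0.
    photoperiod_hours : float
        Duration of the light phase (12 for the standard 12:12 cycle).
    dd_start : datetime.datetime, optional
        Instant after which lights stay off (release into constant
        darkness).  ZT continues to advance on the entrained phase.
    """

    lights_on: _dt.time = _dt.time(8, 0)
    photoperiod_hours: float = 12.0
    dd_start: _dt.datetime | None = None

    def __post_init__(self) -> None:
        if not 0 < self.photoperiod_hours < 24:
            raise ValueError("photoperiod_hours must lie in (0, 24)")

    def zt_hours(self, when: _dt.datetime | np.ndarray) -> np.ndarray:
        """Zeitgeber time in hours, ZT0 = lights-on, for one or many instants."""
        t = np.asarray(when, dtype="datetime64[s]")
        day_anchor = t.astype("datetime64[D]").astype("datetime64[s]")
        secs_of_day = (t - day_anchor) / np.timedelta64(1, "s")
        on = (
            self.lights_on.hour * 3600
            + self.lights_on.minute * 60
            + self.lights_on.second
        )
        return ((secs_of_day - on) / 3600.0) % 24.0

    def lights_on_state(self, when: _dt.datetime | np.ndarray) -> np.ndarray:
        """1 where lights are on, 0 otherwise (always 0 after ``dd_start``)."""
        t = np.asarray(when, dtype="datetime64[s]")
        lit = self.zt_hours(t) < self.photoperiod_hours
        if self.dd_start is not None:
            lit &= t < np.datetime64(self.dd_start, "s")
        return lit.astype(np.int8)


@dataclass
class ActivitySeries:
    """One fly's binned beam-crossing counts with light/ZT annotation.

    Bins follow the half-open convention ``[t, t + bin_width)``.  In a
    gap-free series the timestamp of bin *i* is ``t0 + i * bin_width``;
    dropped rows are recorded in ``gaps`` and shift later timestamps.
    ``valid_until`` is the index one past the last analysable bin (set by
    :func:`detect_death`); analyses never read beyond it.
    """

    fly_id: str
    monitor_id: str
    channel: int
    group_label: str
    bin_width: int  # minutes
    t0: _dt.datetime
    counts: np.ndarray
    light: np.ndarray | None = None
    zt: np.ndarray | None = None
    valid_until: int | None = None
    dead: bool = False
    gaps: list[Gap] = field(default_factory=list)
    light_sensor: np.ndarray | None = None  # advisory only

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if not 1 <= self.channel <= N_CHANNELS:
            raise ValueError(f"channel must be 1..{N_CHANNELS}, got {self.channel}")
        if self.valid_until is None:
            self.valid_until = len(self.counts)

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def times(self) -> np.ndarray:
        """Per-bin start timestamps (datetime64[s]), honouring gaps."""
        step = np.timedelta64(self.bin_width * 60, "s")
        offsets = np.arange(len(self.counts), dtype=np.int64)
        for gap in self.gaps:
            offsets[gap.index :] += gap.n_bins
        return np.datetime64(self.t0, "s") + offsets * step

    def has_gap_in(self, start: int, stop: int) -> bool:
        """True if a dropped-row gap falls strictly inside ``[start, stop)``."""
        return any(start < g.index < stop for g in self.gaps)

    def require_gap_free(self, start: int, stop: int) -> None:
        if self.has_gap_in(start, stop):
            raise GapError(
                f"{self.fly_id}: analysis window [{start}, {stop}) intersects "
                "a dropped-row gap"
            )


def _parse_timestamp(date_s: str, time_s: str, lineno: int) -> _dt.datetime:
    try:
        d = _dt.datetime.strptime(date_s.strip(), "%d %b %y").date()
        t = _dt.time.fromisoformat(time_s.strip())
    except ValueError as exc:
        raise ValueError(f"unparseable date/time on line {lineno}: {exc}") from exc
    return _dt.datetime.combine(d, t)


def read_dam_file(
    path: str | Path,
    channel_map: dict[int, str],
    *,
    monitor_id: str | None = None,
) -> list[ActivitySeries]:
    """Read a TriKinetics monitor file into per-channel activity series.

    Parameters
    ----------
    path : path to a tab-delimited DAM monitor text file.
    channel_map : mapping from channel number (1-32) to group label.
        Channels absent from the map are skipped with a warning.
    monitor_id : identifier for the monitor; defaults to the file stem.

    Returns
    -------
    list of :class:`ActivitySeries`, one per mapped channel, in channel
    order.  Rows with status code != 1 are dropped and reported as gaps.

    Raises
    ------
    ValueError
        On an unparseable timestamp (with line number) or non-monotone
        timestamps.
    """
    path = Path(path)
    if monitor_id is None:
        monitor_id = path.stem

    stamps: list[_dt.datetime] = []
    sensor: list[int] = []
    rows: list[list[int]] = []
    dropped: list[_dt.datetime] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < _N_FIELDS:
                raise ValueError(
                    f"{path}: line {lineno} has {len(fields)} fields, "
                    f"expected {_N_FIELDS}"
                )
            when = _parse_timestamp(fields[1], fields[2], lineno)
            try:
                status = int(fields[3])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: bad status code on line {lineno}"
                ) from exc
            if status != 1:
                dropped.append(when)
                continue
            stamps.append(when)
            sensor.append(int(fields[9]))
            rows.append([int(v) for v in fields[10 : 10 + N_CHANNELS]])
    if not rows:
        raise ValueError(f"{path}: no valid data rows")

    times = np.array(stamps, dtype="datetime64[s]")
    # infer bin width from the full timeline, dropped rows included,
    # so a gap next to a dropped row cannot masquerade as a wider bin
    all_times = np.sort(
        np.concatenate([times, np.array(dropped, dtype="datetime64[s]")])
    ) if dropped else times
    if len(times) > 1:
        deltas = np.diff(times) / np.timedelta64(60, "s")
        if (deltas <= 0).any():
            bad = int(np.argmax(deltas <= 0))
            raise ValueError(
                f"{path}: non-monotone timestamps near row {bad + 2}"
            )
        all_deltas = np.diff(all_times) / np.timedelta64(60, "s")
        bin_width = int(all_deltas[all_deltas > 0].min())
        if bin_width < 1:
            raise ValueError(f"{path}: sub-minute bin width unsupported")
        # gaps: consecutive valid rows further apart than one bin
        gaps: list[Gap] = []
        step = np.timedelta64(bin_width * 60, "s")
        for i in np.nonzero(deltas != bin_width)[0]:
            missing = int(round(deltas[i] / bin_width)) - 1
            gaps.append(
                Gap(
                    index=int(i) + 1,
                    n_bins=missing,
                    start=(times[i] + step).astype(_dt.datetime),
                )
            )
    else:
        bin_width = 1
        gaps = []
    if dropped:
        logger.warning(
            "%s: dropped %d bad-status row(s); %d gap(s) in timeline",
            path,
            len(dropped),
            len(gaps),
        )

    counts = np.asarray(rows, dtype=np.int64)  # (n_bins, 32)
    sensor_arr = np.asarray(sensor, dtype=np.int64)
    out: list[ActivitySeries] = []
    for ch in range(1, N_CHANNELS + 1):
        if ch not in channel_map:
            continue
        out.append(
            ActivitySeries(
                fly_id=f"{monitor_id}#{ch:02d}",
                monitor_id=monitor_id,
                channel=ch,
                group_label=channel_map[ch],
                bin_width=bin_width,
                t0=times[0].astype(_dt.datetime),
                counts=counts[:, ch - 1],
                gaps=list(gaps),
                light_sensor=sensor_arr,
            )
        )
    unmapped = sorted(set(range(1, N_CHANNELS + 1)) - set(channel_map))
    if unmapped:
        logger.warning("%s: skipping unmapped channels %s", path, unmapped)
    return out


def write_dam_file(
    series: Sequence[ActivitySeries],
    path: str | Path,
) -> None:
    """Write activity series as a TriKinetics monitor file.

    All series must share ``t0``, ``bin_width`` and length (one monitor,
    one timeline).  Channels not present among ``series`` are written as
    zero columns.  The light-sensor field is taken from the first series'
    ``light`` annotation when available, else 0.
    """
    if not series:
        raise ValueError("cannot write an empty series list")
    first = series[0]
    for s in series[1:]:
        if (
            s.t0 != first.t0
            or s.bin_width != first.bin_width
            or len(s) != len(first)
        ):
            raise ValueError(
                f"series {s.fly_id} does not share the monitor timeline"
            )
    seen: dict[int, ActivitySeries] = {}
    for s in series:
        if s.channel in seen:
            raise ValueError(f"duplicate channel {s.channel}")
        seen[s.channel] = s

    n = len(first)
    cols = np.zeros((n, N_CHANNELS), dtype=np.int64)
    for ch, s in seen.items():
        cols[:, ch - 1] = s.counts
    sensor = (
        first.light
        if first.light is not None
        else np.zeros(n, dtype=np.int64)
    )
    times = first.times
    with open(path, "w") as fh:
        for i in range(n):
            when = times[i].astype(_dt.datetime)
            fields = [
                str(i + 1),
                when.strftime("%-d %b %y"),
                when.strftime("%H:%M:%S"),
                "1",
                "1", "0", "0", "0", "0",  # unused metadata
                str(int(sensor[i])),
            ] + [str(int(v)) for v in cols[i]]
            fh.write("\t".join(fields) + "\n")


def rebin(series: ActivitySeries, target_bin: int) -> ActivitySeries:
    """Sum counts into coarser bins of ``target_bin`` minutes.

    ``target_bin`` must be a positive integer multiple of the current bin
    width.  A trailing incomplete bin is dropped.  The light flag and ZT
    of a new bin are those at its start.
    """
    if target_bin <= 0 or target_bin % series.bin_width:
        raise ValueError(
            f"target bin {target_bin} min is not a multiple of "
            f"{series.bin_width} min"
        )
    k = target_bin // series.bin_width
    if k == 1:
        return replace(series)
    if series.gaps:
        raise GapError(f"{series.fly_id}: cannot rebin across gaps")
    n_new = len(series) // k
    counts = series.counts[: n_new * k].reshape(n_new, k).sum(axis=1)
    light = series.light[: n_new * k : k] if series.light is not None else None
    zt = series.zt[: n_new * k : k] if series.zt is not None else None
    sens = (
        series.light_sensor[: n_new * k : k]
        if series.light_sensor is not None
        else None
    )
    return replace(
        series,
        bin_width=target_bin,
        counts=counts,
        light=light,
        zt=zt,
        light_sensor=sens,
        valid_until=series.valid_until // k,
        gaps=[],
    )


def annotate_photoperiod(
    series: ActivitySeries, schedule: LightSchedule
) -> ActivitySeries:
    """Populate per-bin ``light`` and ``zt`` fields from a schedule.

    After ``schedule.dd_start`` the light flag is 0 everywhere while ZT
    keeps advancing on the entrained phase, so day/night attribution
    remains defined in constant darkness.
    """
    times = series.times
    return replace(
        series,
        zt=schedule.zt_hours(times),
        light=schedule.lights_on_state(times),
    )


def detect_death(series: ActivitySeries, lookback_hours: float = 24.0) -> int:
    """Algorithmic death call from the terminal zero-activity run.

    Returns the index one past the last bin of the final nonzero count
    when the terminal run of zero-count bins lasts at least
    ``lookback_hours``; otherwise returns the full series length.  A fly
    whose series ends in activity is never truncated.  The caller decides
    whether truncated flies are excluded outright (the default policy in
    :mod:`damsleep.pipeline`).
    """
    n = len(series)
    nz = np.nonzero(series.counts)[0]
    last_active = int(nz[-1]) + 1 if nz.size else 0
    run_bins = n - last_active
    threshold = lookback_hours * 60.0 / series.bin_width
    if run_bins >= threshold:
        return last_active
    return n


def series_to_frame(series_list: Sequence[ActivitySeries]):
    """Tidy per-fly long table: fly_id, group, time, zt, light, counts."""
    import pandas as pd

    frames = []
    for s in series_list:
        frames.append(
            pd.DataFrame(
                {
                    "fly_id": s.fly_id,
                    "group": s.group_label,
                    "time": s.times,
                    "zt": s.zt if s.zt is not None else np.nan,
                    "light": s.light if s.light is not None else -1,
                    "counts": s.counts,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
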