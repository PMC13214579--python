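"""Generative two-state Markov model of fly locomotor activity.

Virtual flies alternate between an active and an inactive state at
1-min resolution: an active minute is followed by an inactive one with
probability ``p_doze(ZT)`` and an inactive minute by an active one with
probability ``p_wake(ZT)``.  Because these are exactly the transition
probabilities that the P(Doze)/P(Wake) estimators measure, analysing a
simulated fly is a direct parameter-recovery exercise rather than an
approximation.

Transition probabilities and the Poisson beam-cross intensity are
modulated on the fly's *endogenous* clock, which advances at 24/tau
hours of subjective time per hour of real time; in entrained conditions
(tau = 24 and aligned phase) the endogenous and Zeitgeber clocks
coincide, while in constant darkness the activity rhythm free-runs at
tau.  Arrhythmic flies carry flat profiles (no modulation), giving an
unambiguous ground truth for the binary rhythmicity call.  An active
minute emits at least one beam crossing (zero-truncated Poisson) so the
observed active/inactive state equals the latent Markov state.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from damsleep.damio import (
    ActivitySeries,
    LightSchedule,
    annotate_photoperiod,
    write_dam_file,
)

__all__ = [
    "GroupSpec",
    "SimScenario",
    "simulate_fly",
    "simulate_population",
    "simulate_monitor",
    "scenario_c9ftd_study",
]

FLIES_PER_HALF = 16  # one genotype per monitor half, as in DAM practice


@dataclass
class GroupSpec:
    """Generative parameters for one genotype x age group.

    Sleep-state profiles are cosine-modulated around a mesor:
    ``p_doze(zt) = mesor + amp * cos(2*pi*(zt - peak)/24)`` (clipped to
    [0, 1]), and likewise for ``p_wake``.  The beam-cross intensity is a
    baseline plus Gaussian morning and evening activity peaks, with a
    multiplicative night elevation knob.  ``fragmentation_multiplier``
    scales p_wake during subjective night (sleep fragmentation);
    ``arrhythmic_fraction`` of flies get flat profiles at the mesor
    levels.  ``death_hazard`` is the daily probability of dying.
    """

    label: str
    tau_hours: float = 24.0
    p_doze_mesor: float = 0.225
    p_doze_amp: float = 0.075
    p_doze_peak_zt: float = 18.0
    p_wake_mesor: float = 0.105
    p_wake_amp: float = 0.045
    p_wake_peak_zt: float = 6.0
    lambda_base: float = 1.5
    morning_peak_height: float = 4.0
    morning_peak_zt: float = 0.5
    evening_peak_height: float = 5.0
    evening_peak_zt: float = 11.5
    peak_width_hours: float = 1.5
    startle_boost: float = 6.0
    night_activity_multiplier: float = 1.0
    fragmentation_multiplier: float = 1.0
    arrhythmic_fraction: float = 0.0
    death_hazard: float = 0.0

    def __post_init__(self) -> None:
        for name in ("p_doze_mesor", "p_wake_mesor", "arrhythmic_fraction",
                     "death_hazard"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.lambda_base < 0:
            raise ValueError("lambda_base must be >= 0")
        if self.tau_hours <= 0:
            raise ValueError("tau_hours must be positive")

    def p_doze_at(self, zt: np.ndarray, flat: bool = False) -> np.ndarray:
        if flat:
            return np.full_like(zt, self.p_doze_mesor, dtype=float)
        prof = self.p_doze_mesor + self.p_doze_amp * np.cos(
            2 * np.pi * (zt - self.p_doze_peak_zt) / 24.0
        )
        return np.clip(prof, 0.0, 1.0)

    def p_wake_at(self, zt: np.ndarray, flat: bool = False) -> np.ndarray:
        if flat:
            prof = np.full_like(zt, self.p_wake_mesor, dtype=float)
        else:
            prof = self.p_wake_mesor + self.p_wake_amp * np.cos(
                2 * np.pi * (zt - self.p_wake_peak_zt) / 24.0
            )
            night = (zt % 24.0) >= 12.0
            prof = np.where(night, prof * self.fragmentation_multiplier, prof)
        return np.clip(prof, 0.0, 1.0)

    def lambda_at(self, zt: np.ndarray, flat: bool = False) -> np.ndarray:
        if flat:
            return np.full_like(zt, self.lambda_base, dtype=float)
        z = zt % 24.0

        def bump(center: float, height: float) -> np.ndarray:
            # circular distance so peaks near ZT0 wrap cleanly
            dz = np.minimum(np.abs(z - center), 24.0 - np.abs(z - center))
            return height * np.exp(-0.5 * (dz / self.peak_width_hours) ** 2)

        lam = (
            self.lambda_base
            + bump(self.morning_peak_zt, self.morning_peak_height)
            + bump(self.evening_peak_zt, self.evening_peak_height)
        )
        night = z >= 12.0
        return np.where(night, lam * self.night_activity_multiplier, lam)


@dataclass
class SimScenario:
    """A reproducible virtual experiment: groups, schedule and durations."""

    seed: int
    groups: list[GroupSpec]
    n_flies: int = 32  # per group
    days_ld: int = 5
    days_dd: int = 8
    lights_on: _dt.time = _dt.time(8, 0)
    start_date: _dt.date = _dt.date(2024, 1, 1)

    @property
    def t0(self) -> _dt.datetime:
        return _dt.datetime.combine(self.start_date, self.lights_on)

    @property
    def schedule(self) -> LightSchedule:
        return LightSchedule(
            lights_on=self.lights_on,
            photoperiod_hours=12.0,
            dd_start=self.t0 + _dt.timedelta(days=self.days_ld),
        )

    @property
    def n_days(self) -> int:
        return self.days_ld + self.days_dd


def _fly_rng(master_seed: int, monitor: int, channel: int) -> np.random.Generator:
    """Per-fly generator from a stable (master, monitor, channel) derivation."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(monitor, channel))
    return np.random.default_rng(ss)


def _ztp_poisson(rng: np.random.Generator, lam: np.ndarray) -> np.ndarray:
    """Zero-truncated Poisson draws (elementwise), floor-at-one variant."""
    return np.maximum(rng.poisson(lam), 1)


def simulate_fly(
    spec: GroupSpec,
    schedule: LightSchedule,
    days: int,
    seed: int | np.random.Generator,
    *,
    t0: _dt.datetime | None = None,
    arrhythmic: bool | None = None,
    fly_id: str = "sim#01",
    monitor_id: str = "sim",
    channel: int = 1,
) -> ActivitySeries:
    """Simulate one fly's 1-min activity series over ``days`` days.

    ``arrhythmic`` forces flat (or modulated) profiles; when None it is
    drawn from ``spec.arrhythmic_fraction``.  The series starts at the
    schedule's lights-on (or ``t0``) and is returned fully annotated.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if t0 is None:
        t0 = _dt.datetime.combine(_dt.date(2024, 1, 1), schedule.lights_on)
    n = days * 1440
    if arrhythmic is None:
        arrhythmic = bool(rng.random() < spec.arrhythmic_fraction)

    minutes = np.arange(n)
    times = np.datetime64(t0, "s") + minutes * np.timedelta64(60, "s")
    zt_sched = schedule.zt_hours(times)
    light = schedule.lights_on_state(times)
    in_dd = (
        times >= np.datetime64(schedule.dd_start, "s")
        if schedule.dd_start is not None
        else np.zeros(n, dtype=bool)
    )
    # endogenous clock: tracks the entrained clock until DD release, then
    # free-runs at tau (phase continuous at the transition)
    hours = minutes / 60.0
    if schedule.dd_start is not None:
        dd_h = (np.datetime64(schedule.dd_start, "s") - times[0]) / np.timedelta64(
            1, "h"
        )
    else:
        dd_h = float(n)  # never released
    zt0 = zt_sched[0]
    zt_endog = np.where(
        hours < dd_h,
        (zt0 + hours) % 24.0,
        (zt0 + dd_h + (hours - dd_h) * 24.0 / spec.tau_hours) % 24.0,
    )

    pd_prof = spec.p_doze_at(zt_endog, flat=arrhythmic)
    pw_prof = spec.p_wake_at(zt_endog, flat=arrhythmic)
    lam = spec.lambda_at(zt_endog, flat=arrhythmic)

    # light-transition startle: forced activity burst at lights on/off
    if not arrhythmic and spec.startle_boost > 0:
        trans = np.zeros(n, dtype=bool)
        trans[1:] = light[1:] != light[:-1]
        trans &= ~in_dd
        lam = np.where(trans, lam + spec.startle_boost, lam)
    else:
        trans = np.zeros(n, dtype=bool)

    u = rng.random(n)
    p0 = spec.p_wake_at(np.array([zt_endog[0]]), flat=arrhythmic)[0] / max(
        spec.p_doze_at(np.array([zt_endog[0]]), flat=arrhythmic)[0]
        + spec.p_wake_at(np.array([zt_endog[0]]), flat=arrhythmic)[0],
        1e-12,
    )
    active = np.empty(n, dtype=bool)
    state = bool(rng.random() < p0)
    for i in range(n):
        if trans[i]:
            state = True
        active[i] = state
        if state:
            state = not (u[i] < pd_prof[i])
        else:
            state = u[i] < pw_prof[i]

    counts = np.zeros(n, dtype=np.int64)
    counts[active] = _ztp_poisson(rng, lam[active])

    death_day = None
    if spec.death_hazard > 0:
        draws = rng.random(days)
        dead_days = np.nonzero(draws < spec.death_hazard)[0]
        if dead_days.size:
            death_day = int(dead_days[0])
            death_minute = death_day * 1440 + int(rng.integers(0, 1440))
            counts[death_minute:] = 0

    series = ActivitySeries(
        fly_id=fly_id,
        monitor_id=monitor_id,
        channel=channel,
        group_label=spec.label,
        bin_width=1,
        t0=t0,
        counts=counts,
    )
    series = annotate_photoperiod(series, schedule)
    series.death_day = death_day  # truth annotation, not part of the format
    series.true_arrhythmic = arrhythmic
    return series


def simulate_population(
    scenario: SimScenario,
) -> tuple[list[ActivitySeries], pd.DataFrame]:
    """Simulate every fly of a scenario, in monitor/channel layout.

    Groups are paired onto monitors: each monitor holds 16 flies of one
    group on channels 1-16 and 16 of the next group on channels 17-32.

    Returns the annotated series plus a ground-truth table (one row per
    fly: group, tau, arrhythmic flag, death day).
    """
    if scenario.n_flies > 2 * FLIES_PER_HALF * 1000:
        raise ValueError("implausible group size")
    series: list[ActivitySeries] = []
    truth_rows = []
    n_monitors_per_pair = -(-scenario.n_flies // FLIES_PER_HALF)
    pairs = [
        scenario.groups[i : i + 2] for i in range(0, len(scenario.groups), 2)
    ]
    monitor_index = 0
    for pair in pairs:
        for j in range(n_monitors_per_pair):
            monitor_index += 1
            monitor_id = f"Monitor{monitor_index:02d}"
            for half, spec in enumerate(pair):
                lo = j * FLIES_PER_HALF
                hi = min(lo + FLIES_PER_HALF, scenario.n_flies)
                for k in range(hi - lo):
                    channel = half * FLIES_PER_HALF + k + 1
                    rng = _fly_rng(scenario.seed, monitor_index, channel)
                    s = simulate_fly(
                        spec,
                        scenario.schedule,
                        scenario.n_days,
                        rng,
                        t0=scenario.t0,
                        fly_id=f"{monitor_id}#{channel:02d}",
                        monitor_id=monitor_id,
                        channel=channel,
                    )
                    series.append(s)
                    truth_rows.append(
                        {
                            "fly_id": s.fly_id,
                            "monitor_id": monitor_id,
                            "channel": channel,
                            "group": spec.label,
                            "tau_hours": spec.tau_hours,
                            "arrhythmic": s.true_arrhythmic,
                            "death_day": s.death_day,
                            "p_doze_mesor": spec.p_doze_mesor,
                            "p_wake_mesor": spec.p_wake_mesor,
                        }
                    )
    return series, pd.DataFrame(truth_rows)


def simulate_monitor(
    scenario: SimScenario, out_dir: str | Path
) -> tuple[list[Path], pd.DataFrame]:
    """Write a scenario as TriKinetics monitor files plus a truth table.

    One tab-delimited monitor file per 32-channel monitor, a
    ``truth.csv`` with per-fly generating parameters, and the channel
    map implied by the layout are written into ``out_dir``.  Re-running
    with the same scenario reproduces the files byte-identically.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    series, truth = simulate_population(scenario)
    paths = []
    by_monitor: dict[str, list[ActivitySeries]] = {}
    for s in series:
        by_monitor.setdefault(s.monitor_id, []).append(s)
    for monitor_id, group in sorted(by_monitor.items()):
        if len(group) > 32:
            raise ValueError(f"{monitor_id}: more than 32 flies on one monitor")
        path = out_dir / f"{monitor_id}.txt"
        write_dam_file(group, path)
        paths.append(path)
    truth.to_csv(out_dir / "truth.csv", index=False)
    return paths, truth


def scenario_c9ftd_study(
    seed: int = 0,
    n_flies: int = 32,
    days_ld: int = 5,
    days_dd: int = 8,
) -> SimScenario:
    """Four-group scenario mirroring a C9orf72-FTD fly study design.

    Control and pathogenic genotypes at young and old ages, with the
    pathogenic effect directions: elevated night activity, fragmented
    night sleep (raised night P(Wake)), sleep pressure (P(Doze)) falling
    with age, and a much larger arrhythmic fraction in constant darkness
    (about 30% versus about 7% in controls).
    """
    control_young = GroupSpec(
        label="control_young",
        tau_hours=23.8,
        arrhythmic_fraction=0.07,
    )
    pathogenic_young = GroupSpec(
        label="pathogenic_young",
        tau_hours=23.9,
        arrhythmic_fraction=0.30,
        night_activity_multiplier=1.8,
        fragmentation_multiplier=1.6,
    )
    control_old = GroupSpec(
        label="control_old",
        tau_hours=24.0,
        arrhythmic_fraction=0.07,
        morning_peak_height=3.0,
        evening_peak_height=3.5,
    )
    pathogenic_old = GroupSpec(
        label="pathogenic_old",
        tau_hours=24.5,
        arrhythmic_fraction=0.33,
        night_activity_multiplier=1.8,
        fragmentation_multiplier=1.5,
        p_doze_mesor=0.14,  # reduced sleep pressure with age
        p_doze_amp=0.05,
        morning_peak_height=3.0,
        evening_peak_height=3.5,
    )
    return SimScenario(
        seed=seed,
        groups=[control_young, pathogenic_young, control_old, pathogenic_old],
        n_flies=n_flies,
        days_ld=days_ld,
        days_dd=days_dd,
    )
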