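"""End-to-end orchestration: monitor files (or a scenario) to result tables.

One run produces one self-documenting output directory containing tidy
CSV tables shaped like the standard figures of a DAM sleep/circadian
study — per-fly sleep and activity metrics split by day/night phase,
group eduction and sleep time-course profiles, per-fly rhythm calls with
a rhythm summary table (n rhythmic / arrhythmic, % rhythmic, period /
power / robustness means with SEM), anticipation scores, factorial and
repeated-measures test tables — plus the resolved configuration and an
exclusion log.  Dead flies (terminal zero-activity run) are excluded
from every summary outright.

Group labels of the form ``<genotype>_<age>`` (e.g. ``pathogenic_old``)
are parsed into the two between-fly factors for the statistics layer.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from damsleep import circadian, damio, sleep, stats
from damsleep.damio import ActivitySeries, LightSchedule
from damsleep.synthetic import SimScenario, simulate_population

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "load_config", "run_analysis", "make_report"]


@dataclass
class RunConfig:
    """Resolved configuration of one analysis run."""

    out_dir: Path
    scenario: SimScenario | None = None
    monitor_files: dict[str, dict[int, str]] = field(default_factory=dict)
    lights_on: _dt.time = _dt.time(8, 0)
    photoperiod_hours: float = 12.0
    dd_start: _dt.datetime | None = None
    death_lookback_hours: float = 24.0
    dd_days: int = 7
    dd_skip_hours: float = 24.0
    eduction_bin_min: int = 30
    actogram_bin_min: int = 10
    periodogram_bin_min: int = 30
    period_range_hours: tuple[float, float] = (16.0, 32.0)
    alpha: float = 0.05
    seed: int = 0

    @property
    def schedule(self) -> LightSchedule:
        if self.scenario is not None:
            return self.scenario.schedule
        return LightSchedule(
            lights_on=self.lights_on,
            photoperiod_hours=self.photoperiod_hours,
            dd_start=self.dd_start,
        )


def load_config(path: str | Path, out_dir: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML file describing monitors and schedule.

    Expected keys: ``monitors`` (file -> {channel: group}), ``lights_on``
    ("HH:MM"), ``photoperiod_hours``, ``dd_start`` (ISO datetime or
    null), and optional analysis knobs matching RunConfig field names.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    monitors = {
        str(fname): {int(ch): str(lbl) for ch, lbl in cmap.items()}
        for fname, cmap in raw.get("monitors", {}).items()
    }
    kwargs: dict = {}
    for key in (
        "death_lookback_hours", "dd_days", "dd_skip_hours",
        "eduction_bin_min", "actogram_bin_min", "periodogram_bin_min",
        "alpha", "seed", "photoperiod_hours",
    ):
        if key in raw:
            kwargs[key] = raw[key]
    if "lights_on" in raw:
        kwargs["lights_on"] = _dt.time.fromisoformat(str(raw["lights_on"]))
    if raw.get("dd_start"):
        kwargs["dd_start"] = _dt.datetime.fromisoformat(str(raw["dd_start"]))
    return RunConfig(out_dir=Path(out_dir), monitor_files=monitors, **kwargs)


def _split_group(label: str) -> tuple[str, str]:
    """``control_young`` -> (``control``, ``young``); fallback to (label, 'all')."""
    if "_" in label:
        genotype, age = label.rsplit("_", 1)
        return genotype, age
    return label, "all"


def _acquire_series(config: RunConfig, base_dir: Path | None) -> list[ActivitySeries]:
    if config.scenario is not None:
        series, _ = simulate_population(config.scenario)
        return series
    if not config.monitor_files:
        raise ValueError("config names neither a scenario nor monitor files")
    out = []
    for fname, cmap in config.monitor_files.items():
        path = Path(fname)
        if base_dir is not None and not path.is_absolute():
            path = base_dir / path
        for s in damio.read_dam_file(path, cmap):
            out.append(damio.annotate_photoperiod(s, config.schedule))
    return out


def _exclude_dead(
    series: list[ActivitySeries], lookback_hours: float
) -> tuple[list[ActivitySeries], pd.DataFrame]:
    alive, rows = [], []
    for s in series:
        idx = damio.detect_death(s, lookback_hours)
        dead = idx < len(s)
        rows.append(
            {"fly_id": s.fly_id, "group": s.group_label, "dead": dead,
             "valid_until": idx}
        )
        if dead:
            logger.info("excluding dead fly %s (valid to bin %d)", s.fly_id, idx)
        else:
            alive.append(s)
    return alive, pd.DataFrame(rows)


def _sem(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 2:
        return 0.0
    return float(np.std(x, ddof=1) / np.sqrt(len(x)))


def run_analysis(config: RunConfig, base_dir: str | Path | None = None) -> Path:
    """Run the full sleep + circadian analysis; returns the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    series = _acquire_series(config, Path(base_dir) if base_dir else None)
    if not series:
        raise ValueError("no fly series to analyse")
    series, exclusions = _exclude_dead(series, config.death_lookback_hours)
    exclusions.to_csv(out / "exclusions.csv", index=False)
    groups = sorted({s.group_label for s in series})
    for g in groups:
        if not any(s.group_label == g for s in series):
            raise ValueError(f"group {g!r} has no surviving flies")
    if not series:
        raise ValueError("all flies were excluded as dead")

    # --- per-fly sleep and activity metrics -------------------------------
    rows = []
    for s in series:
        try:
            metrics = sleep.sleep_metrics(s)
        except ValueError as exc:
            raise RuntimeError(f"sleep stage failed for {s.fly_id}: {exc}") from exc
        for phase, m in metrics.items():
            n_act, act_min = sleep.activity_metrics(s, phase)
            genotype, age = _split_group(s.group_label)
            rows.append(
                {
                    "fly_id": s.fly_id, "group": s.group_label,
                    "genotype": genotype, "age": age, "phase": phase,
                    "n_sleep_episodes": m.n_episodes,
                    "total_sleep_min": m.total_sleep_min,
                    "mean_bout_min": m.mean_bout_min,
                    "latency_min": m.latency_min,
                    "latency_uncensored_min": m.latency_uncensored_min,
                    "n_latency_censored": m.n_latency_censored,
                    "p_doze": m.p_doze, "p_wake": m.p_wake,
                    "n_activity_episodes": n_act,
                    "total_activity_min": act_min,
                    "n_days_averaged": m.n_days_averaged,
                }
            )
    per_fly = pd.DataFrame(rows)
    per_fly.to_csv(out / "per_fly_metrics.csv", index=False)

    # --- group eduction and sleep time-course -----------------------------
    ed_rows, tc_rows = [], []
    for g in groups:
        gs = [s for s in series if s.group_label == g]
        prof = sleep.eduction(gs, config.eduction_bin_min)
        tc = sleep.sleep_timecourse(gs, config.eduction_bin_min)
        for i, zt in enumerate(prof.bin_zt):
            ed_rows.append(
                {"group": g, "zt": zt, "mean_activity": prof.mean[i],
                 "sem_activity": prof.sem[i], "n_flies": prof.n_flies}
            )
            tc_rows.append(
                {"group": g, "zt": zt, "mean_sleep_min": tc.mean[i],
                 "sem_sleep_min": tc.sem[i], "n_flies": tc.n_flies}
            )
    pd.DataFrame(ed_rows).to_csv(out / "eduction.csv", index=False)
    pd.DataFrame(tc_rows).to_csv(out / "sleep_timecourse.csv", index=False)

    # --- anticipation -----------------------------------------------------
    ant_rows = []
    for s in series:
        a = circadian.anticipation_score(s)
        genotype, age = _split_group(s.group_label)
        ant_rows.append(
            {"fly_id": s.fly_id, "group": s.group_label, "genotype": genotype,
             "age": age, "anticipation_percent": a.score_percent,
             "n_days": a.n_days}
        )
    anticipation = pd.DataFrame(ant_rows)
    anticipation.to_csv(out / "anticipation.csv", index=False)

    # --- free-running rhythm analysis -------------------------------------
    rhythm_rows = []
    for s in series:
        try:
            win = circadian.dd_window(s, config.dd_days, config.dd_skip_hours)
        except ValueError:
            continue  # no usable DD window for this fly
        pg = circadian.chi_square_periodogram(
            s, win, config.periodogram_bin_min,
            config.period_range_hours, config.alpha,
        )
        res = circadian.classify_rhythmicity(pg, s.fly_id)
        genotype, age = _split_group(s.group_label)
        rhythm_rows.append(
            {"fly_id": s.fly_id, "group": s.group_label, "genotype": genotype,
             "age": age, "rhythmic": res.rhythmic,
             "period_hours": res.period_hours, "power": res.power,
             "robustness": res.robustness, "degenerate": res.degenerate}
        )
    rhythm = pd.DataFrame(rhythm_rows)
    rhythm.to_csv(out / "rhythm_per_fly.csv", index=False)

    summary_rows = []
    if len(rhythm):
        for g, sub in rhythm.groupby("group"):
            n_r = int(sub["rhythmic"].sum())
            n_a = int(len(sub) - n_r)
            per = sub.loc[sub["rhythmic"], "period_hours"]
            summary_rows.append(
                {
                    "group": g,
                    "genotype": _split_group(g)[0], "age": _split_group(g)[1],
                    "n_rhythmic": n_r, "n_arrhythmic": n_a,
                    "pct_rhythmic": 100.0 * n_r / len(sub),
                    "period_mean": float(per.mean()) if len(per) else np.nan,
                    "period_sem": _sem(per.to_numpy()),
                    "power_mean": float(sub["power"].mean()),
                    "power_sem": _sem(sub["power"].to_numpy()),
                    "robustness_mean": float(sub["robustness"].mean()),
                    "robustness_sem": _sem(sub["robustness"].to_numpy()),
                }
            )
    rhythm_summary = pd.DataFrame(summary_rows)
    rhythm_summary.to_csv(out / "rhythm_summary.csv", index=False)

    # --- group statistics --------------------------------------------------
    stats_dir = out / "stats"
    stats_dir.mkdir(exist_ok=True)
    _rhythm_tests(rhythm, config.alpha).to_csv(
        stats_dir / "rhythmicity_tests.csv", index=False
    )
    _metric_tests(per_fly, anticipation).to_csv(
        stats_dir / "metric_tests.csv", index=False
    )

    # --- representative actograms ------------------------------------------
    act_dir = out / "actograms"
    act_dir.mkdir(exist_ok=True)
    for g in groups:
        rep = next(s for s in series if s.group_label == g)
        mat, lig = circadian.actogram_matrix(rep, config.actogram_bin_min)
        np.savetxt(act_dir / f"{g}_activity.csv", mat, fmt="%.1f", delimiter=",")
        np.savetxt(act_dir / f"{g}_light.csv", lig, fmt="%d", delimiter=",")

    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(_config_to_dict(config), fh, sort_keys=True)
    return out


def _config_to_dict(config: RunConfig) -> dict:
    d: dict = {}
    for f in dataclasses.fields(config):
        v = getattr(config, f.name)
        if isinstance(v, Path):
            v = str(v)
        elif isinstance(v, (_dt.time, _dt.datetime)):
            v = v.isoformat()
        elif isinstance(v, tuple):
            v = list(v)
        elif isinstance(v, SimScenario):
            v = {
                "seed": v.seed, "n_flies": v.n_flies,
                "days_ld": v.days_ld, "days_dd": v.days_dd,
                "groups": [dataclasses.asdict(g) for g in v.groups],
            }
        d[f.name] = v
    return d


def _rhythm_tests(rhythm: pd.DataFrame, alpha: float) -> pd.DataFrame:
    """Fisher's exact within each age stratum + CMH consistency across ages."""
    rows = []
    if not len(rhythm):
        return pd.DataFrame(rows)
    tables = []
    for age, sub in rhythm.groupby("age"):
        genotypes = sorted(sub["genotype"].unique())
        if len(genotypes) != 2:
            continue
        cells = []
        for g in genotypes:
            gsub = sub[sub["genotype"] == g]
            cells.append(
                [int(gsub["rhythmic"].sum()), int((~gsub["rhythmic"]).sum())]
            )
        t = stats.ContingencyTable(cells[0][0], cells[0][1],
                                   cells[1][0], cells[1][1])
        res = stats.fisher_exact(t)
        rows.append(
            {"test": "fisher_exact", "stratum": age,
             "statistic": res.odds_ratio, "p": res.p_value,
             "stars": stats.significance_stars(res.p_value)}
        )
        tables.append(t)
    if len(tables) >= 2:
        cmh = stats.stratified_2x2(tables)
        rows.append(
            {"test": "cmh_stratified", "stratum": "all",
             "statistic": cmh["statistic"], "p": cmh["p_value"],
             "stars": stats.significance_stars(cmh["p_value"])}
        )
    return pd.DataFrame(rows)


def _metric_tests(per_fly: pd.DataFrame, anticipation: pd.DataFrame) -> pd.DataFrame:
    """Factorial + repeated-measures tests for each sleep/activity metric."""
    metrics = [
        "n_sleep_episodes", "total_sleep_min", "mean_bout_min",
        "latency_min", "p_doze", "p_wake",
        "n_activity_episodes", "total_activity_min",
    ]
    two_factor = (
        per_fly["genotype"].nunique() == 2 and per_fly["age"].nunique() == 2
    )
    rows = []
    for metric in metrics:
        if two_factor:
            try:
                rm = stats.three_way_rm_anova(
                    per_fly[metric], per_fly["genotype"], per_fly["age"],
                    per_fly["phase"], per_fly["fly_id"],
                )
            except ValueError:
                continue
            for term, r in rm.iterrows():
                rows.append(
                    {"metric": metric, "analysis": "rm_anova", "term": term,
                     "F": r["F"], "p": r["p"],
                     "stars": stats.significance_stars(r["p"])
                     if np.isfinite(r["p"]) else ""}
                )
        for phase, sub in per_fly.groupby("phase"):
            if not two_factor:
                continue
            tab = stats.two_way_anova(sub[metric], sub["genotype"], sub["age"])
            for term, r in tab.iterrows():
                if term == "residual":
                    continue
                rows.append(
                    {"metric": f"{metric}[{phase}]", "analysis": "two_way_anova",
                     "term": term, "F": r["F"], "p": r["p"],
                     "stars": stats.significance_stars(r["p"])}
                )
    if two_factor and len(anticipation):
        sub = anticipation.dropna(subset=["anticipation_percent"])
        tab = stats.two_way_anova(
            sub["anticipation_percent"], sub["genotype"], sub["age"]
        )
        for term, r in tab.iterrows():
            if term == "residual":
                continue
            rows.append(
                {"metric": "anticipation_percent", "analysis": "two_way_anova",
                 "term": term, "F": r["F"], "p": r["p"],
                 "stars": stats.significance_stars(r["p"])}
            )
    return pd.DataFrame(rows)


def make_report(out_dir: str | Path) -> list[Path]:
    """Render static plots (eduction, time-course, actograms) from a run."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    made = []

    def _plot_profiles(fname, csv, value_col, sem_col, ylabel):
        path = out_dir / csv
        if not path.exists():
            logger.warning("missing table %s; skipping plot", path)
            return
        df = pd.read_csv(path)
        fig, ax = plt.subplots(figsize=(7, 3.2))
        for g, sub in df.groupby("group"):
            ax.errorbar(sub["zt"], sub[value_col], yerr=sub[sem_col],
                        label=g, lw=1.2, elinewidth=0.6, capsize=0)
        ax.axvspan(0, 12, color="gold", alpha=0.25, lw=0)  # light phase
        ax.set_xlabel("ZT (h)")
        ax.set_ylabel(ylabel)
        ax.set_xlim(0, 24)
        ax.legend(fontsize=7)
        fig.tight_layout()
        p = out_dir / fname
        fig.savefig(p, dpi=120)
        plt.close(fig)
        made.append(p)

    _plot_profiles("eduction.png", "eduction.csv", "mean_activity",
                   "sem_activity", "beam crosses / bin")
    _plot_profiles("sleep_timecourse.png", "sleep_timecourse.csv",
                   "mean_sleep_min", "sem_sleep_min", "sleep (min / bin)")

    act_dir = out_dir / "actograms"
    if act_dir.exists():
        for f in sorted(act_dir.glob("*_activity.csv")):
            mat = np.loadtxt(f, delimiter=",", ndmin=2)
            light = np.loadtxt(
                act_dir / f.name.replace("_activity", "_light"),
                delimiter=",", ndmin=2,
            )
            n_days, width = mat.shape
            fig, axes = plt.subplots(
                n_days, 1, figsize=(6, 0.3 * n_days + 0.6),
                sharex=True, squeeze=False,
            )
            x = np.arange(width)
            for d in range(n_days):
                ax = axes[d, 0]
                lit = light[d] > 0
                if lit.any():
                    ax.fill_between(x, 0, mat.max() or 1, where=lit,
                                    color="gold", alpha=0.3, step="post", lw=0)
                ax.bar(x, mat[d], width=1.0, color="black")
                ax.set_yticks([])
            axes[-1, 0].set_xlabel("bin (double-plotted day)")
            p = out_dir / f.name.replace("_activity.csv", "_actogram.png")
            fig.savefig(p, dpi=120)
            plt.close(fig)
            made.append(p)
    return made
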