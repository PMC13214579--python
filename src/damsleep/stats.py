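"""Group-comparison statistics for sleep and circadian phenotypes.

Covers the tests used for activity-monitor phenotyping: Fisher's exact
test on rhythmic/arrhythmic contingency tables, the Cochran-Mantel-
Haenszel stratified 2x2 test for consistency of a genotype effect across
age strata, factorial two-way ANOVA (genotype x age, Type II sums of
squares for unbalanced groups) with Tukey HSD post-hoc comparisons, a
mixed between-within (repeated-measures) ANOVA with day/night phase as
the within-fly factor, and Sidak multiple-comparison adjustment.

The repeated-measures design with a two-level within factor is computed
exactly by the sum/difference decomposition: between-fly effects are a
factorial ANOVA on each fly's phase mean, within-fly effects a factorial
ANOVA on each fly's day-minus-night difference (the phase main effect is
the test of the sum-coded intercept).  With only two within levels
sphericity holds trivially, so no correction is needed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.contingency_tables import StratifiedTable
from statsmodels.stats.multicomp import pairwise_tukeyhsd

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable",
    "FisherResult",
    "fisher_exact",
    "stratified_2x2",
    "two_way_anova",
    "tukey_hsd",
    "three_way_rm_anova",
    "sidak_adjust",
    "significance_stars",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts; rows = genotype, columns = rhythmic/arrhythmic."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(v) != v or v < 0 for v in cells):
            raise ValueError("cells must be non-negative integers")
        if sum(cells) < 1:
            raise ValueError("table total must be >= 1")

    def to_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


class FisherResult(NamedTuple):
    p_value: float
    odds_ratio: float
    degenerate: bool  # a zero margin: p = 1 by convention


def fisher_exact(table: ContingencyTable | Sequence[Sequence[int]]) -> FisherResult:
    """Two-sided Fisher's exact test on a 2x2 table.

    Two-sidedness follows the point-probability rule: the p-value sums
    the hypergeometric probabilities of all tables (with the observed
    margins) no more probable than the observed one.
    """
    if not isinstance(table, ContingencyTable):
        (a, b), (c, d) = table
        table = ContingencyTable(a, b, c, d)
    arr = table.to_array()
    degenerate = bool((arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any())
    res = sps.fisher_exact(arr, alternative="two-sided")
    return FisherResult(
        p_value=float(res.pvalue),
        odds_ratio=float(res.statistic),
        degenerate=degenerate,
    )


def _stratum_degenerate(arr: np.ndarray) -> bool:
    return bool((arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any())


def stratified_2x2(
    tables: Sequence[ContingencyTable | Sequence[Sequence[int]]],
) -> dict:
    """Cochran-Mantel-Haenszel common-association test across strata.

    Tests whether the genotype/rhythmicity association is consistent in
    direction across strata (e.g. age groups), without continuity
    correction.  Strata with a zero margin carry no information and are
    skipped with a warning.

    Returns a dict with ``statistic``, ``p_value``, ``common_odds_ratio``
    (Mantel-Haenszel pooled estimate) and ``n_strata_used``.
    """
    arrays = []
    for t in tables:
        if not isinstance(t, ContingencyTable):
            (a, b), (c, d) = t
            t = ContingencyTable(a, b, c, d)
        arr = t.to_array()
        if _stratum_degenerate(arr):
            logger.warning("skipping degenerate stratum %s", arr.tolist())
            continue
        arrays.append(arr)
    if not arrays:
        raise ValueError("no informative stratum")
    st = StratifiedTable([a.astype(float) for a in arrays])
    res = st.test_null_odds(correction=False)
    return {
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "common_odds_ratio": float(st.oddsratio_pooled),
        "n_strata_used": len(arrays),
    }


def _anova_lm_quiet(fit, typ: int) -> pd.DataFrame:
    """anova_lm with benign zero-SS rank warnings silenced.

    Fully tied values in a cell give a zero-SS term; statsmodels warns
    about the rank-deficient constraint but still returns the correct
    table (F = NaN for that term).
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.filterwarnings("ignore", message=".*full rank.*")
        return sm.stats.anova_lm(fit, typ=typ)


def _check_cells(df: pd.DataFrame, factors: list[str]) -> None:
    sizes = df.groupby(factors, observed=True).size()
    if (sizes < 2).any():
        small = sizes[sizes < 2]
        raise ValueError(f"groups with n < 2: {small.to_dict()}")


def two_way_anova(
    values: Sequence[float],
    genotype: Sequence[str],
    age: Sequence[str],
) -> pd.DataFrame:
    """Two-way factorial ANOVA (genotype x age), Type II sums of squares.

    Type II is appropriate for unbalanced group sizes without missing
    cells.  Returns the term table with sum_sq, df, F and p columns.
    """
    df = pd.DataFrame(
        {"value": values, "genotype": genotype, "age": age}
    ).dropna()
    _check_cells(df, ["genotype", "age"])
    fit = smf.ols("value ~ C(genotype) * C(age)", data=df).fit()
    table = _anova_lm_quiet(fit, typ=2)
    table = table.rename(
        index={
            "C(genotype)": "genotype",
            "C(age)": "age",
            "C(genotype):C(age)": "genotype:age",
            "Residual": "residual",
        },
        columns={"PR(>F)": "p"},
    )
    return table


def tukey_hsd(
    values: Sequence[float],
    genotype: Sequence[str],
    age: Sequence[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons across the genotype x age cells.

    Adjusted p-values come from the studentized-range distribution on
    all cell means (the standard follow-up to the factorial ANOVA).
    """
    df = pd.DataFrame(
        {"value": values, "genotype": genotype, "age": age}
    ).dropna()
    df["cell"] = df["genotype"].astype(str) + ":" + df["age"].astype(str)
    _check_cells(df, ["cell"])
    res = pairwise_tukeyhsd(df["value"].to_numpy(), df["cell"].to_numpy(), alpha=alpha)
    out = pd.DataFrame(
        res._results_table.data[1:], columns=res._results_table.data[0]
    )
    out = out.rename(columns={"p-adj": "p_adj"})
    out["p_adj"] = res.pvalues
    return out


def three_way_rm_anova(
    values: Sequence[float],
    genotype: Sequence[str],
    age: Sequence[str],
    phase: Sequence[str],
    fly_id: Sequence[str],
) -> pd.DataFrame:
    """Mixed ANOVA: genotype and age between flies, day/night phase within.

    Each fly must contribute exactly one value per phase; flies missing a
    phase are dropped with a warning.  Reports all main effects and
    interactions with separate between-fly and within-fly error terms.
    """
    df = pd.DataFrame(
        {
            "value": values,
            "genotype": genotype,
            "age": age,
            "phase": phase,
            "fly_id": fly_id,
        }
    ).dropna()
    wide = df.pivot_table(
        index=["fly_id", "genotype", "age"],
        columns="phase",
        values="value",
        aggfunc="first",
    ).reset_index()
    phases = sorted(df["phase"].unique())
    if len(phases) != 2:
        raise ValueError(f"expected exactly 2 phase levels, got {phases}")
    complete = wide.dropna(subset=phases)
    dropped = len(wide) - len(complete)
    if dropped:
        warnings.warn(f"dropped {dropped} fly(ies) missing one phase")
    complete = complete.copy()
    _check_cells(complete, ["genotype", "age"])
    # sum/difference decomposition: exact for a 2-level within factor
    complete["m"] = complete[phases].mean(axis=1)
    complete["d"] = complete[phases[0]] - complete[phases[1]]

    between_fit = smf.ols("m ~ C(genotype) * C(age)", data=complete).fit()
    between = _anova_lm_quiet(between_fit, typ=2)
    if np.allclose(complete["d"], 0.0):
        # identical phase values: every within-fly SS is exactly zero
        n_groups = complete.groupby(["genotype", "age"], observed=True).ngroups
        zero = {"sum_sq": 0.0, "df": 1.0, "F": np.nan, "PR(>F)": np.nan}
        within = pd.DataFrame(
            {
                "Intercept": zero,
                "C(genotype, Sum)": zero,
                "C(age, Sum)": zero,
                "C(genotype, Sum):C(age, Sum)": zero,
                "Residual": {"sum_sq": 0.0, "df": float(len(complete) - n_groups),
                             "F": np.nan, "PR(>F)": np.nan},
            }
        ).T
    else:
        within_fit = smf.ols(
            "d ~ C(genotype, Sum) * C(age, Sum)", data=complete
        ).fit()
        within = _anova_lm_quiet(within_fit, typ=3)

    def row(name, src, key, scale):
        return {
            "term": name,
            "sum_sq": float(src.loc[key, "sum_sq"]) * scale,
            "df": float(src.loc[key, "df"]),
            "F": float(src.loc[key, "F"]),
            "p": float(src.loc[key, "PR(>F)"]),
        }

    # scale SS to the observation metric: between SS double (2 obs/fly),
    # within SS halved (d = difference of 2 obs); F and p are unaffected
    rows = [
        row("genotype", between, "C(genotype)", 2.0),
        row("age", between, "C(age)", 2.0),
        row("genotype:age", between, "C(genotype):C(age)", 2.0),
        {
            "term": "error(between)",
            "sum_sq": float(between.loc["Residual", "sum_sq"]) * 2.0,
            "df": float(between.loc["Residual", "df"]),
            "F": np.nan,
            "p": np.nan,
        },
        row("phase", within, "Intercept", 0.5),
        row("phase:genotype", within, "C(genotype, Sum)", 0.5),
        row("phase:age", within, "C(age, Sum)", 0.5),
        row(
            "phase:genotype:age",
            within,
            "C(genotype, Sum):C(age, Sum)",
            0.5,
        ),
        {
            "term": "error(within)",
            "sum_sq": float(within.loc["Residual", "sum_sq"]) * 0.5,
            "df": float(within.loc["Residual", "df"]),
            "F": np.nan,
            "p": np.nan,
        },
    ]
    return pd.DataFrame(rows).set_index("term")


def sidak_adjust(p_values: Sequence[float], m: int | None = None) -> np.ndarray:
    """Sidak multiple-comparison adjustment: 1 - (1 - p)^m, clipped to [0, 1]."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = len(p)
    return np.clip(1.0 - (1.0 - p) ** m, 0.0, 1.0)


def significance_stars(p: float) -> str:
    """Figure-legend star notation at 0.05 / 0.01 / 0.001 / 0.0001."""
    if np.isnan(p):
        return ""
    for threshold, stars in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*")):
        if p < threshold:
            return stars
    return "ns"
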