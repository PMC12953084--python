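"""Group statistics: descriptives, one-way ANOVA, two-way repeated-measures
ANOVA, and Bonferroni-corrected post-hoc contrasts.

Summaries are mean ± SD with t-based 95% CIs.  One-way ANOVA uses the
standard between/within sum-of-squares decomposition with all pairwise
group contrasts Bonferroni-adjusted (m = number of pairs).  The two-way
design (group between, time within) is fitted as a mixed ANOVA with
Greenhouse–Geisser correction reported alongside the uncorrected within
effects; its post-hoc family is restricted to between-group contrasts at
the same time point, with the Bonferroni multiplier
m = (#group pairs) × (#time points) recorded in the output so the family
can be audited.  Because the adjustment of the contrast CIs is a
convention choice, both unadjusted and Bonferroni-adjusted CIs are
emitted.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["StatsResult", "describe", "oneway_anova", "rm_anova", "stars"]


def stars(p: float) -> str:
    """Significance stars at 0.05 / 0.01 / 0.001 / 0.0001."""
    for thresh, mark in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (0.05, "*")):
        if p < thresh:
            return mark
    return "ns"


@dataclass
class StatsResult:
    """ANOVA output: descriptives, effects and pairwise contrasts."""

    descriptives: pd.DataFrame
    effects: pd.DataFrame
    pairwise: pd.DataFrame
    bonferroni_m: int
    notes: list[str] = field(default_factory=list)


def describe(
    table: pd.DataFrame,
    value_col: str = "value",
    group_col: str = "group",
    ci: float = 0.95,
) -> pd.DataFrame:
    """Per-group n, mean, SD and t-based CI.  Single-observation groups get
    NaN SD/CI and a 'flagged' marker rather than an error."""
    rows = []
    for grp, sub in table.groupby(group_col, sort=False):
        x = sub[value_col].to_numpy(dtype=float)
        n = x.size
        mean = float(x.mean())
        if n >= 2:
            sd = float(x.std(ddof=1))
            half = sps.t.ppf(0.5 + ci / 2, n - 1) * sd / np.sqrt(n)
            lo, hi = mean - half, mean + half
            flag = ""
        else:
            sd = lo = hi = np.nan
            flag = "single observation: SD/CI undefined"
        rows.append({group_col: grp, "n": n, "mean": mean, "sd": sd,
                     "ci_low": lo, "ci_high": hi, "flag": flag})
    return pd.DataFrame(rows)


def _pairwise_t(
    table: pd.DataFrame, value_col: str, group_col: str,
    m: int, label_extra: dict | None = None, ci: float = 0.95,
) -> list[dict]:
    rows = []
    groups = list(dict.fromkeys(table[group_col]))
    for a, b in itertools.combinations(groups, 2):
        xa = table.loc[table[group_col] == a, value_col].to_numpy(dtype=float)
        xb = table.loc[table[group_col] == b, value_col].to_numpy(dtype=float)
        na, nb = xa.size, xb.size
        diff = xa.mean() - xb.mean()
        df = na + nb - 2
        sp2 = ((na - 1) * xa.var(ddof=1) + (nb - 1) * xb.var(ddof=1)) / df
        se = np.sqrt(sp2 * (1 / na + 1 / nb))
        tstat = diff / se if se > 0 else (0.0 if diff == 0 else np.inf)
        p = 2 * sps.t.sf(abs(tstat), df) if np.isfinite(tstat) else 0.0
        p_adj = min(1.0, p * m)
        q = sps.t.ppf(0.5 + ci / 2, df)
        q_adj = sps.t.ppf(1 - (1 - ci) / (2 * m), df)
        row = {
            "group_a": a, "group_b": b, "diff": diff, "t": tstat, "df": df,
            "p_raw": p, "p_bonf": p_adj,
            "ci_low": diff - q * se, "ci_high": diff + q * se,
            "ci_low_bonf": diff - q_adj * se, "ci_high_bonf": diff + q_adj * se,
            "stars": stars(p_adj),
        }
        if label_extra:
            row.update(label_extra)
        rows.append(row)
    return rows


def oneway_anova(
    table: pd.DataFrame,
    value_col: str = "value",
    group_col: str = "group",
) -> StatsResult:
    """One-way ANOVA with Bonferroni-adjusted pairwise contrasts.

    Identical groups give F = 0, p = 1; with two groups F equals the
    squared pooled t statistic.
    """
    groups = list(dict.fromkeys(table[group_col]))
    if len(groups) < 2:
        raise ValueError("one-way ANOVA needs >= 2 groups")
    arrays = [
        table.loc[table[group_col] == g, value_col].to_numpy(dtype=float)
        for g in groups
    ]
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs >= 2 observations")
    allx = np.concatenate(arrays)
    grand = allx.mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b = len(groups) - 1
    df_w = allx.size - len(groups)
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    if ms_w == 0:
        f = 0.0 if ms_b == 0 else np.inf
        p = 1.0 if ms_b == 0 else 0.0
    else:
        f = ms_b / ms_w
        p = float(sps.f.sf(f, df_b, df_w))
    effects = pd.DataFrame([
        {"effect": group_col, "ss": ss_between, "df1": df_b, "df2": df_w,
         "ms": ms_b, "F": f, "p": p, "stars": stars(p)},
        {"effect": "residual", "ss": ss_within, "df1": df_w, "df2": np.nan,
         "ms": ms_w, "F": np.nan, "p": np.nan, "stars": ""},
    ])
    m = len(groups) * (len(groups) - 1) // 2
    pairwise = pd.DataFrame(_pairwise_t(table, value_col, group_col, m))
    return StatsResult(
        descriptives=describe(table, value_col, group_col),
        effects=effects,
        pairwise=pairwise,
        bonferroni_m=m,
    )


def rm_anova(
    table: pd.DataFrame,
    value_col: str = "value",
    group_col: str = "group",
    time_col: str = "time",
    subject_col: str = "animal_id",
) -> StatsResult:
    """Two-way repeated-measures (mixed) ANOVA: group between, time within.

    Subjects missing any time point are listed and excluded with a warning,
    never imputed.  Greenhouse–Geisser-corrected p-values accompany the
    uncorrected within effects.  Post-hoc contrasts compare groups within
    each time point only; the Bonferroni multiplier is
    (#group pairs) × (#time points).  A single time point degenerates to
    the one-way analysis.
    """
    times = sorted(table[time_col].unique())
    if len(times) == 1:
        return oneway_anova(table, value_col, group_col)
    dup = table.duplicated([subject_col, time_col]).any()
    if dup:
        raise ValueError("duplicated (subject, time) measurements")

    counts = table.groupby(subject_col)[time_col].nunique()
    incomplete = counts[counts < len(times)].index.tolist()
    notes = []
    if incomplete:
        warnings.warn(
            f"excluding subjects with missing time points: {incomplete}",
            stacklevel=2,
        )
        notes.append(f"excluded incomplete subjects: {incomplete}")
        table = table[~table[subject_col].isin(incomplete)]

    if table[value_col].nunique() == 1:
        # constant response: every effect is exactly null
        effects = pd.DataFrame(
            {"effect": ["group", "time", "Interaction"],
             "ss": 0.0, "df1": np.nan, "df2": np.nan, "ms": 0.0,
             "F": 0.0, "p": 1.0, "p_gg": np.nan, "eps_gg": np.nan,
             "stars": "ns"}
        )
        groups = list(dict.fromkeys(table[group_col]))
        m = len(groups) * (len(groups) - 1) // 2 * len(times)
        return StatsResult(
            descriptives=describe(table, value_col, group_col),
            effects=effects, pairwise=pd.DataFrame(), bonferroni_m=m,
            notes=notes + ["constant response: degenerate ANOVA"],
        )

    import pingouin as pg

    aov = pg.mixed_anova(
        data=table, dv=value_col, within=time_col,
        subject=subject_col, between=group_col, correction=True,
    )
    effects = pd.DataFrame({
        "effect": aov["Source"],
        "ss": aov["SS"],
        "df1": aov["DF1"],
        "df2": aov["DF2"],
        "ms": aov["MS"],
        "F": aov["F"],
        "p": aov["p_unc"],
        "p_gg": aov.get("p_GG_corr", pd.Series([np.nan] * len(aov))),
        "eps_gg": aov.get("eps", pd.Series([np.nan] * len(aov))),
    })
    effects["stars"] = [stars(p) if np.isfinite(p) else "" for p in effects["p"]]

    groups = list(dict.fromkeys(table[group_col]))
    n_pairs = len(groups) * (len(groups) - 1) // 2
    m = n_pairs * len(times)
    rows = []
    for t in times:
        sub = table[table[time_col] == t]
        rows.extend(
            _pairwise_t(sub, value_col, group_col, m, label_extra={time_col: t})
        )
    pairwise = pd.DataFrame(rows)

    desc = (
        table.groupby(time_col, sort=True)
        .apply(lambda s: describe(s, value_col, group_col), include_groups=False)
        .reset_index(level=0)
        .reset_index(drop=True)
    )
    return StatsResult(
        descriptives=desc,
        effects=effects,
        pairwise=pairwise,
        bonferroni_m=m,
        notes=notes,
    )
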