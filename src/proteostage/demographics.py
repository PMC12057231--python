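"""Cohort demographic summaries with the conventional tests.

Continuous variables are summarized as median [IQR] per stratum and compared
with the Kruskal-Wallis test; categorical variables as counts (percent) with
the Pearson chi-square test (continuity correction off by default).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def summarize_demographics(
    meta: pd.DataFrame,
    strata: pd.Series,
    continuous=("age",),
    categorical=("sex", "diagnosis"),
    correction: bool = False,
) -> pd.DataFrame:
    """One row per variable: per-stratum summary, test name, statistic, p.

    Strata with zero samples are dropped with a note column; fewer than two
    populated strata raise.
    """
    strata = strata.reindex(meta.index)
    levels = [lvl for lvl in sorted(strata.dropna().unique())
              if (strata == lvl).sum() > 0]
    if len(levels) < 2:
        raise ValueError("need at least 2 populated strata")
    rows = []
    for var in continuous:
        if var not in meta.columns:
            continue
        vals = pd.to_numeric(meta[var], errors="coerce")
        groups, summaries = [], {}
        for lvl in levels:
            g = vals[strata == lvl].dropna()
            if len(g):
                groups.append(g.to_numpy())
            q1, q2, q3 = g.quantile([0.25, 0.5, 0.75]) if len(g) else (np.nan,) * 3
            summaries[str(lvl)] = f"{q2:.1f} [{q1:.1f}-{q3:.1f}]" if len(g) else "NA"
        if len(groups) >= 2:
            stat, p = stats.kruskal(*groups)
        else:
            stat, p = np.nan, np.nan
        rows.append({"variable": var, "type": "continuous",
                     "test": "Kruskal-Wallis", "statistic": stat, "p": p,
                     **summaries})
    for var in categorical:
        if var not in meta.columns:
            continue
        tab = pd.crosstab(meta[var], strata)
        tab = tab[[lvl for lvl in levels if lvl in tab.columns]]
        summaries = {}
        for lvl in levels:
            col = tab[lvl] if lvl in tab.columns else pd.Series(dtype=int)
            total = col.sum()
            summaries[str(lvl)] = "; ".join(
                f"{cat}: {cnt} ({100 * cnt / total:.0f}%)" for cat, cnt in col.items()
            ) if total else "NA"
        if tab.shape[0] >= 2 and tab.shape[1] >= 2 and (tab.to_numpy().sum(axis=1) > 0).all():
            stat, p, _, _ = stats.chi2_contingency(tab.to_numpy(), correction=correction)
        else:
            stat, p = np.nan, np.nan
        rows.append({"variable": var, "type": "categorical",
                     "test": "Pearson chi-square", "statistic": stat, "p": p,
                     **summaries})
    return pd.DataFrame(rows)
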