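"""ANOVA screening of acoustic features with Tukey-Kramer post hocs.

Each measured variable is tested for colony differences with a one-way
ANOVA; variables significant at ``alpha`` are retained as informative for
the discriminant analysis, and Tukey-Kramer pairwise comparisons (adjusted
p-values from the studentized-range distribution, valid for unequal group
sizes) name the diverging colony pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .measure import FEATURE_NAMES
from .stats import one_way_anova

__all__ = ["FeatureScreenReport", "screen_features"]


@dataclass
class FeatureScreenReport:
    anova: pd.DataFrame                      # feature, F, df1, df2, p, retained
    tukey: dict[str, pd.DataFrame] = field(default_factory=dict)
    excluded_constant: list[str] = field(default_factory=list)

    @property
    def informative(self) -> list[str]:
        return list(self.anova.loc[self.anova["retained"], "feature"])


def screen_features(features: pd.DataFrame, alpha: float = 0.05,
                    feature_cols: list[str] | None = None,
                    group_col: str = "colony") -> FeatureScreenReport:
    """One-way ANOVA per feature across colonies; Tukey on retained features.

    Features that are constant within every group (F undefined) are
    excluded with a warning entry rather than crashing the screen.
    """
    feature_cols = feature_cols or [c for c in FEATURE_NAMES
                                    if c in features.columns]
    groups_by = {g: sub for g, sub in features.groupby(group_col)}
    if len(groups_by) < 2 or any(len(s) < 2 for s in groups_by.values()):
        raise ValueError("need >= 2 colonies with >= 2 observations each")

    rows = []
    tukey: dict[str, pd.DataFrame] = {}
    excluded: list[str] = []
    for col in feature_cols:
        vals = [sub[col].dropna().to_numpy(dtype=float)
                for sub in groups_by.values()]
        if all(np.var(v) == 0 for v in vals) and len({v[0] for v in vals}) == 1:
            excluded.append(col)
            continue
        res = one_way_anova(vals)
        retained = res.p_value < alpha
        rows.append({"feature": col, "F": res.statistic,
                     "df1": res.df[0], "df2": res.df[1],
                     "p": res.p_value, "retained": retained})
        if retained:
            sub = features[[col, group_col]].dropna()
            t = pairwise_tukeyhsd(sub[col].to_numpy(dtype=float),
                                  sub[group_col].to_numpy(), alpha=alpha)
            tukey[col] = pd.DataFrame(
                t.summary().data[1:], columns=t.summary().data[0])
    return FeatureScreenReport(pd.DataFrame(rows), tukey, excluded)
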