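"""Basic group-comparison statistics: Welch's t with Cohen's d, one-way ANOVA."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = ["StatTestResult", "welch_t", "one_way_anova"]


@dataclass
class StatTestResult:
    statistic: float
    df: float | tuple[float, float]
    p_value: float
    effect_size_d: float | None = None
    group_summaries: dict = field(default_factory=dict)


def _summaries(groups: dict[str, np.ndarray]) -> dict:
    return {
        name: {"mean": float(np.mean(v)), "sd": float(np.std(v, ddof=1)),
               "n": int(len(v))}
        for name, v in groups.items()
    }


def welch_t(values_a, values_b) -> StatTestResult:
    """Welch's two-sample t-test (unequal variances) with Cohen's d.

    Cohen's d uses the pooled standard deviation
    sqrt(((n_a-1)s_a^2 + (n_b-1)s_b^2) / (n_a+n_b-2)).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 and vb == 0:
        if np.mean(a) == np.mean(b):
            return StatTestResult(0.0, float(len(a) + len(b) - 2), 1.0, 0.0,
                                  _summaries({"a": a, "b": b}))
        raise ValueError("zero variance in both groups with unequal means")
    res = sps.ttest_ind(a, b, equal_var=False)
    na, nb = len(a), len(b)
    # Welch-Satterthwaite degrees of freedom
    df = (va / na + vb / nb) ** 2 / (
        (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
    )
    s_pooled = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    d = float((np.mean(a) - np.mean(b)) / s_pooled) if s_pooled > 0 else 0.0
    return StatTestResult(float(res.statistic), float(df), float(res.pvalue), d,
                          _summaries({"a": a, "b": b}))


def one_way_anova(groups: list[np.ndarray]) -> StatTestResult:
    """One-way ANOVA across >= 2 groups; df = (k-1, N-k)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    groups = [g[~np.isnan(g)] for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    if all(np.var(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
        raise ValueError("statistic undefined: all values identical")
    f, p = sps.f_oneway(*groups)
    k = len(groups)
    n = sum(len(g) for g in groups)
    return StatTestResult(float(f), (float(k - 1), float(n - k)), float(p),
                          None, _summaries({str(i): g for i, g in enumerate(groups)}))
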