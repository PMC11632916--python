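"""Statistical post-processing: Grubbs' outlier removal and normality-gated
group comparisons.

Grubbs' test is implemented from first principles (it shapes the permeability
group means); Shapiro–Wilk, ANOVA/Tukey, Mann–Whitney and Kruskal–Wallis
delegate to scipy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["GrubbsResult", "ComparisonReport", "grubbs_test",
           "grubbs_critical_value", "compare_groups"]


@dataclass
class GrubbsResult:
    statistic: float
    critical_value: float
    outlier_index: int | None
    cleaned: np.ndarray
    alpha: float


@dataclass
class ComparisonReport:
    test_name: str
    statistic: float
    p_value: float
    groups: list[str]
    normality_pass: dict[str, bool]
    significance: str  # star tier, "" if not significant
    posthoc: dict | None = None


def grubbs_critical_value(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value.

    G_crit = ((n-1)/sqrt(n)) * sqrt(t^2 / (n - 2 + t^2)) with t the upper
    alpha/(2n) quantile of Student's t with n-2 degrees of freedom.
    """
    if n < 3:
        raise ValueError("Grubbs' test requires n >= 3")
    t = sps.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))


def grubbs_test(x, alpha: float = 0.05, iterative: bool = False) -> GrubbsResult:
    """Two-sided single-outlier Grubbs test with single-pass removal.

    G = max |x_i - mean| / s (sample SD).  The most deviant point is removed
    only when G exceeds the critical value; at most one point by default
    (``iterative=True`` repeats until no outlier remains, keeping the
    first-pass statistic in the report).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("Grubbs' test requires n >= 3")
    s = np.std(x, ddof=1)
    if s == 0:
        return GrubbsResult(0.0, grubbs_critical_value(x.size, alpha), None, x.copy(), alpha)
    dev = np.abs(x - x.mean())
    idx = int(np.argmax(dev))
    g = float(dev[idx] / s)
    crit = grubbs_critical_value(x.size, alpha)
    if g <= crit:
        return GrubbsResult(g, crit, None, x.copy(), alpha)
    cleaned = np.delete(x, idx)
    if iterative and cleaned.size >= 3:
        inner = grubbs_test(cleaned, alpha=alpha, iterative=True)
        cleaned = inner.cleaned
    return GrubbsResult(g, crit, idx, cleaned, alpha)


_PARAMETRIC_TIERS = [(1e-5, "****"), (1e-4, "***"), (1e-3, "**"), (0.05, "*")]
_NONPARAMETRIC_TIERS = [(1e-4, "****"), (5e-3, "**")]


def _tier(p: float, tiers) -> str:
    for cut, stars in tiers:
        if p < cut:
            return stars
    return ""


def compare_groups(groups: dict[str, np.ndarray], alpha: float = 0.05) -> ComparisonReport:
    """Normality-gated comparison of labeled groups.

    Each group is checked with Shapiro–Wilk at ``alpha``.  If all pass:
    one-way ANOVA (with Tukey post-hoc for more than two groups; for two
    groups the ANOVA is the equivalent two-sample comparison).  If any fail:
    Mann–Whitney U for two groups, Kruskal–Wallis for more.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 3:
            raise ValueError(f"group {k!r} has n < 3")
    normality = {k: bool(sps.shapiro(v).pvalue > alpha) for k, v in arrays.items()}
    values = [arrays[k] for k in labels]
    posthoc = None
    if all(normality.values()):
        stat, p = sps.f_oneway(*values)
        name = "one-way ANOVA"
        if len(labels) > 2:
            tk = sps.tukey_hsd(*values)
            posthoc = {
                f"{labels[i]} vs {labels[j]}": float(tk.pvalue[i, j])
                for i in range(len(labels)) for j in range(i + 1, len(labels))
            }
        stars = _tier(p, _PARAMETRIC_TIERS)
    elif len(labels) == 2:
        stat, p = sps.mannwhitneyu(values[0], values[1], alternative="two-sided")
        name = "Mann-Whitney U"
        stars = _tier(p, _NONPARAMETRIC_TIERS)
    else:
        stat, p = sps.kruskal(*values)
        name = "Kruskal-Wallis"  # extension beyond the two-group nonparametric path
        stars = _tier(p, _NONPARAMETRIC_TIERS)
    return ComparisonReport(
        test_name=name, statistic=float(stat), p_value=float(p),
        groups=labels, normality_pass=normality, significance=stars,
        posthoc=posthoc,
    )
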