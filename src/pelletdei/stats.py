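"""Group statistics and material classification for per-pellet DEI values.

Per-material summaries (mean, SD, quartiles for box plots), a pairwise
two-sided Wilcoxon rank-sum matrix, and a coarse material-category
classifier.  The rank-sum test uses the exact null distribution whenever the
combined sample is small (n_a + n_b <= 20) and tie free, and the
tie-corrected normal approximation otherwise — matching standard practice
for small forensic samples.

The classifier maps a per-pellet (or per-group) mean DEI to one of three
categories: steel (ferromagnetic — the clinically actionable flag, since
retained steel pellets contraindicate MRI), copper, or "high-Z
indeterminate".  Lead, tungsten and bismuth share nearly identical measured
DEI and are never separated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "MaterialGroup",
    "PairwiseTestResult",
    "ClassificationBoundaries",
    "Category",
    "summarize_groups",
    "rank_sum_test",
    "wilcoxon_matrix",
    "classify_category",
    "boxplot_figure",
]

#: Largest combined sample for which the exact rank-sum null is enumerated.
EXACT_MAX_TOTAL_N = 20


@dataclass
class MaterialGroup:
    """Per-pellet mean DEI values for one pellet material."""

    material: str
    dei_values: np.ndarray

    def __post_init__(self) -> None:
        self.dei_values = np.asarray(self.dei_values, dtype=float).ravel()
        if self.dei_values.size < 1:
            raise ValueError(f"group {self.material!r} is empty")
        if not np.all(np.isfinite(self.dei_values)):
            raise ValueError(f"group {self.material!r} has non-finite values")

    @property
    def n(self) -> int:
        return int(self.dei_values.size)


@dataclass(frozen=True)
class PairwiseTestResult:
    """Two-sided Wilcoxon rank-sum comparison of two material groups."""

    material_a: str
    material_b: str
    p_value: float
    statistic: float  # rank sum of group a (W = U + n_a(n_a+1)/2)
    method: str  # "exact" | "normal-approximation"
    significant: bool


def summarize_groups(groups: list[MaterialGroup]) -> pd.DataFrame:
    """Mean, SD and box-plot quartiles per material.

    SD uses the n-1 denominator; for a single-pellet group it is undefined
    and reported as NaN.
    """
    rows = []
    for g in groups:
        v = g.dei_values
        rows.append(
            {
                "material": g.material,
                "n": g.n,
                "mean_dei": float(v.mean()),
                "sd_dei": float(v.std(ddof=1)) if g.n > 1 else np.nan,
                "min": float(v.min()),
                "q1": float(np.percentile(v, 25)),
                "median": float(np.percentile(v, 50)),
                "q3": float(np.percentile(v, 75)),
                "max": float(v.max()),
            }
        )
    return pd.DataFrame(rows)


def rank_sum_test(
    a: np.ndarray, b: np.ndarray, alpha: float = 0.05
) -> tuple[float, float, str]:
    """Two-sided Wilcoxon rank-sum p-value for two samples.

    Returns (p_value, rank_sum_statistic, method).  Exact enumeration is
    used when n_a + n_b <= 20 and the pooled sample has no ties; otherwise
    the normal approximation with midranks and tie-corrected variance.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 1 or b.size < 1:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if a.size + b.size <= EXACT_MAX_TOTAL_N and not has_ties:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        method = "exact"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        method = "normal-approximation"
    w = float(res.statistic) + a.size * (a.size + 1) / 2.0
    return float(res.pvalue), w, method


def wilcoxon_matrix(
    groups: list[MaterialGroup], alpha: float = 0.05, holm: bool = False
) -> tuple[pd.DataFrame, list[PairwiseTestResult]]:
    """Pairwise two-sided rank-sum p-value matrix across material groups.

    The matrix is symmetric with the diagonal fixed at 1.000 (a group is
    never distinguishable from itself).  Raw p-values are reported by
    default; ``holm=True`` applies Holm step-down adjustment to the
    off-diagonal pairs before the significance flags are set.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    names = [g.material for g in groups]
    if len(set(names)) != len(names):
        raise ValueError("duplicate group names")
    k = len(groups)
    p = np.ones((k, k))
    raw: list[tuple[int, int, float, float, str]] = []
    for i in range(k):
        for j in range(i + 1, k):
            pv, w, method = rank_sum_test(groups[i].dei_values, groups[j].dei_values)
            raw.append((i, j, pv, w, method))
    pvals = np.array([r[2] for r in raw])
    if holm and pvals.size:
        order = np.argsort(pvals)
        m = pvals.size
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * pvals[idx])
            adj[idx] = min(1.0, running)
        pvals = adj
    results = []
    for (i, j, _, w, method), pv in zip(raw, pvals):
        p[i, j] = p[j, i] = pv
        results.append(
            PairwiseTestResult(
                material_a=names[i],
                material_b=names[j],
                p_value=float(pv),
                statistic=w,
                method=method,
                significant=bool(pv < alpha),
            )
        )
    return pd.DataFrame(p, index=names, columns=names), results


@dataclass(frozen=True)
class ClassificationBoundaries:
    """DEI interval boundaries separating the material categories.

    The defaults are tied to the 100/140 kVp tin-filtered protocol: steel
    above the copper/steel midpoint (0.1995), copper down to 0.1, everything
    below is high-Z indeterminate.  Boundaries are protocol specific (an
    80/140 kVp run shifts steel to about 0.30) and should come from the
    matching profile configuration.  ``ambiguous_halfwidth`` widens each
    boundary into a buffer that maps to "indeterminate".
    """

    steel_min: float = 0.1995
    copper_min: float = 0.1
    ambiguous_halfwidth: float = 0.0


@dataclass(frozen=True)
class Category:
    name: str  # "steel" | "copper" | "high-Z indeterminate" | "indeterminate"
    ferromagnetic: bool


def classify_category(
    mean_dei: float, boundaries: ClassificationBoundaries | None = None
) -> Category:
    """Assign a pellet-material category from a mean DEI value.

    Steel carries ``ferromagnetic=True``; lead, tungsten and bismuth are
    deliberately pooled as "high-Z indeterminate" — their DEI values overlap
    too strongly for separation.  Values inside the configured ambiguous
    buffer around either boundary return "indeterminate".
    """
    if not np.isfinite(mean_dei):
        raise ValueError("mean DEI must be finite")
    b = boundaries if boundaries is not None else ClassificationBoundaries()
    h = b.ambiguous_halfwidth
    if h > 0 and (abs(mean_dei - b.steel_min) < h or abs(mean_dei - b.copper_min) < h):
        return Category("indeterminate", False)
    if mean_dei >= b.steel_min:
        return Category("steel", True)
    if mean_dei >= b.copper_min:
        return Category("copper", False)
    return Category("high-Z indeterminate", False)


def boxplot_figure(groups: list[MaterialGroup], path=None):
    """Box plots of per-pellet DEI by material (mean marked with a cross)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    data = [g.dei_values for g in groups]
    ax.boxplot(data, tick_labels=[g.material for g in groups], showmeans=True)
    ax.set_ylabel("dual-energy index")
    ax.set_xlabel("pellet material")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
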