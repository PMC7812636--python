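"""Link networks and coupling density from pairwise-conditional GC.

A link i -> j is present when its asymptotic chi-squared p-value clears
alpha (uncorrected by default; with 29 exploratory models the study design
deliberately trades type-I control for sensitivity, and a Benjamini-
Hochberg option is provided for stricter use).  The between-subject density
is the fraction of the 18 possible directed links crossing the two-subject
partition that are present.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DyadNetworkResult",
    "threshold_links",
    "between_density",
    "within_density",
    "build_network",
    "link_prevalence",
    "compare_densities",
    "spearman_gc_vs_score",
]

BLOCK_A = (0, 1, 2)
BLOCK_B = (3, 4, 5)
N_BETWEEN = 18  # 2 directions x 3 x 3
N_WITHIN = 6  # 3 x 2 directed links inside one block


@dataclass
class DyadNetworkResult:
    """Thresholded 6x6 link network for one dyad/condition."""

    adjacency: np.ndarray  # boolean, diagonal False
    F_matrix: np.ndarray
    density_between: float
    density_within_a: float
    density_within_b: float
    condition: str = ""
    dyad_id: str = ""


def threshold_links(
    F_matrix: np.ndarray,
    pvalues: np.ndarray,
    alpha: float = 0.05,
    fdr: bool = False,
) -> np.ndarray:
    """Boolean adjacency: link present iff p < alpha (optionally after
    Benjamini-Hochberg adjustment of the off-diagonal p-values)."""
    F_matrix = np.asarray(F_matrix, dtype=float)
    pvalues = np.asarray(pvalues, dtype=float)
    if F_matrix.shape != pvalues.shape:
        raise ValueError("matrices must be conformable")
    p = pvalues.copy()
    off = ~np.eye(p.shape[0], dtype=bool)
    if fdr:
        flat = p[off]
        order = np.argsort(flat)
        m = flat.size
        ranked = flat[order] * m / (np.arange(m) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        adj_flat = np.empty_like(flat)
        adj_flat[order] = np.minimum(ranked, 1.0)
        p[off] = adj_flat
    adjacency = (p < alpha) & off & ~np.isnan(p)
    return adjacency


def between_density(adjacency: np.ndarray, partition: tuple = (BLOCK_A, BLOCK_B)) -> float:
    """Fraction of the 18 possible directed between-subject links present."""
    a, b = partition
    if sorted(list(a) + list(b)) != list(range(adjacency.shape[0])):
        raise ValueError("partition must split all nodes into two blocks")
    count = int(adjacency[np.ix_(a, b)].sum() + adjacency[np.ix_(b, a)].sum())
    return count / (2 * len(a) * len(b))


def within_density(adjacency: np.ndarray, block: tuple) -> float:
    """Fraction of directed links inside one subject's block present."""
    sub = adjacency[np.ix_(block, block)]
    possible = len(block) * (len(block) - 1)
    return int(sub.sum()) / possible


def build_network(
    F_matrix: np.ndarray,
    pvalues: np.ndarray,
    alpha: float = 0.05,
    condition: str = "",
    dyad_id: str = "",
    fdr: bool = False,
) -> DyadNetworkResult:
    adjacency = threshold_links(F_matrix, pvalues, alpha=alpha, fdr=fdr)
    return DyadNetworkResult(
        adjacency=adjacency,
        F_matrix=np.asarray(F_matrix, dtype=float),
        density_between=between_density(adjacency),
        density_within_a=within_density(adjacency, BLOCK_A),
        density_within_b=within_density(adjacency, BLOCK_B),
        condition=condition,
        dyad_id=dyad_id,
    )


def link_prevalence(adjacencies: list[np.ndarray]) -> np.ndarray:
    """Per-link fraction of dyads in which the link is significant."""
    if not adjacencies:
        raise ValueError("need at least one dyad")
    stack = np.stack([np.asarray(a, dtype=float) for a in adjacencies])
    return stack.mean(axis=0)


def compare_densities(density_table: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Compare coupling densities across conditions on paired dyads.

    ``density_table`` has one row per dyad and one column per condition.
    Three or more conditions: Friedman test with Dunn-Sidak-adjusted
    pairwise Wilcoxon post hocs; exactly two: Wilcoxon signed-rank.
    """
    table = density_table.dropna()
    n_dyads, n_cond = table.shape
    if n_dyads < 3:
        raise ValueError("need at least 3 paired dyads")
    if n_cond < 2:
        raise ValueError("need at least 2 conditions")
    report: dict = {"n_dyads": n_dyads, "conditions": list(table.columns)}
    if n_cond == 2:
        a, b = table.iloc[:, 0], table.iloc[:, 1]
        if np.allclose(a, b):
            report.update(test="wilcoxon", statistic=0.0, p=1.0)
        else:
            res = stats.wilcoxon(a, b)
            report.update(test="wilcoxon", statistic=float(res.statistic), p=float(res.pvalue))
        return report
    cols = [table.iloc[:, i].to_numpy() for i in range(n_cond)]
    if all(np.allclose(c, cols[0]) for c in cols[1:]):
        report.update(test="friedman", statistic=0.0, p=1.0, posthoc={})
        return report
    chi2, p = stats.friedmanchisquare(*cols)
    report.update(test="friedman", statistic=float(chi2), p=float(p))
    posthoc = {}
    m = n_cond * (n_cond - 1) // 2
    for i in range(n_cond):
        for j in range(i + 1, n_cond):
            key = f"{table.columns[i]} vs {table.columns[j]}"
            if np.allclose(cols[i], cols[j]):
                praw = 1.0
            else:
                praw = float(stats.wilcoxon(cols[i], cols[j]).pvalue)
            posthoc[key] = min(1.0, 1.0 - (1.0 - praw) ** m)  # Dunn-Sidak
    report["posthoc"] = posthoc
    return report


def spearman_gc_vs_score(gc_values, scores) -> tuple[float, float]:
    """Spearman rank correlation between dyad-level GC and performance."""
    gc_values = np.asarray(gc_values, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if gc_values.size != scores.size:
        raise ValueError("length mismatch")
    if gc_values.size < 5:
        raise ValueError("need at least 5 pairs")
    if np.ptp(gc_values) == 0 or np.ptp(scores) == 0:
        raise ValueError("constant input has no rank correlation")
    rho, p = stats.spearmanr(gc_values, scores)
    return float(rho), float(p)
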