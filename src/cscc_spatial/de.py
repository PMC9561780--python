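"""Two-group Wilcoxon rank-sum differential expression with marker filters.

Implements the marker-calling recipe common in single-cell toolkits:
per-gene two-sided rank-sum test on log-normalized expression, a
log2 fold change computed on de-logged means with a +1 pseudocount,
the fraction of expressing units per group, Benjamini-Hochberg
adjustment across all tested genes, and the strict filter

    |log2FC| > 0.25  AND  pct1 > 0.25  AND  adjusted p < 0.05.

Exact enumeration of the rank-sum null is used for small groups
(n1 + n2 <= 10); the tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

FC_THRESHOLD = 0.25
PCT_THRESHOLD = 0.25
ALPHA = 0.05
EXACT_MAX_N = 10


@dataclass(frozen=True)
class DEResult:
    gene: str
    log2fc: float
    pct1: float
    pct2: float
    p: float
    p_adj: float
    passes_filter: bool


def bh_adjust(p: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact rank-sum p by enumerating all group assignments.

    Handles ties through midranks; p = P(|W - E[W]| >= |w_obs - E[W]|)
    over all C(n1+n2, n1) assignments of the pooled values.
    """
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    mu = ranks.sum() * n1 / len(pooled)
    d_obs = abs(w_obs - mu)
    hits = total = 0
    for idx in combinations(range(len(pooled)), n1):
        w = ranks[list(idx)].sum()
        total += 1
        if abs(w - mu) >= d_obs - 1e-12:
            hits += 1
    return hits / total


def _ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) + len(y) <= EXACT_MAX_N:
        return _exact_ranksum_p(x, y)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):  # all tied: no evidence either way
        return 1.0
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(min(res.pvalue, 1.0))


def log2_fold_change(x1: np.ndarray, x2: np.ndarray) -> float:
    """log2((mean(expm1(x1)) + 1) / (mean(expm1(x2)) + 1)) on log-normalized data."""
    return float(np.log2((np.mean(np.expm1(x1)) + 1.0) / (np.mean(np.expm1(x2)) + 1.0)))


def de_test(
    expr: pd.DataFrame,
    group1: list,
    group2: list,
    fc_threshold: float = FC_THRESHOLD,
    pct_threshold: float = PCT_THRESHOLD,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Differential expression of group1 vs group2 over all genes.

    ``expr`` is a units x genes log-normalized table; ``group1``/``group2``
    are disjoint lists of unit ids, each with at least 2 members. Returns a
    DataFrame (gene, log2fc, pct1, pct2, p, p_adj, passes_filter) in gene
    order, with BH adjustment across all tested genes and the strict
    three-way filter applied.
    """
    g1, g2 = set(group1), set(group2)
    if g1 & g2:
        raise ValueError(f"groups overlap: {sorted(g1 & g2)[:5]}")
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 units")
    m1 = expr.loc[list(group1)].to_numpy()
    m2 = expr.loc[list(group2)].to_numpy()
    genes = list(expr.columns)
    if m1.shape[0] + m2.shape[0] <= EXACT_MAX_N:
        pvals = np.array([_exact_ranksum_p(m1[:, j], m2[:, j]) for j in range(len(genes))])
    else:
        pooled = np.vstack([m1, m2])
        tied = np.all(pooled == pooled[0], axis=0)
        pvals = np.ones(len(genes))
        if (~tied).any():
            with np.errstate(divide="ignore", invalid="ignore"):
                res = stats.mannwhitneyu(
                    m1[:, ~tied], m2[:, ~tied], alternative="two-sided", method="asymptotic"
                )
            pvals[~tied] = np.minimum(np.nan_to_num(res.pvalue, nan=1.0), 1.0)
    lfc = np.log2(
        (np.mean(np.expm1(m1), axis=0) + 1.0) / (np.mean(np.expm1(m2), axis=0) + 1.0)
    )
    pct1 = (m1 > 0).mean(axis=0)
    pct2 = (m2 > 0).mean(axis=0)
    p_adj = bh_adjust(pvals)
    passes = (np.abs(lfc) > fc_threshold) & (pct1 > pct_threshold) & (p_adj < alpha)
    return pd.DataFrame(
        {
            "gene": genes,
            "log2fc": lfc,
            "pct1": pct1,
            "pct2": pct2,
            "p": pvals,
            "p_adj": p_adj,
            "passes_filter": passes,
        }
    )


def markers_for(
    expr: pd.DataFrame,
    labels: pd.Series,
    mode: str = "one_vs_rest",
    pair: tuple | None = None,
    max_genes: int | None = None,
    **thresholds,
) -> dict[str, list[str]]:
    """Marker genes per label, filtered and sorted by log2fc descending.

    ``one_vs_rest`` compares each label against the union of all others;
    ``pairwise`` compares only the two labels given in ``pair``. Markers are
    the genes with ``passes_filter`` true and positive fold change in the
    target group, optionally truncated to ``max_genes``.
    """
    labels = labels.loc[expr.index]
    uniq = list(dict.fromkeys(labels))
    if len(uniq) < 2:
        raise ValueError("need at least 2 labels")
    counts = labels.value_counts()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"label(s) with < 2 units: {small}")
    if mode == "pairwise":
        if pair is None or len(pair) != 2:
            raise ValueError("pairwise mode requires pair=(label_a, label_b)")
        targets = [(pair[0], [pair[1]]), (pair[1], [pair[0]])]
    elif mode == "one_vs_rest":
        targets = [(lab, [o for o in uniq if o != lab]) for lab in uniq]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out: dict[str, list[str]] = {}
    for lab, rest in targets:
        ids1 = labels.index[labels == lab].tolist()
        ids2 = labels.index[labels.isin(rest)].tolist()
        res = de_test(expr, ids1, ids2, **thresholds)
        up = res[res.passes_filter & (res.log2fc > 0)].sort_values(
            "log2fc", ascending=False, kind="stable"
        )
        genes = up.gene.tolist()
        out[lab] = genes[:max_genes] if max_genes else genes
    return out
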