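"""Multimodal intersection analysis (MIA) and the myCAF region gate.

MIA maps cell types (defined by single-nucleus marker genes) onto spatial
regions (defined by region marker genes) by testing the overlap of the two
marker sets against a shared background gene universe with the exact
hypergeometric distribution. The enrichment p-value — the "MIA score";
smaller means stronger cell-type/region correspondence — is complemented by
a depletion p-value from the lower tail.

Because enrichment alone is unreliable in regions with low RNA abundance,
myofibroblastic cancer-associated fibroblast (myCAF) regions are called by
a conjunctive gate: a significant (BH-adjusted) myCAF enrichment p-value
AND high regional expression of a single specific marker gene (POSTN by
default, thresholded at a quantile of the per-region means).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust


@dataclass(frozen=True)
class MarkerSet:
    """Marker genes for one cell type (source='cell') or region (source='region')."""

    owner: str
    genes: frozenset[str]
    source: str = "cell"

    def __post_init__(self) -> None:
        if self.source not in {"cell", "region"}:
            raise ValueError(f"source must be 'cell' or 'region', got {self.source!r}")


@dataclass(frozen=True)
class MIAResult:
    cell_type: str
    region: str
    overlap_k: int
    m: int  # cell marker set size
    n: int  # region marker set size
    background_N: int
    p_enrich: float
    p_deplete: float

    @property
    def neg_log10_p(self) -> float:
        return float(-np.log10(self.p_enrich))


@dataclass(frozen=True)
class MyCAFGate:
    """Joint threshold for calling myCAF regions.

    ``mia_alpha`` applies to the BH-adjusted enrichment p; ``expr_quantile``
    is the quantile of per-region mean marker expression a region must
    exceed.
    """

    mia_alpha: float = 0.05
    marker_gene: str = "POSTN"
    expr_quantile: float = 0.75
    cell_type: str = "myCAF"

    def __post_init__(self) -> None:
        if not (0 < self.mia_alpha < 1):
            raise ValueError("mia_alpha must be in (0, 1)")
        if not (0 < self.expr_quantile < 1):
            raise ValueError("expr_quantile must be in (0, 1)")


def mia_test(cell_set: MarkerSet, region_set: MarkerSet, background_N: int) -> MIAResult:
    """Exact hypergeometric overlap test between two marker sets.

    With m cell markers, n region markers and k = |overlap| drawn from a
    background of N genes: p_enrich = P(X >= k), p_deplete = P(X <= k).
    """
    m, n = len(cell_set.genes), len(region_set.genes)
    k = len(cell_set.genes & region_set.genes)
    if background_N < max(m, n):
        raise ValueError(f"background N={background_N} smaller than a set (m={m}, n={n})")
    if k < m + n - background_N:
        raise ValueError(
            f"infeasible overlap: k={k} < m + n - N = {m + n - background_N}"
        )
    p_enrich = float(stats.hypergeom.sf(k - 1, background_N, m, n))
    p_deplete = float(stats.hypergeom.cdf(k, background_N, m, n))
    return MIAResult(
        cell_type=cell_set.owner,
        region=region_set.owner,
        overlap_k=k,
        m=m,
        n=n,
        background_N=background_N,
        p_enrich=min(p_enrich, 1.0),
        p_deplete=min(p_deplete, 1.0),
    )


def mia_matrix(
    cell_sets: list[MarkerSet], region_sets: list[MarkerSet], background_N: int
) -> pd.DataFrame:
    """All pairwise MIA tests with BH adjustment across the whole grid.

    Returns a long-format DataFrame (cell_type, region, k, m, n, N,
    p_enrich, p_deplete, p_enrich_adj, neg_log10_p).
    """
    for sets, kind in ((cell_sets, "cell"), (region_sets, "region")):
        if not sets:
            raise ValueError(f"no {kind} marker sets supplied")
        owners = [s.owner for s in sets]
        if len(set(owners)) != len(owners):
            raise ValueError(f"duplicate {kind} owners: {owners}")
    rows = []
    for cs in cell_sets:
        for rs in region_sets:
            r = mia_test(cs, rs, background_N)
            rows.append(
                {
                    "cell_type": r.cell_type,
                    "region": r.region,
                    "k": r.overlap_k,
                    "m": r.m,
                    "n": r.n,
                    "N": r.background_N,
                    "p_enrich": r.p_enrich,
                    "p_deplete": r.p_deplete,
                }
            )
    df = pd.DataFrame(rows)
    df["p_enrich_adj"] = bh_adjust(df["p_enrich"].to_numpy())
    df["neg_log10_p"] = -np.log10(df["p_enrich"])
    return df


def call_mycaf_regions(
    mia: pd.DataFrame,
    expr: pd.DataFrame,
    region_of_unit: pd.Series,
    gate: MyCAFGate = MyCAFGate(),
) -> pd.DataFrame:
    """Flag regions passing the joint MIA + marker-expression myCAF gate.

    ``mia`` is the grid from :func:`mia_matrix`; ``expr`` the units x genes
    log-normalized table; ``region_of_unit`` maps unit id -> region id. A
    region is flagged iff its adjusted myCAF enrichment p < ``gate.mia_alpha``
    AND its mean marker expression exceeds the ``gate.expr_quantile``
    quantile of all per-region means. Both conditions are reported per
    region.
    """
    if gate.marker_gene not in expr.columns:
        raise ValueError(f"marker gene {gate.marker_gene!r} absent from expression table")
    sub = mia[mia.cell_type == gate.cell_type]
    if sub.empty:
        raise ValueError(f"cell type {gate.cell_type!r} absent from the MIA grid")
    region_of_unit = region_of_unit.loc[expr.index]
    region_means = (
        expr[gate.marker_gene].groupby(region_of_unit).mean().rename("marker_mean")
    )
    threshold = float(region_means.quantile(gate.expr_quantile))
    rows = []
    for _, r in sub.iterrows():
        mean = float(region_means.get(r.region, np.nan))
        mia_ok = bool(r.p_enrich_adj < gate.mia_alpha)
        expr_ok = bool(mean > threshold) if np.isfinite(mean) else False
        rows.append(
            {
                "region": r.region,
                "p_enrich_adj": r.p_enrich_adj,
                "mia_pass": mia_ok,
                "marker_mean": mean,
                "marker_threshold": threshold,
                "expr_pass": expr_ok,
                "flagged": mia_ok and expr_ok,
            }
        )
    return pd.DataFrame(rows)
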