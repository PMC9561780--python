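"""Gene-signature scoring for bins or cells.

Two engines are provided:

* :func:`module_score` — the control-matched module score popularized by
  Tirosh-style single-cell scoring: each signature gene is matched with
  control genes drawn from the same average-expression bin, and the score
  is the mean signature expression minus the mean control expression.
  Robust to per-unit depth and to additive shifts.
* :func:`ssgsea_score` — a single-sample, rank-based running-sum
  enrichment statistic (ssGSEA style): genes are ranked by expression
  within the unit and the score integrates the difference between the
  weighted in-set and unweighted out-of-set empirical CDFs. Invariant to
  any strictly monotone transform of the expression vector.

Both operate on a log-normalized units x genes DataFrame as produced by
:func:`cscc_spatial.spatial.log_normalize`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class GeneSignature:
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"signature {self.name!r} is empty")

    @staticmethod
    def of(name: str, genes) -> "GeneSignature":
        return GeneSignature(name=name, genes=frozenset(genes))


def read_gmt(path: str | Path) -> list[GeneSignature]:
    """Read a GMT signature file (name, description, tab-separated genes)."""
    sigs = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"GMT line has fewer than 3 fields: {line!r}")
        sigs.append(GeneSignature.of(parts[0], [g for g in parts[2:] if g]))
    return sigs


def write_gmt(signatures: list[GeneSignature], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sig in signatures:
            fh.write("\t".join([sig.name, "na", *sorted(sig.genes)]) + "\n")


def module_score(
    expr: pd.DataFrame,
    sig: GeneSignature,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Control-matched module score per unit.

    Genes are ranked by mean expression across units and cut into
    ``n_bins`` expression bins of near-equal size; for every signature
    gene, ``n_ctrl`` control genes are drawn with replacement from its
    bin, and score(unit) = mean signature expression - mean control
    expression. Fully reproducible from ``seed``.
    """
    present = [g for g in expr.columns if g in sig.genes]
    if not present:
        raise ValueError(
            f"no gene of signature {sig.name!r} present in the expression table; "
            f"missing: {sorted(sig.genes)[:10]}..."
        )
    if expr.shape[1] <= n_bins:
        raise ValueError(f"need more than n_bins={n_bins} genes, got {expr.shape[1]}")
    mean_expr = expr.mean(axis=0)
    # stable rank: ties broken by column order
    order = np.argsort(mean_expr.to_numpy(), kind="stable")
    bin_of = np.empty(expr.shape[1], dtype=np.int64)
    bin_of[order] = np.floor(np.arange(expr.shape[1]) * n_bins / expr.shape[1]).astype(np.int64)
    bin_members = {b: np.flatnonzero(bin_of == b) for b in range(n_bins)}
    col_index = {g: i for i, g in enumerate(expr.columns)}

    rng = np.random.default_rng(seed)
    ctrl_cols: list[int] = []
    for g in present:
        members = bin_members[bin_of[col_index[g]]]
        ctrl_cols.extend(rng.choice(members, size=n_ctrl, replace=True))
    vals = expr.to_numpy()
    sig_mean = vals[:, [col_index[g] for g in present]].mean(axis=1)
    ctrl_mean = vals[:, ctrl_cols].mean(axis=1)
    return pd.Series(sig_mean - ctrl_mean, index=expr.index, name=sig.name)


def ssgsea_score(expr_vector: pd.Series, sig: GeneSignature, alpha: float = 0.25) -> float:
    """Single-sample rank-based enrichment score for one unit.

    Genes are sorted by expression descending (ties broken by stable gene
    order); with in-set weights rank^alpha (rank = number of genes minus
    descending position, so the top gene carries the largest weight), the
    score is sum_i [P_in(i) - P_out(i)] / N where P_in is the weighted
    in-set ECDF and P_out the unweighted out-of-set ECDF.
    """
    genes = expr_vector.index
    n = len(genes)
    in_set = np.fromiter((g in sig.genes for g in genes), dtype=bool, count=n)
    n_in = int(in_set.sum())
    if n_in == 0:
        raise ValueError(f"no gene of signature {sig.name!r} in the expression vector")
    if n_in == n:
        raise ValueError("signature covers the entire gene universe; out-set is empty")
    order = np.argsort(-expr_vector.to_numpy(), kind="stable")
    in_sorted = in_set[order]
    rank_stat = (n - np.arange(n)).astype(float)  # N down to 1 along the sort
    w = np.where(in_sorted, rank_stat**alpha, 0.0)
    p_in = np.cumsum(w) / w.sum()
    p_out = np.cumsum(~in_sorted) / (n - n_in)
    return float((p_in - p_out).sum() / n)


def score_matrix(
    expr: pd.DataFrame,
    registry: list[GeneSignature],
    engine: str = "module",
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Score every signature in the registry; columns follow registry order.

    ``engine`` selects :func:`module_score` (one seeded control draw per
    signature) or :func:`ssgsea_score` (applied per unit row).
    """
    if not registry:
        raise ValueError("empty signature registry")
    names = [s.name for s in registry]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate signature names in registry: {names}")
    if engine not in {"module", "ssgsea"}:
        raise ValueError(f"unknown engine {engine!r}; choose 'module' or 'ssgsea'")
    out = pd.DataFrame(index=expr.index)
    if expr.empty:
        for nm in names:
            out[nm] = pd.Series(dtype=float)
        return out
    for i, sig in enumerate(registry):
        if engine == "module":
            out[sig.name] = module_score(expr, sig, seed=seed + i, **kwargs)
        else:
            out[sig.name] = expr.apply(lambda row: ssgsea_score(row, sig, **kwargs), axis=1)
    return out
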