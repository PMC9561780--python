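"""Composite metabolic scoring and hyper/hypometabolic classification.

Tumor areas (connected components of tumor-annotated bins, or supplied
ids) receive six pathway activity scores — hypoxia, lactic acid,
glycolysis, lipid metabolism, pentose phosphate, oxidative
phosphorylation — averaged over their member bins. The composite
metabolic score of an area is the arithmetic mean of the six pathway
scores; areas ranked in the top k are called hypermetabolic, the bottom
k hypometabolic, everything between intermediate. Immune-signature
abundance can then be contrasted between the two classes per signature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .de import _exact_ranksum_p

METABOLIC_PATHWAYS = (
    "hypoxia",
    "lactic_acid",
    "glycolysis",
    "lipid_metabolism",
    "pentose_phosphate",
    "oxidative_phosphorylation",
)

_STAR_BOUNDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    for bound, stars in _STAR_BOUNDS:
        if p < bound:
            return stars
    return "ns"


@dataclass(frozen=True)
class TumorArea:
    area_id: str
    bin_ids: tuple[str, ...]
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not self.bin_ids:
            raise ValueError(f"tumor area {self.area_id!r} has no bins")


@dataclass
class MetabolicCall:
    area_id: str
    pathway_scores: dict[str, float]
    metabolic_score: float
    rank: int = 0
    label: str = "intermediate"
    degenerate: bool = field(default=False)


def find_tumor_areas(annotations: pd.DataFrame, region_label: str = "tumor") -> list[TumorArea]:
    """Tumor areas as 8-connected components of tumor-annotated bins.

    ``annotations`` needs columns bin_id, bx, by, region. When an
    ``area_id`` column is present it is used directly instead.
    """
    tumor = annotations[annotations.region == region_label]
    if "area_id" in tumor.columns and tumor["area_id"].notna().all() and len(tumor):
        return [
            TumorArea(area_id=str(aid), bin_ids=tuple(g.bin_id))
            for aid, g in tumor.groupby("area_id", sort=True)
        ]
    coords = {(int(r.bx), int(r.by)): r.bin_id for r in tumor.itertuples()}
    seen: set[tuple[int, int]] = set()
    areas = []
    for start in sorted(coords):
        if start in seen:
            continue
        stack, comp = [start], []
        seen.add(start)
        while stack:
            cx, cy = stack.pop()
            comp.append(coords[(cx, cy)])
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    nb = (cx + dx, cy + dy)
                    if nb in coords and nb not in seen:
                        seen.add(nb)
                        stack.append(nb)
        areas.append(TumorArea(area_id=f"area_{len(areas)}", bin_ids=tuple(sorted(comp))))
    return areas


def area_pathway_scores(
    scores: pd.DataFrame, areas: list[TumorArea], pathways: tuple[str, ...] = METABOLIC_PATHWAYS
) -> pd.DataFrame:
    """Mean pathway score per area (rows = areas, columns = pathways)."""
    missing = [p for p in pathways if p not in scores.columns]
    if missing:
        raise ValueError(f"score table lacks pathway column(s): {missing}")
    rows = {}
    for area in areas:
        absent = [b for b in area.bin_ids if b not in scores.index]
        if absent:
            raise ValueError(f"area {area.area_id!r}: bins missing from score table: {absent[:5]}")
        rows[area.area_id] = scores.loc[list(area.bin_ids), list(pathways)].mean(axis=0)
    return pd.DataFrame(rows).T


def classify_metabolic(area_scores: pd.DataFrame, k: int = 20) -> list[MetabolicCall]:
    """Rank areas by composite metabolic score; top k hyper, bottom k hypo.

    The composite score is the arithmetic mean of the pathway columns. Ties
    are broken by area_id (ascending, stable). If fewer than 2k areas are
    available, k shrinks to floor(n/2) with a warning. A run where every
    area has an identical score is flagged degenerate on every call.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    n = len(area_scores)
    if n < 2:
        raise ValueError("need at least 2 areas to classify")
    if n < 2 * k:
        k = n // 2
        warnings.warn(f"fewer than 2k areas; shrinking k to {k}", stacklevel=2)
    composite = area_scores.mean(axis=1)
    order = sorted(composite.index, key=lambda a: (-composite[a], a))
    degenerate = bool(np.all(composite.to_numpy() == composite.iloc[0]))
    calls = []
    for rank, aid in enumerate(order, start=1):
        label = "hyper" if rank <= k else ("hypo" if rank > n - k else "intermediate")
        calls.append(
            MetabolicCall(
                area_id=aid,
                pathway_scores=area_scores.loc[aid].to_dict(),
                metabolic_score=float(composite[aid]),
                rank=rank,
                label=label,
                degenerate=degenerate,
            )
        )
    return calls


def contrast_immune(
    hyper_scores: pd.DataFrame,
    hypo_scores: pd.DataFrame,
    test: str = "ranksum",
) -> pd.DataFrame:
    """Per-signature comparison of per-area immune scores, hyper vs hypo.

    Inputs are areas x immune-signature tables (one row per area, as from
    :func:`area_pathway_scores` run on immune signatures). ``test`` selects
    the engine: unpaired two-sided Wilcoxon rank-sum (default), paired
    signed-rank, Welch t, or Kruskal-Wallis. Returns one row per signature
    with statistic, p, direction and significance stars.
    """
    if len(hyper_scores) < 2 or len(hypo_scores) < 2:
        raise ValueError("need at least 2 areas per class")
    if list(hyper_scores.columns) != list(hypo_scores.columns):
        raise ValueError("hyper and hypo tables must share signature columns")
    rows = []
    for sig in hyper_scores.columns:
        a = hyper_scores[sig].to_numpy(dtype=float)
        b = hypo_scores[sig].to_numpy(dtype=float)
        if np.array_equal(np.sort(a), np.sort(b)):
            stat, p = 0.0, 1.0
        elif test == "ranksum":
            stat = float(stats.mannwhitneyu(a, b, alternative="two-sided").statistic)
            # exact enumeration (tie-aware) for small groups, normal approx otherwise
            if len(a) + len(b) <= 12:
                p = _exact_ranksum_p(a, b)
            else:
                p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        elif test == "signedrank":
            if len(a) != len(b):
                raise ValueError("signedrank is paired and needs equal group sizes")
            stat, p = stats.wilcoxon(a, b)
        elif test == "ttest":
            stat, p = stats.ttest_ind(a, b, equal_var=False)
        elif test == "kruskal":
            stat, p = stats.kruskal(a, b)
        else:
            raise ValueError(f"unknown test {test!r}")
        d = float(np.median(a) - np.median(b))
        rows.append(
            {
                "signature": sig,
                "n_hyper": len(a),
                "n_hypo": len(b),
                "statistic": float(stat),
                "p": float(p),
                "direction": "none" if p == 1.0 and d == 0 else ("up_in_hyper" if d > 0 else "up_in_hypo" if d < 0 else "none"),
                "stars": significance_stars(float(p)),
            }
        )
    return pd.DataFrame(rows)
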