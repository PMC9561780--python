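"""End-to-end planted-structure recovery experiments.

These functions wire the synthetic generators into the analysis stages
and measure how well each stage recovers what was planted: cell-type
markers, the hyper/hypometabolic split, the myCAF annuli, and the type-I
error of the IHC association pipeline. They define the study conditions
used by the test suite and the acceptance script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import synthetic
from .de import markers_for
from .metabolic import METABOLIC_PATHWAYS, TumorArea, area_pathway_scores, classify_metabolic
from .mia import MarkerSet, MyCAFGate, call_mycaf_regions, mia_matrix
from .scoring import score_matrix
from .spatial import BinSpec, bin_spots, log_normalize, qc_bins


def _normalized_bins(spots, truth, bin_size: int, min_umi: int):
    """Bin, attach majority-vote truth, QC, and log-normalize."""
    binmat = bin_spots(spots, BinSpec(bin_size))
    ann = synthetic.bin_truth(truth, bin_size).set_index("bin_id")
    binmat.annotations = ann.loc[binmat.bin_ids()].reset_index()
    binmat, _ = qc_bins(binmat, min_umi=min_umi, min_median_genes=0)
    expr = log_normalize(binmat)
    ann = binmat.annotations.set_index("bin_id").loc[expr.index]
    return expr, ann


def marker_recovery(seed: int, n_per_type: int = 150, n_genes: int = 400) -> float:
    """Sensitivity of marker recovery on synthetic cells (min across types)."""
    uni = synthetic.default_universe(n_genes=n_genes, seed=seed)
    counts, labels = synthetic.simulate_cells(uni.cell_specs, uni.genes, n_per_type, seed=seed)
    expr = np.log1p(counts * 1e4 / counts.sum(axis=1).to_numpy()[:, None])
    found = markers_for(expr, labels)
    sens = [
        len(set(found[ct]) & uni.marker_sets[ct]) / len(uni.marker_sets[ct])
        for ct in uni.marker_sets
    ]
    return float(min(sens))


def metabolic_recovery(
    seed: int,
    n_tumors: int = 12,
    pathway_fold: float = 4.0,
    n_genes: int = 400,
    bin_size: int = 4,
) -> float:
    """Accuracy of the hyper/hypo classification against the planted split."""
    uni = synthetic.default_universe(n_genes=n_genes, seed=seed)
    layout = synthetic.make_layout(
        width=96, height=96, n_tumors=n_tumors, ringed_tumors=(), n_inflammation=1, seed=seed
    )
    hyper = frozenset(range(n_tumors // 2))
    hypo = frozenset(range(n_tumors // 2, n_tumors))
    plant = synthetic.MetabolicPlant(hyper, hypo, pathway_fold=pathway_fold)
    spots, truth = synthetic.simulate_chip(
        layout, uni.cell_specs, uni.genes, plant=plant,
        pathway_signatures=uni.pathway_signatures, seed=seed,
    )
    expr, ann = _normalized_bins(spots, truth, bin_size, min_umi=20)
    scores = score_matrix(expr, uni.pathway_signatures, engine="ssgsea")
    tumor_bins = ann[ann.region == "tumor"]
    areas = [
        TumorArea(area_id=str(aid), bin_ids=tuple(g.index))
        for aid, g in tumor_bins.groupby("area_id")
        if len(g) >= 1
    ]
    area_scores = area_pathway_scores(scores, areas, pathways=METABOLIC_PATHWAYS)
    calls = classify_metabolic(area_scores, k=len(hyper))
    correct = sum(
        1
        for c in calls
        if (int(c.area_id) in hyper and c.label == "hyper")
        or (int(c.area_id) in hypo and c.label == "hypo")
    )
    return correct / len(calls)


def _mia_pipeline(
    seed: int,
    n_tumors: int = 5,
    ringed: tuple[int, ...] = (0, 1),
    n_genes: int = 400,
    bin_size: int = 2,  # analysis unit must not exceed the annulus width
    n_cells_per_type: int = 80,
    gate: MyCAFGate | None = None,
) -> dict:
    """Chip + cells -> marker sets -> MIA grid -> myCAF gate, with truth."""
    uni = synthetic.default_universe(n_genes=n_genes, seed=seed)
    layout = synthetic.make_layout(
        width=120, height=120, n_tumors=n_tumors, ringed_tumors=ringed,
        ring_width=2, n_inflammation=1, seed=seed,
    )
    spots, truth = synthetic.simulate_chip(layout, uni.cell_specs, uni.genes, seed=seed)
    expr, ann = _normalized_bins(spots, truth, bin_size, min_umi=20)

    counts, labels = synthetic.simulate_cells(
        uni.cell_specs, uni.genes, n_cells_per_type, seed=seed + 1
    )
    cell_expr = np.log1p(counts * 1e4 / counts.sum(axis=1).to_numpy()[:, None])
    cell_markers = markers_for(cell_expr, labels, max_genes=100)

    # regions with at least 2 bins are testable
    region_counts = ann.region_id.value_counts()
    keep = ann.region_id.isin(region_counts[region_counts >= 2].index)
    expr, ann = expr.loc[keep.to_numpy()], ann.loc[keep.to_numpy()]
    region_markers = markers_for(expr, ann.region_id, max_genes=100)

    detected_cells = set(counts.columns[(counts > 0).any(axis=0)])
    detected_bins = set(expr.columns[(expr > 0).any(axis=0)])
    background = detected_cells & detected_bins
    cell_sets = [
        MarkerSet(owner=ct, genes=frozenset(g) & frozenset(background), source="cell")
        for ct, g in cell_markers.items()
    ]
    region_sets = [
        MarkerSet(owner=r, genes=frozenset(g) & frozenset(background), source="region")
        for r, g in region_markers.items()
        if g
    ]
    grid = mia_matrix(
        [c for c in cell_sets if c.genes], [r for r in region_sets if r.genes], len(background)
    )
    gate = gate or MyCAFGate(cell_type="mycaf")
    flags = call_mycaf_regions(grid, expr, ann.region_id, gate=gate)
    return {"grid": grid, "flags": flags, "ringed": ringed, "expr": expr, "ann": ann}


def mycaf_metrics(res: dict) -> tuple[float, float]:
    """Precision and recall of the gate from a :func:`_mia_pipeline` result."""
    flagged = set(res["flags"][res["flags"].flagged].region)
    true_rings = {f"mycaf_ring_{i}" for i in res["ringed"]}
    tp = len(flagged & true_rings)
    precision = tp / len(flagged) if flagged else (1.0 if not true_rings else 0.0)
    recall = tp / len(true_rings) if true_rings else 1.0
    return precision, recall


def mycaf_recovery(seed: int, **kwargs) -> tuple[float, float]:
    """Precision and recall of the joint MIA + POSTN gate on planted annuli."""
    return mycaf_metrics(_mia_pipeline(seed, **kwargs))


_HOME_REGION_PREFIX = {
    "cancer": "tumor",
    "fibroblast": "stroma",
    "immune": "inflammation",
    "mycaf": "mycaf_ring",
}


def mia_match_from_grid(grid) -> float:
    """Fraction of cell types whose minimum-p region is their home region.

    Home regions: cancer -> tumor areas, fibroblast -> stroma,
    immune -> inflammation, myCAF -> the planted annuli (epithelial has no
    home region in the default layout and is not scored).
    """
    hits = total = 0
    for ct, prefix in _HOME_REGION_PREFIX.items():
        rows = grid[grid.cell_type == ct]
        if rows.empty:
            continue
        best = rows.loc[rows.p_enrich_adj.idxmin()]
        total += 1
        hits += int(str(best.region).startswith(prefix))
    return hits / total if total else 0.0


def mia_match_rate(seed: int, **kwargs) -> float:
    """Home-region match rate for one simulated chip (see
    :func:`mia_match_from_grid`)."""
    return mia_match_from_grid(_mia_pipeline(seed, **kwargs)["grid"])


def ihc_type1_error(
    n_seeds: int = 500, n: int = 120, alpha: float = 0.05, base_seed: int = 0
) -> float:
    """Rejection rate of the stage association test under a null cohort."""
    from .ihc import table1_report

    rejections = 0
    for s in range(n_seeds):
        records = synthetic.simulate_ihc_cohort(n=n, effect=0.0, seed=base_seed + s)
        report = table1_report(records, covariates=("stage",))
        rejections += int(report.iloc[0].p < alpha)
    return rejections / n_seeds


def ihc_power(
    n_seeds: int = 100, n: int = 200, effect: float = 2.0, alpha: float = 0.05, base_seed: int = 0
) -> float:
    """Rejection rate of the stage association test under a planted effect."""
    from .ihc import table1_report

    rejections = 0
    for s in range(n_seeds):
        records = synthetic.simulate_ihc_cohort(
            n=n, effect=effect, seed=base_seed + s, baseline_logit=-2.0
        )
        report = table1_report(records, covariates=("stage",))
        rejections += int(report.iloc[0].p < alpha)
    return rejections / n_seeds
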