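"""End-to-end pipeline: simulate -> bin -> score -> classify -> MIA ->
myCAF gate -> DE -> HPV -> IHC, with a checksummed manifest.

Each stage writes diff-able TSV/JSON outputs into the run directory and
registers them in ``manifest.json`` together with a SHA-256 checksum, the
full configuration echo and the master seed. Per-stage child seeds are
derived deterministically (splitmix), so re-running a stage in isolation
reproduces its slice of a full run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic
from ._rng import child_seed
from .de import de_test, markers_for
from .hpv import CoverageProfile, call_hpv, summarize_typing
from .ihc import table1_report
from .metabolic import (
    METABOLIC_PATHWAYS,
    TumorArea,
    area_pathway_scores,
    classify_metabolic,
    contrast_immune,
)
from .mia import MarkerSet, MyCAFGate, call_mycaf_regions, mia_matrix
from .scoring import score_matrix, write_gmt
from .spatial import (
    BinSpec,
    ChipGeometry,
    bin_spots,
    log_normalize,
    physical_bin_edge,
    qc_bins,
    read_gem,
    write_bin_matrix,
    write_gem,
)

log = logging.getLogger("cscc_spatial.pipeline")


@dataclass
class RunConfig:
    """Configuration for a full synthetic-data pipeline run."""

    seed: int = 0
    outdir: str = "cscc_run"
    # chip
    width: int = 120
    height: int = 120
    n_tumors: int = 5
    ringed_tumors: tuple[int, ...] = (0, 1)
    n_genes: int = 400
    n_cells_per_type: int = 80
    pathway_fold: float = 4.0
    # binning / QC
    bin_size: int = 4
    min_umi: int = 20
    min_median_genes: int = 0
    # geometry (for the manifest's physical bin edge)
    spot_diameter_nm: float = 220.0
    pitch_nm: float = 500.0
    # classification / gating
    k: int = 2
    contrast_test: str = "ranksum"
    mia_alpha: float = 0.05
    marker_gene: str = "POSTN"
    expr_quantile: float = 0.75
    # HPV cohort
    hpv_genome_len: int = 7906
    n_hpv_samples: int = 14

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns the manifest dict (also written to disk)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": {}, "outputs": {}}
    t0 = time.time()

    def register(stage: str, *paths: Path) -> None:
        manifest["stages"].setdefault(stage, [])
        for p in paths:
            manifest["stages"][stage].append(p.name)
            manifest["outputs"][p.name] = _sha256(p)
        log.info("[%.1fs] stage %s: %d file(s)", time.time() - t0, stage, len(paths))

    def stage_seed(name: str) -> int:
        return child_seed(config.seed, name)

    try:
        # ---- simulate ------------------------------------------------
        uni = synthetic.default_universe(n_genes=config.n_genes, seed=stage_seed("universe"))
        layout = synthetic.make_layout(
            width=config.width,
            height=config.height,
            n_tumors=config.n_tumors,
            ringed_tumors=config.ringed_tumors,
            seed=stage_seed("layout"),
        )
        n_half = config.n_tumors // 2
        plant = synthetic.MetabolicPlant(
            frozenset(range(n_half)),
            frozenset(range(n_half, config.n_tumors)),
            pathway_fold=config.pathway_fold,
        )
        spots, truth = synthetic.simulate_chip(
            layout,
            uni.cell_specs,
            uni.genes,
            plant=plant,
            pathway_signatures=uni.pathway_signatures,
            seed=stage_seed("chip"),
        )
        write_gem(spots, out / "chip.gem.tsv")
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        write_gmt(uni.pathway_signatures + uni.immune_signatures, out / "signatures.gmt")
        (out / "config_echo.json").write_text(json.dumps(config.to_dict(), indent=2))
        register(
            "simulate", out / "chip.gem.tsv", out / "truth.tsv", out / "signatures.gmt",
            out / "config_echo.json",
        )

        # ---- bin + QC ------------------------------------------------
        spots2 = read_gem(out / "chip.gem.tsv")
        binmat = bin_spots(spots2, BinSpec(config.bin_size))
        ann = synthetic.bin_truth(truth, config.bin_size).set_index("bin_id")
        binmat.annotations = ann.loc[binmat.bin_ids()].reset_index()
        binmat, qc_report = qc_bins(
            binmat, min_umi=config.min_umi, min_median_genes=config.min_median_genes
        )
        geometry = ChipGeometry(config.spot_diameter_nm, config.pitch_nm)
        qc_report["physical_bin_edge_um"] = physical_bin_edge(config.bin_size, geometry)
        qc_report["physical_bin_edge_um_bin100"] = physical_bin_edge(100, geometry)
        write_bin_matrix(binmat, out / "bins")
        (out / "qc_report.json").write_text(json.dumps(qc_report, indent=2))
        manifest["physical_bin_edge_um"] = qc_report["physical_bin_edge_um"]
        manifest["physical_bin_edge_um_bin100"] = qc_report["physical_bin_edge_um_bin100"]
        register("bin", out / "bins" / "counts.mtx", out / "bins" / "bins.tsv",
                 out / "bins" / "genes.tsv", out / "qc_report.json")

        # ---- score ---------------------------------------------------
        expr = log_normalize(binmat)
        ann = binmat.annotations.set_index("bin_id").loc[expr.index]
        pathway_scores = score_matrix(expr, uni.pathway_signatures, engine="ssgsea")
        immune_scores = score_matrix(
            expr, uni.immune_signatures, engine="module", seed=stage_seed("module_score")
        )
        scores = pd.concat([pathway_scores, immune_scores], axis=1)
        scores.rename_axis("bin_id").reset_index().pipe(_write_tsv, out / "signature_scores.tsv")
        register("score", out / "signature_scores.tsv")

        # ---- classify ------------------------------------------------
        tumor_bins = ann[ann.region == "tumor"]
        areas = [
            TumorArea(area_id=str(aid), bin_ids=tuple(g.index))
            for aid, g in tumor_bins.groupby("area_id")
        ]
        area_scores = area_pathway_scores(pathway_scores, areas, pathways=METABOLIC_PATHWAYS)
        calls = classify_metabolic(area_scores, k=config.k)
        calls_df = pd.DataFrame(
            [
                {"area_id": c.area_id, "metabolic_score": c.metabolic_score,
                 "rank": c.rank, "label": c.label, **c.pathway_scores}
                for c in calls
            ]
        )
        _write_tsv(calls_df, out / "metabolic_calls.tsv")
        hyper_ids = [c.area_id for c in calls if c.label == "hyper"]
        hypo_ids = [c.area_id for c in calls if c.label == "hypo"]
        imm_cols = [s.name for s in uni.immune_signatures]
        area_immune = area_pathway_scores(immune_scores, areas, pathways=tuple(imm_cols))
        contrast = contrast_immune(
            area_immune.loc[hyper_ids], area_immune.loc[hypo_ids], test=config.contrast_test
        )
        _write_tsv(contrast, out / "immune_contrast.tsv")
        register("classify", out / "metabolic_calls.tsv", out / "immune_contrast.tsv")

        # ---- DE: region markers -------------------------------------
        region_counts = ann.region_id.value_counts()
        ok = ann.region_id.isin(region_counts[region_counts >= 2].index).to_numpy()
        expr_ok, ann_ok = expr.loc[ok], ann.loc[ok]
        region_markers = markers_for(expr_ok, ann_ok.region_id, max_genes=100)
        rows = [
            {"region": r, "n_markers": len(g), "markers": ",".join(g)}
            for r, g in region_markers.items()
        ]
        _write_tsv(pd.DataFrame(rows), out / "region_markers.tsv")
        register("de", out / "region_markers.tsv")

        # ---- MIA + myCAF gate ---------------------------------------
        cells, labels = synthetic.simulate_cells(
            uni.cell_specs, uni.genes, config.n_cells_per_type, seed=stage_seed("cells")
        )
        cell_expr = np.log1p(cells * 1e4 / cells.sum(axis=1).to_numpy()[:, None])
        cell_markers = markers_for(cell_expr, labels, max_genes=100)
        background = sorted(
            set(cells.columns[(cells > 0).any(axis=0)])
            & set(expr.columns[(expr > 0).any(axis=0)])
        )
        bg = frozenset(background)
        cell_sets = [
            MarkerSet(ct, frozenset(g) & bg, "cell") for ct, g in cell_markers.items()
        ]
        region_sets = [
            MarkerSet(r, frozenset(g) & bg, "region") for r, g in region_markers.items()
        ]
        grid = mia_matrix(
            [c for c in cell_sets if c.genes],
            [r for r in region_sets if r.genes],
            len(background),
        )
        _write_tsv(grid, out / "mia_grid.tsv")
        gate = MyCAFGate(
            mia_alpha=config.mia_alpha,
            marker_gene=config.marker_gene,
            expr_quantile=config.expr_quantile,
            cell_type="mycaf",
        )
        flags = call_mycaf_regions(grid, expr_ok, ann_ok.region_id, gate=gate)
        _write_tsv(flags, out / "mycaf_regions.tsv")
        register("mia", out / "mia_grid.tsv", out / "mycaf_regions.tsv")

        # ---- DE: myCAF+ vs myCAF- tumor bins ------------------------
        flagged_areas = {
            r.split("_")[-1] for r in flags[flags.flagged].region if r.startswith("mycaf_ring")
        }
        tumor_ok = ann_ok[ann_ok.region == "tumor"]
        pos_bins = tumor_ok.index[tumor_ok.area_id.astype(str).isin(flagged_areas)].tolist()
        neg_bins = tumor_ok.index[~tumor_ok.area_id.astype(str).isin(flagged_areas)].tolist()
        if len(pos_bins) >= 2 and len(neg_bins) >= 2:
            de = de_test(expr_ok, pos_bins, neg_bins)
            _write_tsv(de, out / "mycaf_de.tsv")
            up = int((de.passes_filter & (de.log2fc > 0)).sum())
            down = int((de.passes_filter & (de.log2fc < 0)).sum())
            manifest["mycaf_de"] = {"up": up, "down": down, "total": up + down}
            register("mycaf_de", out / "mycaf_de.tsv")

        # ---- HPV ----------------------------------------------------
        rng = np.random.default_rng(stage_seed("hpv"))
        calls_by_sample = {}
        type_of = ["HPV16"] * 12 + ["HPV33", "HPV58"]
        for i in range(config.n_hpv_samples):
            t = type_of[i % len(type_of)]
            frac = float(rng.uniform(0.08, 1.0))
            depth = synthetic.simulate_viral_depth(
                config.hpv_genome_len, frac, mean_depth=float(rng.uniform(60, 300)),
                seed=stage_seed(f"hpv_{i}"),
            )
            calls_by_sample[f"P{i:02d}"] = [call_hpv(CoverageProfile(t, depth))]
        prevalence = summarize_typing(calls_by_sample)
        _write_tsv(prevalence, out / "hpv_prevalence.tsv")
        register("hpv", out / "hpv_prevalence.tsv")

        # ---- IHC ----------------------------------------------------
        cohort = synthetic.simulate_ihc_cohort(n=71, effect=1.2, seed=stage_seed("ihc"))
        report = table1_report(cohort)
        _write_tsv(report, out / "ihc_report.tsv")
        register("ihc", out / "ihc_report.tsv")
    except Exception as exc:  # structured stage failure; prior outputs stay
        failed = len(manifest["stages"])
        (out / "error.json").write_text(
            json.dumps({"failed_after_stages": list(manifest["stages"]), "error": str(exc)})
        )
        log.error("pipeline failed after %d stage(s): %s", failed, exc)
        raise

    manifest["elapsed_s"] = round(time.time() - t0, 2)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
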