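"""Synthetic data with planted structure for every pipeline stage.

The generators emulate the statistical shape of a cervical squamous cell
carcinoma (CSCC) spatial + single-nucleus study:

* negative-binomial cell-by-gene counts with cell-type-specific marker
  elevation (stand-in for snRNA-seq);
* a spatial chip with contiguous regions — tumor blobs, stroma,
  inflammation patches, optional gland, and 1-3-spot-wide myCAF annuli
  ("ribbons") around a configurable subset of tumors — where each spot
  draws counts from the region's cell-type mixture scaled by a per-region
  RNA-abundance factor (tumors richer than stroma);
* planted hypermetabolic tumor areas in which the six metabolic pathway
  gene sets are elevated by a known fold;
* per-base viral-genome depth vectors with exact coverage control;
* an IHC cohort whose composite-score dichotomy depends on pathologic
  stage through a chosen log-odds.

Everything is reproducible from an integer seed. Counts use the
mean/dispersion NB parameterization var = mu + mu^2/theta (Poisson as
theta -> infinity), drawn as a gamma-Poisson mixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .ihc import IHCRecord
from .metabolic import METABOLIC_PATHWAYS
from .scoring import GeneSignature
from .spatial import ChipGeometry, SpotMatrix

REGION_LABELS = ("tumor", "stroma", "inflammation", "mycaf_ring", "gland", "background")

# a few canonical CSCC marker genes keep the synthetic universe readable
_NAMED_MARKERS = {
    "cancer": ["SERPINB3", "KRT5", "KRT17", "CDKN2A", "TP63", "KRT13"],
    "fibroblast": ["LAMA2", "VIM", "COL1A1", "COL1A2", "DCN", "LUM"],
    "mycaf": ["ACTA2", "POSTN", "ITGB4", "FAP", "TAGLN", "MYL9"],
    "immune": ["PTPRC", "CD3E", "CD8A", "IGKC", "IGLC2", "CD68"],
    "epithelial": ["MUC5B", "MUC4", "AGR2"],
}

IMMUNE_SIGNATURE_NAMES = ("CD56_NK", "Treg", "eosinophil", "immature_B", "immature_DC")


@dataclass
class CellProfileSpec:
    """Expression profile of one cell type.

    ``baseline_mean`` and ``dispersion`` are per-gene vectors (or scalars
    broadcast over the universe); markers get their means multiplied by
    ``marker_fold`` in cells of this type only.
    """

    cell_type: str
    baseline_mean: np.ndarray
    dispersion: np.ndarray
    marker_genes: frozenset[str]
    marker_fold: float = 8.0

    def __post_init__(self) -> None:
        self.baseline_mean = np.atleast_1d(np.asarray(self.baseline_mean, dtype=float))
        self.dispersion = np.atleast_1d(np.asarray(self.dispersion, dtype=float))
        if not np.all(np.isfinite(self.baseline_mean)) or (self.baseline_mean < 0).any():
            raise ValueError(f"{self.cell_type}: baseline means must be finite and >= 0")
        if (self.dispersion <= 0).any():
            raise ValueError(f"{self.cell_type}: dispersion must be > 0")
        if self.marker_fold < 1:
            raise ValueError(f"{self.cell_type}: marker_fold must be >= 1")

    def mean_vector(self, genes: list[str]) -> np.ndarray:
        mu = np.broadcast_to(self.baseline_mean, (len(genes),)).copy()
        unknown = self.marker_genes - set(genes)
        if unknown:
            raise ValueError(
                f"{self.cell_type}: marker gene(s) not in universe: {sorted(unknown)}"
            )
        idx = [i for i, g in enumerate(genes) if g in self.marker_genes]
        mu[idx] *= self.marker_fold
        return mu


@dataclass
class RegionLayout:
    """Spot-lattice region geometry plus per-region mixing rules.

    ``region_map`` holds one label per spot; ``area_id`` numbers tumor
    blobs (their myCAF annulus shares the blob's id), -1 elsewhere.
    ``composition`` maps region label -> cell-type mixture (sums to 1);
    ``abundance_factor`` scales each region's expected RNA depth.
    """

    width: int
    height: int
    region_map: np.ndarray
    area_id: np.ndarray
    composition: dict[str, dict[str, float]]
    abundance_factor: dict[str, float]

    def __post_init__(self) -> None:
        if self.region_map.shape != (self.height, self.width):
            raise ValueError("region_map shape must be (height, width)")
        for label, comp in self.composition.items():
            if comp and abs(sum(comp.values()) - 1.0) > 1e-9:
                raise ValueError(f"composition of {label!r} does not sum to 1")
        if "tumor" in self.abundance_factor and "stroma" in self.abundance_factor:
            if not self.abundance_factor["tumor"] > self.abundance_factor["stroma"]:
                raise ValueError("abundance_factor(tumor) must exceed abundance_factor(stroma)")

    def present_labels(self) -> list[str]:
        return sorted(np.unique(self.region_map).tolist())


@dataclass(frozen=True)
class MetabolicPlant:
    """Planted metabolic split: pathway genes elevated in hyper areas."""

    hyper_area_ids: frozenset[int]
    hypo_area_ids: frozenset[int]
    pathway_fold: float = 4.0

    def __post_init__(self) -> None:
        if self.hyper_area_ids & self.hypo_area_ids:
            raise ValueError("hyper and hypo area sets overlap")
        if self.pathway_fold <= 1:
            raise ValueError("pathway_fold must be > 1")


@dataclass
class Universe:
    """A self-consistent gene universe with cell types and signatures."""

    genes: list[str]
    cell_specs: list[CellProfileSpec]
    pathway_signatures: list[GeneSignature]
    immune_signatures: list[GeneSignature]
    marker_sets: dict[str, frozenset[str]] = field(default_factory=dict)


def default_universe(
    n_genes: int = 2000,
    n_markers: int = 12,
    pathway_size: int = 30,
    immune_size: int = 15,
    marker_fold: float = 8.0,
    seed: int = 0,
) -> Universe:
    """Build the default desk-scale universe.

    Named CSCC marker genes are padded with synthetic ones up to
    ``n_markers`` per cell type; six 30-gene metabolic pathway signatures
    and five immune-cell signatures are carved out of the remaining
    filler genes. Baseline means are log-normal (median 0.3), dispersion
    theta = 2 for every gene.
    """
    rng = np.random.default_rng(seed)
    genes: list[str] = []
    marker_sets: dict[str, frozenset[str]] = {}
    for ct, named in _NAMED_MARKERS.items():
        pad = [f"{ct.upper()[:4]}M{i:02d}" for i in range(n_markers - len(named))]
        marker_sets[ct] = frozenset(named + pad)
        genes.extend(named + pad)

    pathway_signatures = []
    for pw in METABOLIC_PATHWAYS:
        members = [f"{pw.upper()[:8]}{i:03d}" for i in range(pathway_size)]
        pathway_signatures.append(GeneSignature.of(pw, members))
        genes.extend(members)
    immune_signatures = []
    for sig in IMMUNE_SIGNATURE_NAMES:
        members = [f"{sig.upper()}{i:03d}" for i in range(immune_size)]
        immune_signatures.append(GeneSignature.of(sig, members))
        genes.extend(members)
    if len(set(genes)) != len(genes):
        raise ValueError("internal: gene name collision in the default universe")

    n_filler = n_genes - len(genes)
    if n_filler < 1:
        raise ValueError(f"n_genes={n_genes} too small for the named structure ({len(genes)})")
    genes.extend(f"G{i:04d}" for i in range(n_filler))

    baseline = rng.lognormal(mean=np.log(0.3), sigma=0.8, size=len(genes))
    # markers emulate well-detected genes (as real marker panels are chosen
    # to be); without a floor a rare marker would make region means pure noise
    all_markers = set().union(*marker_sets.values())
    marker_idx = [i for i, g in enumerate(genes) if g in all_markers]
    baseline[marker_idx] = np.maximum(baseline[marker_idx], 0.5)
    cell_specs = [
        CellProfileSpec(
            cell_type=ct,
            baseline_mean=baseline,
            dispersion=np.full(len(genes), 2.0),
            marker_genes=marker_sets[ct],
            marker_fold=marker_fold,
        )
        for ct in _NAMED_MARKERS
    ]
    return Universe(
        genes=genes,
        cell_specs=cell_specs,
        pathway_signatures=pathway_signatures,
        immune_signatures=immune_signatures,
        marker_sets=marker_sets,
    )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, theta: np.ndarray, size0: int) -> np.ndarray:
    """Gamma-Poisson draw of shape (size0, len(mean)); var = mu + mu^2/theta."""
    lam = rng.gamma(shape=theta, scale=np.where(theta > 0, mean / theta, 0.0), size=(size0, mean.size))
    return rng.poisson(lam)


def simulate_cells(
    specs: list[CellProfileSpec],
    genes: list[str],
    n_per_type: int,
    seed: int,
) -> tuple[pd.DataFrame, pd.Series]:
    """Labeled cell-by-gene NB count matrix, ``n_per_type`` cells per spec.

    Returns (counts DataFrame indexed by cell id, label Series).
    """
    if n_per_type < 1:
        raise ValueError("n_per_type must be >= 1")
    rng = np.random.default_rng(seed)
    blocks, labels, ids = [], [], []
    for spec in specs:
        mu = spec.mean_vector(genes)
        theta = np.broadcast_to(spec.dispersion, (len(genes),))
        blocks.append(_nb_draw(rng, mu, theta, n_per_type))
        labels.extend([spec.cell_type] * n_per_type)
        ids.extend(f"{spec.cell_type}_{i}" for i in range(n_per_type))
    counts = pd.DataFrame(np.vstack(blocks), index=ids, columns=genes)
    return counts, pd.Series(labels, index=ids, name="cell_type")


DEFAULT_COMPOSITION: dict[str, dict[str, float]] = {
    "tumor": {"cancer": 0.80, "immune": 0.10, "fibroblast": 0.10},
    "stroma": {"fibroblast": 0.70, "immune": 0.20, "epithelial": 0.10},
    "inflammation": {"immune": 0.80, "fibroblast": 0.20},
    "mycaf_ring": {"mycaf": 0.70, "fibroblast": 0.20, "immune": 0.10},
    "gland": {"epithelial": 0.80, "fibroblast": 0.20},
    "background": {"fibroblast": 1.0},
}

DEFAULT_ABUNDANCE: dict[str, float] = {
    "tumor": 3.0,
    "stroma": 1.0,
    "inflammation": 1.2,
    "mycaf_ring": 1.2,
    "gland": 1.0,
    "background": 0.3,
}


def make_layout(
    width: int = 96,
    height: int = 96,
    n_tumors: int = 4,
    ringed_tumors: tuple[int, ...] = (0,),
    ring_width: int = 2,
    n_inflammation: int = 1,
    seed: int = 0,
    composition: dict | None = None,
    abundance_factor: dict | None = None,
) -> RegionLayout:
    """Place circular tumor blobs (optionally ringed by a myCAF annulus
    1-3 spots wide), inflammation patches, and stroma elsewhere.

    Blob centres sit on a jittered grid so placements never overlap;
    ``ringed_tumors`` selects which blob indices get an annulus (the
    annulus inherits the blob's area id).
    """
    if not (1 <= ring_width <= 3):
        raise ValueError("ring_width must be 1..3 spots")
    rng = np.random.default_rng(seed)
    n_sites = n_tumors + n_inflammation
    grid = int(np.ceil(np.sqrt(n_sites)))
    cw, ch = width // grid, height // grid
    if min(cw, ch) < 6 + 2 * ring_width:
        raise ValueError("chip too small for the requested number of blobs")
    cells = [(i, j) for i in range(grid) for j in range(grid)]
    rng.shuffle(cells)

    region = np.full((height, width), "stroma", dtype=object)
    area = np.full((height, width), -1, dtype=np.int64)
    yy, xx = np.mgrid[0:height, 0:width]

    for idx in range(n_sites):
        ci, cj = cells[idx]
        r_max = (min(cw, ch) - 2 * ring_width - 2) // 2
        r = int(rng.integers(max(2, r_max - 2), r_max + 1))
        cx = ci * cw + cw // 2 + int(rng.integers(-1, 2))
        cy = cj * ch + ch // 2 + int(rng.integers(-1, 2))
        d2 = (xx - cx) ** 2 + (yy - cy) ** 2
        if idx < n_tumors:
            blob = d2 <= r * r
            region[blob] = "tumor"
            area[blob] = idx
            if idx in ringed_tumors:
                ring = (d2 > r * r) & (d2 <= (r + ring_width) ** 2)
                region[ring] = "mycaf_ring"
                area[ring] = idx
        else:
            blob = d2 <= (r - 1) ** 2
            region[blob] = "inflammation"
    return RegionLayout(
        width=width,
        height=height,
        region_map=region,
        area_id=area,
        composition=composition or DEFAULT_COMPOSITION,
        abundance_factor=abundance_factor or DEFAULT_ABUNDANCE,
    )


def simulate_chip(
    layout: RegionLayout,
    specs: list[CellProfileSpec],
    genes: list[str],
    plant: MetabolicPlant | None = None,
    pathway_signatures: list[GeneSignature] | None = None,
    seed: int = 0,
    spot_depth: float = 0.05,
    theta: float = 2.0,
) -> tuple[SpotMatrix, pd.DataFrame]:
    """Draw per-spot counts from the region mixtures and return ground truth.

    The expected count of gene g at a spot in region R is
    ``abundance_factor(R) * spot_depth * sum_t composition(R, t) * mean_t(g)``,
    with the six metabolic pathway gene sets further multiplied by
    ``plant.pathway_fold`` inside hyper areas. Returns the SpotMatrix and a
    truth table (x, y, region, area_id).
    """
    spec_by_type = {s.cell_type: s for s in specs}
    mean_by_type = {s.cell_type: s.mean_vector(genes) for s in specs}
    rng = np.random.default_rng(seed)

    pathway_idx: np.ndarray | None = None
    if plant is not None:
        if pathway_signatures is None:
            raise ValueError("a MetabolicPlant requires pathway_signatures")
        members = set().union(*(s.genes for s in pathway_signatures))
        pathway_idx = np.array([i for i, g in enumerate(genes) if g in members])

    h, w = layout.height, layout.width
    region_flat = layout.region_map.ravel()
    area_flat = layout.area_id.ravel()
    xs = np.tile(np.arange(w), h)
    ys = np.repeat(np.arange(h), w)

    hyper = (
        np.isin(area_flat, list(plant.hyper_area_ids)) & (region_flat == "tumor")
        if plant is not None
        else np.zeros(region_flat.size, dtype=bool)
    )

    dense = np.zeros((region_flat.size, len(genes)), dtype=np.int64)
    for label in np.unique(region_flat):
        comp = layout.composition.get(label)
        if not comp:
            raise ValueError(f"region {label!r} has an empty composition")
        unknown = set(comp) - set(spec_by_type)
        if unknown:
            raise ValueError(f"region {label!r}: unknown cell type(s) {sorted(unknown)}")
        base = sum(frac * mean_by_type[ct] for ct, frac in comp.items())
        base = layout.abundance_factor.get(label, 1.0) * spot_depth * base
        for is_hyper in (False, True):
            sel = (region_flat == label) & (hyper == is_hyper)
            if not sel.any():
                continue
            mu = base.copy()
            if is_hyper and pathway_idx is not None and plant is not None:
                mu[pathway_idx] *= plant.pathway_fold
            block = _nb_draw(rng, mu, np.full(len(genes), theta), int(sel.sum()))
            dense[sel] = block
    truth = pd.DataFrame({"x": xs, "y": ys, "region": region_flat, "area_id": area_flat})
    spots = SpotMatrix(
        genes=list(genes),
        coords=np.column_stack([xs, ys]),
        counts=sparse.csr_matrix(dense),
        geometry=ChipGeometry(),
    )
    return spots, truth


def bin_truth(truth: pd.DataFrame, bin_size: int) -> pd.DataFrame:
    """Majority-vote region/area ground truth per bin.

    A bin's label is the most frequent (region, area_id) pair among its
    member spots (ties broken lexicographically). Returns a DataFrame
    (bin_id, bx, by, region, area_id, region_id) where region_id appends
    the area id for tumor and ring regions.
    """
    t = truth.copy()
    t["bx"] = t.x // bin_size
    t["by"] = t.y // bin_size
    rows = []
    for (bx, by), g in t.groupby(["bx", "by"], sort=True):
        pairs = g.groupby(["region", "area_id"]).size()
        (region, aid) = pairs.sort_values(ascending=False).index[0]
        region_id = f"{region}_{aid}" if aid >= 0 else str(region)
        rows.append(
            {
                "bin_id": f"{bx}_{by}",
                "bx": bx,
                "by": by,
                "region": region,
                "area_id": int(aid),
                "region_id": region_id,
            }
        )
    return pd.DataFrame(rows)


def simulate_viral_depth(
    genome_len: int, covered_fraction: float, mean_depth: float, seed: int = 0
) -> np.ndarray:
    """Per-base depth vector with exactly round(f * L) covered positions.

    Covered positions form one contiguous block at a random offset (viral
    transcription covers contiguous stretches); per-base depth is
    1 + Poisson(mean_depth - 1) so every covered base has depth >= 1.
    """
    if genome_len < 1:
        raise ValueError("genome_len must be >= 1")
    if not (0 <= covered_fraction <= 1):
        raise ValueError("covered_fraction must be in [0, 1]")
    if mean_depth < 0:
        raise ValueError("mean_depth must be non-negative")
    rng = np.random.default_rng(seed)
    n_cov = int(round(covered_fraction * genome_len))
    depth = np.zeros(genome_len, dtype=np.int64)
    if n_cov:
        start = int(rng.integers(0, genome_len - n_cov + 1))
        depth[start : start + n_cov] = 1 + rng.poisson(max(mean_depth - 1.0, 0.0), size=n_cov)
    return depth


_IHC_COVARIATE_LEVELS: dict[str, tuple[tuple[str, float], ...]] = {
    "nodal_status": (("N0", 0.6), (">=N1", 0.4)),
    "differentiation": (("low", 0.4), ("well_moderate", 0.6)),
    "tumor_size": (("<4cm", 0.65), (">=4cm", 0.35)),
    "scc_antigen": (("<=1.5", 0.4), (">1.5", 0.6)),
    "age_group": (("<=50", 0.45), (">50", 0.55)),
}

_HIGH_COMBOS = [
    (p, i) for p in range(5) for i in range(4) if p * i >= 4
]
_LOW_COMBOS = [(p, i) for p in range(5) for i in range(4) if p * i < 4]
_PCT_RANGES = {0: (0, 5), 1: (6, 25), 2: (26, 50), 3: (51, 75), 4: (76, 100)}


def simulate_ihc_cohort(
    n: int,
    effect: float,
    seed: int = 0,
    baseline_logit: float = -0.5,
    na_rate: float = 0.0,
) -> list[IHCRecord]:
    """Synthetic IHC cohort with a stage-dependent composite score.

    Stage (I/II/III) is drawn at probabilities (0.4, 0.35, 0.25);
    P(composite score >= 4) follows a logistic model
    logit(p) = baseline_logit + effect * stage_index (stage I = 0). The
    positivity percentage / intensity pair is then drawn uniformly among
    the combinations consistent with the high/low outcome. Other clinical
    covariates are drawn independently; each covariate value is replaced
    by NA with probability ``na_rate``.
    """
    if n < 10:
        raise ValueError("cohort size must be >= 10")
    rng = np.random.default_rng(seed)
    stages = rng.choice(["I", "II", "III"], size=n, p=[0.40, 0.35, 0.25])
    stage_idx = np.array([{"I": 0, "II": 1, "III": 2}[s] for s in stages])
    p_high = 1.0 / (1.0 + np.exp(-(baseline_logit + effect * stage_idx)))
    high = rng.random(n) < p_high
    records = []
    for i in range(n):
        combos = _HIGH_COMBOS if high[i] else _LOW_COMBOS
        ps, intensity = combos[int(rng.integers(len(combos)))]
        lo, hi = _PCT_RANGES[ps]
        pct = float(rng.integers(lo, hi + 1))
        cov: dict[str, str | None] = {"stage": str(stages[i])}
        for name, levels in _IHC_COVARIATE_LEVELS.items():
            labels, probs = zip(*levels)
            cov[name] = str(rng.choice(labels, p=probs))
        for name in cov:
            if na_rate and rng.random() < na_rate:
                cov[name] = None
        records.append(
            IHCRecord(
                sample_id=f"S{i:03d}", positivity_pct=pct, intensity=int(intensity), covariates=cov
            )
        )
    return records
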