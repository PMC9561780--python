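"""Spot-level spatial I/O, square binning, QC and normalization.

Sub-micron spatial transcriptomics chips (Stereo-seq style) resolve
expression at individual capture spots laid out on an integer lattice.
Single spots capture too few molecules to analyze, so adjacent spots are
aggregated into square bins (e.g. "bin100" = 100 x 100 spots) which become
the analysis units. This module reads the GEM-like TSV dialect
(geneID, x, y, MIDCount), aggregates spots into bins, applies bin-level
quality control and produces a log-normalized expression table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import sparse

GEM_COLUMNS = ("geneID", "x", "y", "MIDCount")


class GemParseError(ValueError):
    """Raised when a GEM-like TSV does not conform to the expected schema."""


@dataclass(frozen=True)
class ChipGeometry:
    """Physical geometry of the capture-spot lattice.

    Parameters
    ----------
    spot_diameter_nm
        Diameter of one capture spot, in nanometres.
    pitch_nm
        Centre-to-centre distance between adjacent spots, in nanometres.
    """

    spot_diameter_nm: float = 220.0
    pitch_nm: float = 500.0

    def __post_init__(self) -> None:
        if not (0 < self.spot_diameter_nm <= self.pitch_nm):
            raise ValueError(
                "require 0 < spot_diameter_nm <= pitch_nm, got "
                f"{self.spot_diameter_nm} / {self.pitch_nm}"
            )


@dataclass(frozen=True)
class BinSpec:
    """Number of spots per bin side (100 for bin100, 200 for bin200)."""

    bin_size: int = 100

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValueError(f"bin_size must be >= 1, got {self.bin_size}")


@dataclass
class SpotMatrix:
    """Sparse gene x spot counts on an integer lattice.

    ``counts`` is spots x genes (CSR); ``coords`` holds the 0-based integer
    (x, y) of each spot, unique per row.
    """

    genes: list[str]
    coords: np.ndarray
    counts: sparse.csr_matrix
    geometry: ChipGeometry = field(default_factory=ChipGeometry)

    @property
    def n_spots(self) -> int:
        return self.coords.shape[0]

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def total_counts(self) -> int:
        return int(self.counts.sum())


@dataclass
class BinMatrix:
    """Bin x gene counts with integer bin coordinates.

    ``annotations``, when present, is a DataFrame aligned to bins with at
    least a ``region`` column and optionally ``area_id``.
    """

    bin_coords: np.ndarray
    genes: list[str]
    counts: sparse.csr_matrix
    bin_spec: BinSpec
    annotations: Optional[pd.DataFrame] = None

    @property
    def n_bins(self) -> int:
        return self.bin_coords.shape[0]

    def bin_ids(self) -> list[str]:
        return [f"{bx}_{by}" for bx, by in self.bin_coords]

    def umi_per_bin(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def genes_per_bin(self) -> np.ndarray:
        return np.diff(self.counts.indptr) if sparse.issparse(self.counts) else (
            np.asarray(self.counts > 0).sum(axis=1)
        )


def read_gem(path: str | Path, geometry: ChipGeometry | None = None) -> SpotMatrix:
    """Read a GEM-like TSV (geneID, x, y, MIDCount) into a SpotMatrix.

    Counts for duplicate (gene, x, y) rows are summed; gene order follows
    first appearance in the file. Malformed rows raise
    :class:`GemParseError` naming the offending line.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in GEM_COLUMNS if c not in df.columns]
    if missing:
        raise GemParseError(f"{path}: missing column(s) {missing}; header was {list(df.columns)}")
    df = df[list(GEM_COLUMNS)]

    def _to_int(col: str) -> np.ndarray:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != np.floor(vals))
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # +1 header, +1 1-based
            raise GemParseError(f"{path}: non-integer value in column {col!r} at line {line}")
        return vals.astype(np.int64).to_numpy()

    x = _to_int("x")
    y = _to_int("y")
    cnt = _to_int("MIDCount")
    if (cnt < 0).any() or (x < 0).any() or (y < 0).any():
        bad = np.flatnonzero((cnt < 0) | (x < 0) | (y < 0))[0]
        raise GemParseError(f"{path}: negative value at line {int(bad) + 2}")

    genes = list(dict.fromkeys(df["geneID"]))
    gene_idx = {g: i for i, g in enumerate(genes)}
    gi = df["geneID"].map(gene_idx).to_numpy()

    coord_df = pd.DataFrame({"x": x, "y": y})
    uniq = coord_df.drop_duplicates().reset_index(drop=True)
    coord_idx = {(int(r.x), int(r.y)): i for i, r in enumerate(uniq.itertuples())}
    si = np.fromiter(
        (coord_idx[(int(a), int(b))] for a, b in zip(x, y)), dtype=np.int64, count=len(x)
    )

    counts = sparse.coo_matrix(
        (cnt, (si, gi)), shape=(len(uniq), len(genes)), dtype=np.int64
    ).tocsr()
    counts.sum_duplicates()
    return SpotMatrix(
        genes=genes,
        coords=uniq[["x", "y"]].to_numpy(dtype=np.int64),
        counts=counts,
        geometry=geometry or ChipGeometry(),
    )


def write_gem(spots: SpotMatrix, path: str | Path) -> None:
    """Write a SpotMatrix back to GEM-like TSV, one row per nonzero entry."""
    coo = spots.counts.tocoo()
    df = pd.DataFrame(
        {
            "geneID": [spots.genes[j] for j in coo.col],
            "x": spots.coords[coo.row, 0],
            "y": spots.coords[coo.row, 1],
            "MIDCount": coo.data,
        }
    )
    # stable order: gene first-appearance, then coordinates
    order = np.lexsort((df["y"], df["x"], coo.col))
    df.iloc[order].to_csv(path, sep="\t", index=False)


def physical_bin_edge(bin_size: int, geometry: ChipGeometry) -> float:
    """Physical edge length of a square bin, in micrometres.

    A bin of ``bin_size`` spots spans (bin_size - 1) pitches plus one spot
    diameter: bin100 at 220 nm spots / 500 nm pitch covers 49.72 um.
    """
    if bin_size < 1:
        raise ValueError(f"bin_size must be >= 1, got {bin_size}")
    nm = (bin_size - 1) * geometry.pitch_nm + geometry.spot_diameter_nm
    return nm / 1000.0


def bin_spots(spots: SpotMatrix, spec: BinSpec) -> BinMatrix:
    """Aggregate spot counts into square bins by floor division of coordinates.

    Spot (x, y) lands in bin (x // s, y // s); per-gene totals are conserved
    exactly.
    """
    s = spec.bin_size
    bx = spots.coords[:, 0] // s
    by = spots.coords[:, 1] // s
    keys = bx * (by.max() + 1 if len(by) else 1) + by
    uniq, inverse = np.unique(keys, return_inverse=True)
    n_bins = len(uniq)
    # indicator matrix bins x spots, then one spmm does the aggregation
    agg = sparse.coo_matrix(
        (np.ones(spots.n_spots), (inverse, np.arange(spots.n_spots))),
        shape=(n_bins, spots.n_spots),
    ).tocsr()
    counts = (agg @ spots.counts).tocsr().astype(np.int64)
    first = np.full(n_bins, -1, dtype=np.int64)
    for i, inv in enumerate(inverse):
        if first[inv] < 0:
            first[inv] = i
    bin_coords = np.column_stack([bx[first], by[first]])
    return BinMatrix(bin_coords=bin_coords, genes=list(spots.genes), counts=counts, bin_spec=spec)


def drop_rare_genes(binmat: BinMatrix, min_bins: int = 1) -> BinMatrix:
    """Drop genes expressed in fewer than ``min_bins`` bins."""
    expressed_in = np.asarray((binmat.counts > 0).sum(axis=0)).ravel()
    keep = expressed_in >= min_bins
    return BinMatrix(
        bin_coords=binmat.bin_coords,
        genes=[g for g, k in zip(binmat.genes, keep) if k],
        counts=binmat.counts[:, keep].tocsr(),
        bin_spec=binmat.bin_spec,
        annotations=binmat.annotations,
    )


def qc_bins(
    binmat: BinMatrix, min_umi: int = 200, min_median_genes: int = 1000
) -> tuple[BinMatrix, dict]:
    """Remove low-signal bins and flag chips with too few genes per bin.

    Bins are retained only when total UMI > ``min_umi`` (strict). The chip
    passes QC only when the median number of distinct genes across retained
    bins is > ``min_median_genes`` (strict). Returns the filtered matrix and
    a report dict; an empty result is reported with status ``"empty"``
    rather than silently.
    """
    if binmat.n_bins == 0:
        raise ValueError("qc_bins requires a non-empty BinMatrix")
    umi = binmat.umi_per_bin()
    keep = umi > min_umi
    kept = BinMatrix(
        bin_coords=binmat.bin_coords[keep],
        genes=list(binmat.genes),
        counts=binmat.counts[keep].tocsr(),
        bin_spec=binmat.bin_spec,
        annotations=(
            binmat.annotations.loc[keep].reset_index(drop=True)
            if binmat.annotations is not None
            else None
        ),
    )
    genes_per_bin = np.asarray((kept.counts > 0).sum(axis=1)).ravel()
    median_genes = float(np.median(genes_per_bin)) if kept.n_bins else 0.0
    report = {
        "status": "empty" if kept.n_bins == 0 else "ok",
        "n_bins_in": int(binmat.n_bins),
        "n_bins_kept": int(kept.n_bins),
        "min_umi": int(min_umi),
        "min_median_genes": int(min_median_genes),
        "median_genes_per_bin": median_genes,
        "chip_pass": bool(kept.n_bins > 0 and median_genes > min_median_genes),
        "umi_per_kept_bin": {
            "min": int(umi[keep].min()) if kept.n_bins else 0,
            "median": float(np.median(umi[keep])) if kept.n_bins else 0.0,
            "max": int(umi[keep].max()) if kept.n_bins else 0,
        },
    }
    return kept, report


def log_normalize(binmat: BinMatrix, scale: float = 1e4) -> pd.DataFrame:
    """Library-size log-normalization: ln(count * scale / bin_total + 1).

    Returns a dense bins x genes DataFrame indexed by bin id. Zero counts
    map to 0; a zero-total bin (impossible after QC) raises.
    """
    totals = binmat.umi_per_bin().astype(float)
    if (totals == 0).any():
        bad = binmat.bin_ids()[int(np.flatnonzero(totals == 0)[0])]
        raise ValueError(f"bin {bad} has zero total counts; run qc_bins first")
    dense = binmat.counts.toarray().astype(float)
    vals = np.log1p(dense * scale / totals[:, None])
    return pd.DataFrame(vals, index=binmat.bin_ids(), columns=binmat.genes)


def write_bin_matrix(binmat: BinMatrix, outdir: str | Path) -> None:
    """Export bins as MTX (sparse counts) + bins TSV + genes TSV."""
    from scipy.io import mmwrite

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mmwrite(str(outdir / "counts.mtx"), binmat.counts.tocoo())
    bins = pd.DataFrame(binmat.bin_coords, columns=["bx", "by"])
    bins.insert(0, "bin_id", binmat.bin_ids())
    if binmat.annotations is not None:
        bins = pd.concat([bins, binmat.annotations.reset_index(drop=True)], axis=1)
    bins.to_csv(outdir / "bins.tsv", sep="\t", index=False)
    pd.Series(binmat.genes, name="gene").to_csv(outdir / "genes.tsv", sep="\t", index=False)
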