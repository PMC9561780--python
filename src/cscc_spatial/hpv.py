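"""HPV positivity calling from per-base viral genome coverage.

Viral reads aligned to an HPV reference genome (e.g. HPV16, 7906 bp)
yield a per-base depth vector. A sample is called positive for a type
when the genome coverage (covered length / genome length) exceeds 5%
AND the effective depth (total mapped bases / covered length) exceeds
50x — both strictly. "Covered" means depth >= 1 at that base.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

MIN_COVERAGE_FRAC = 0.05
MIN_EFFECTIVE_DEPTH = 50.0


@dataclass
class CoverageProfile:
    hpv_type: str
    depth: np.ndarray  # per-base depth, length = genome length

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if self.depth.ndim != 1 or self.depth.size == 0:
            raise ValueError("depth must be a non-empty 1-D vector")
        if (self.depth < 0).any():
            raise ValueError("depth values must be non-negative")

    @property
    def genome_len(self) -> int:
        return int(self.depth.size)


@dataclass(frozen=True)
class HPVCall:
    hpv_type: str
    genome_len: int
    covered_len: int
    coverage_frac: float
    effective_depth: float
    positive: bool


def read_depth_table(path: str | Path, hpv_type: str | None = None) -> CoverageProfile:
    """Read a depth TSV: 2 columns (pos, depth) or samtools-depth style
    3 columns (ref, pos, depth). Positions are 1-based; absent positions
    get depth 0; genome length is taken as the maximum position present.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] == 2:
        ref, pos, dep = hpv_type or "HPV", df[0], df[1]
    elif df.shape[1] == 3:
        refs = df[0].unique()
        if len(refs) != 1:
            raise ValueError(f"expected a single reference, got {list(refs)}")
        ref, pos, dep = hpv_type or str(refs[0]), df[1], df[2]
    else:
        raise ValueError(f"{path}: expected 2 or 3 columns, got {df.shape[1]}")
    pos = pos.astype(int).to_numpy()
    dep = dep.astype(int).to_numpy()
    if (pos < 1).any():
        raise ValueError(f"{path}: positions must be 1-based positive integers")
    depth = np.zeros(int(pos.max()), dtype=np.int64)
    np.add.at(depth, pos - 1, dep)
    return CoverageProfile(hpv_type=str(ref), depth=depth)


def call_hpv(
    profile: CoverageProfile,
    min_cov: float = MIN_COVERAGE_FRAC,
    min_depth: float = MIN_EFFECTIVE_DEPTH,
) -> HPVCall:
    """Positivity call from a coverage profile; both thresholds strict."""
    covered = profile.depth > 0
    covered_len = int(covered.sum())
    coverage_frac = covered_len / profile.genome_len
    total_bases = int(profile.depth.sum())
    effective_depth = total_bases / covered_len if covered_len else 0.0
    return HPVCall(
        hpv_type=profile.hpv_type,
        genome_len=profile.genome_len,
        covered_len=covered_len,
        coverage_frac=coverage_frac,
        effective_depth=effective_depth,
        positive=bool(coverage_frac > min_cov and effective_depth > min_depth),
    )


def summarize_typing(calls_by_sample: dict[str, list[HPVCall]]) -> pd.DataFrame:
    """Per-type prevalence across samples.

    ``calls_by_sample`` maps sample id -> its HPVCall list (one per typed
    reference); an iterable of (sample_id, calls) pairs is also accepted.
    A sample may be positive for several types. Returns a DataFrame
    (hpv_type, n_positive, n_samples, prevalence_pct).
    """
    if not isinstance(calls_by_sample, dict):
        pairs = list(calls_by_sample)
        ids = [s for s, _ in pairs]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids")
        calls_by_sample = dict(pairs)
    if not calls_by_sample:
        raise ValueError("no samples supplied")
    n_samples = len(calls_by_sample)
    types: dict[str, int] = {}
    for calls in calls_by_sample.values():
        seen = set()
        for c in calls:
            if c.hpv_type in seen:
                raise ValueError(f"duplicate call for type {c.hpv_type} within one sample")
            seen.add(c.hpv_type)
            types.setdefault(c.hpv_type, 0)
            if c.positive:
                types[c.hpv_type] += 1
    rows = [
        {
            "hpv_type": t,
            "n_positive": k,
            "n_samples": n_samples,
            "prevalence_pct": 100.0 * k / n_samples,
        }
        for t, k in sorted(types.items())
    ]
    return pd.DataFrame(rows)
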