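"""Composite immunohistochemistry (IHC) scoring and association tests.

Pathologist-style POSTN staining readouts are combined into a composite
score: a positivity-percentage bin score (0-5% -> 0, 6-25% -> 1,
26-50% -> 2, 51-75% -> 3, >75% -> 4) multiplied by a staining-intensity
score (negative/weak/moderate/strong -> 0..3), giving 0..12, categorized
as negative (0), weak (1-4), moderate (5-8) or strong (9-12) and
dichotomized at >= 4 ("high"). Associations between the high/low call and
clinical covariates use the Pearson chi-square test, with the Yates
continuity correction on 2x2 tables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

MAX_COMPOSITE_SCORE = 12
HIGH_CUTOFF = 4

CLINICAL_COVARIATES = (
    "stage",
    "nodal_status",
    "differentiation",
    "tumor_size",
    "scc_antigen",
    "age_group",
)


@dataclass(frozen=True)
class IHCRecord:
    sample_id: str
    positivity_pct: float
    intensity: int
    covariates: dict[str, Optional[str]]

    def __post_init__(self) -> None:
        if not (0 <= self.positivity_pct <= 100):
            raise ValueError(f"positivity_pct must be in [0, 100], got {self.positivity_pct}")
        if self.intensity not in (0, 1, 2, 3):
            raise ValueError(f"intensity must be one of 0..3, got {self.intensity}")


@dataclass(frozen=True)
class CompositeScore:
    positivity_score: int
    intensity_score: int
    final: int
    category: str
    high: bool


@dataclass(frozen=True)
class ContingencyResult:
    table: np.ndarray
    statistic: float
    df: int
    p: float
    correction: bool


def positivity_bin(pct: float) -> int:
    """Map a positivity percentage onto the 0..4 bin score.

    Bins are by value: <=5 -> 0, (5, 25] -> 1, (25, 50] -> 2,
    (50, 75] -> 3, >75 -> 4 (fractional percentages land in the bin
    containing them).
    """
    if not (0 <= pct <= 100):
        raise ValueError(f"positivity percentage out of [0, 100]: {pct}")
    for bound, score in ((5, 0), (25, 1), (50, 2), (75, 3)):
        if pct <= bound:
            return score
    return 4


def composite_score(rec: IHCRecord) -> CompositeScore:
    """Composite score = positivity bin score x intensity score (0..12)."""
    ps = positivity_bin(rec.positivity_pct)
    final = ps * rec.intensity
    category = (
        "negative" if final == 0 else "weak" if final <= 4 else "moderate" if final <= 8 else "strong"
    )
    return CompositeScore(
        positivity_score=ps,
        intensity_score=rec.intensity,
        final=final,
        category=category,
        high=final >= HIGH_CUTOFF,
    )


def chi_square(table, yates: str | bool = "auto") -> ContingencyResult:
    """Pearson chi-square test of independence on an r x c count table.

    The statistic is sum (O - E)^2 / E with E from the margins. With
    ``yates="auto"`` the continuity correction (|O - E| reduced by 0.5
    before squaring) is applied exactly when the table is 2x2; True/False
    force it. p is the chi-square upper tail at df = (r-1)(c-1).
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError(f"need an r x c table with r, c >= 2, got shape {obs.shape}")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero row or column margin")
    expected = np.outer(row, col) / obs.sum()
    use_yates = obs.shape == (2, 2) if yates == "auto" else bool(yates)
    dev = np.abs(obs - expected)
    if use_yates:
        dev = np.maximum(dev - 0.5, 0.0)
    statistic = float((dev**2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(stats.chi2.sf(statistic, df))
    return ContingencyResult(
        table=obs.astype(np.int64), statistic=statistic, df=df, p=p, correction=use_yates
    )


def chi_square_upper_tail(statistic: float, df: int) -> float:
    """Chi-square survival function via the regularized upper incomplete
    gamma function, Q(df/2, x/2); independent of the test routine."""
    from scipy.special import gammaincc

    return float(gammaincc(df / 2.0, statistic / 2.0))


def table1_report(
    records: list[IHCRecord],
    covariates: tuple[str, ...] = CLINICAL_COVARIATES,
    yates: str | bool = "auto",
) -> pd.DataFrame:
    """Chi-square association of the dichotomized score with each covariate.

    Rows with NA in a covariate are excluded from that covariate's test
    (listwise per covariate). Returns one row per testable covariate with
    the levels, per-level high/low counts, statistic and p; covariates that
    are entirely NA or single-level are skipped with a warning.
    """
    high = np.array([composite_score(r).high for r in records])
    rows = []
    for cov in covariates:
        vals = np.array([r.covariates.get(cov) for r in records], dtype=object)
        mask = np.array([v is not None and not (isinstance(v, float) and math.isnan(v)) for v in vals])
        if mask.sum() == 0:
            warnings.warn(f"covariate {cov!r} entirely NA; skipped", stacklevel=2)
            continue
        levels = sorted({str(v) for v in vals[mask]})
        if len(levels) < 2:
            warnings.warn(f"covariate {cov!r} has < 2 non-NA levels; skipped", stacklevel=2)
            continue
        tab = np.zeros((len(levels), 2), dtype=np.int64)
        for i, lev in enumerate(levels):
            sel = mask & (vals.astype(str) == lev)
            tab[i, 0] = int((high & sel).sum())
            tab[i, 1] = int((~high & sel).sum())
        res = chi_square(tab, yates=yates)
        rows.append(
            {
                "covariate": cov,
                "levels": "|".join(levels),
                "n": int(mask.sum()),
                "counts_high": "|".join(str(v) for v in tab[:, 0]),
                "counts_low": "|".join(str(v) for v in tab[:, 1]),
                "statistic": res.statistic,
                "df": res.df,
                "p": res.p,
                "correction": res.correction,
            }
        )
    return pd.DataFrame(rows)
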