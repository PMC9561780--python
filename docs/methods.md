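# Methods

This note describes the models and procedures implemented in
`cscc_spatial`, the parameters that matter, what the synthetic generators
do and do not emulate, and the numerical choices made where the design was
genuinely open.

## Spatial binning and quality control

Capture spots sit on an integer lattice with pitch 500 nm and spot
diameter 220 nm (configurable through `ChipGeometry`). A bin of side *s*
spots covers `(s − 1)·pitch + diameter` physically — 49.72 µm for bin100,
99.72 µm for bin200. Spot (x, y) is assigned to bin
(⌊x/s⌋, ⌊y/s⌋); coordinates are 0-based and the bin footprint is the
half-open square `[k·s, (k+1)·s)`. This origin convention is a choice —
any consistent alternative shifts bin boundaries by a constant — and was
picked because it is the simplest to audit. Binning conserves per-gene
counts exactly.

QC applies two strict thresholds: a bin is kept only if its UMI total is
*greater than* `min_umi` (default 200), and the chip passes only if the
median number of distinct genes per retained bin is *greater than*
`min_median_genes` (default 1,000). Both boundaries are exclusive on
purpose: a bin with exactly 200 UMIs is removed. QC is idempotent. The
filter is applied to whatever spots were loaded; restricting to a
tissue-covered subregion (in the real workflow done from stained images)
is upstream of this package.

Normalization is library-size log-normalization,
`ln(count · scale / bin_total + 1)` with scale 10⁴. A variance-stabilizing
model (e.g. regularized NB regression) would be an alternative; the plain
log-normalization was chosen because the downstream module scoring is
defined on log-normalized data and the transform is exactly specifiable.
It is invariant to per-bin depth and monotone in counts within a bin.

## Signature scoring

Two single-sample engines, both operating on the normalized bins × genes
table:

**Module score.** Genes are ranked by mean expression across units and cut
into `n_bins = 24` near-equal expression bins (ties broken by stable gene
order). For each signature gene, `n_ctrl = 100` control genes are drawn
with replacement from its bin; the unit's score is the mean signature
expression minus the mean control expression. These defaults are the
documented defaults of the widely used single-cell implementation of this
score. The score is exactly invariant to adding a constant to all
expression values and is reproducible from the seed.

**Rank-based enrichment (ssGSEA-style).** Genes are sorted by expression
descending; with the rank statistic `r = N, N−1, …, 1` along the sort, the
in-set weighted ECDF uses weights `r^α` (α = 0.25) and the out-set ECDF is
unweighted; the score is `Σᵢ (P_in(i) − P_out(i)) / N`. Ties are broken by
stable gene order. The score depends on the expression vector only through
its ranks, so any strictly monotone transform leaves it unchanged.

Numerical note: for α > 0 this statistic has a *positive null offset* — a
uniformly random gene set scores slightly above zero on average (≈ +0.05
at N = 2000, |S| = 30, α = 0.25), because rank weighting makes the in-set
ECDF rise faster than the unweighted out-set ECDF in expectation. At α = 0
the null mean is exactly zero. Scores should therefore be compared
*between* units or signatures of equal size, never against zero; that is
how the package uses them (area ranking, class contrasts), so the offset
cancels. This engine stands in wherever a per-unit "pathway activity"
score is needed; it is not a numerical replica of kernel-density GSVA,
and no output of this package should be compared numerically to GSVA
values.

## Metabolic classification

Tumor areas are either provided (ground-truth ids in synthetic runs) or
derived as 8-connected components of tumor-annotated bins. Each area's
pathway score is the mean over member bins; the composite metabolic score
is the arithmetic mean of the six pathway scores (hypoxia, lactic acid,
glycolysis, lipid metabolism, pentose phosphate, oxidative
phosphorylation) — exactly, order-invariantly. Areas sorted by composite
score descending: top *k* hyper, bottom *k* hypo, rest intermediate, ties
broken by area id (stable, documented). `k` defaults to 20 in the headline
convention but auto-shrinks to ⌊n/2⌋ with a warning on smaller runs; the
ranking is shared across samples. A run where all areas tie is flagged
degenerate rather than silently ordered.

Immune contrasts between hyper and hypo areas default to the unpaired
two-sided Wilcoxon rank-sum test (exact tie-aware enumeration when the two
groups together have ≤ 12 areas): the two classes are independent groups,
so a paired signed-rank test is not directly applicable, though it — and
Welch's t and Kruskal–Wallis — are selectable. Significance stars follow
the usual convention (ns, <0.05, <0.01, <0.001, <0.0001).

## MIA and the myCAF gate

The multimodal intersection analysis tests, for every (cell type, region)
pair, the overlap k of the m cell-type marker genes and n region marker
genes against the hypergeometric distribution on a background of N genes:
`p_enrich = P(X ≥ k)`, `p_deplete = P(X ≤ k)`. The background is the
*intersection* of genes detected in both modalities — the test's universe
must contain every set member, and genes undetectable in either modality
cannot overlap. Benjamini–Hochberg adjustment is applied across the whole
grid. Marker sets come from the differential-expression module with the
standard filter and are truncated to the top 100 genes by log2FC to keep
set sizes comparable.

myCAF regions are called by a conjunction: adjusted enrichment p below
`mia_alpha` (default 0.05) **and** regional mean POSTN above the
`expr_quantile` (default 0.75) quantile of all region means. Both
thresholds are configurable; the defaults operationalize "high MIA score"
and "high POSTN" in the absence of published numbers. The gate is monotone
in both thresholds. The expression arm exists because enrichment alone
is unreliable in low-RNA regions; POSTN is used as the single most
specific myCAF marker.

## Differential expression

Two-sided Wilcoxon rank-sum per gene. For n₁+n₂ ≤ 10 the p-value is
computed by exhaustive enumeration of all group assignments with midranks
(`p = P(|W − E W| ≥ |w − E W|)`); otherwise the tie-corrected,
continuity-corrected normal approximation. The approximation sits within
about 0.02 of the exact value for groups of 6–10 and within 0.01 by
12–15, converging from there; for the marker filter (α = 0.05 after BH)
this is immaterial at realistic group sizes. log2FC uses the de-logged
means convention `log2((mean(expm1 x₁)+1)/(mean(expm1 x₂)+1))`; pct is the
expressed fraction (> 0) per group, and the strict filter is
`|log2FC| > 0.25 ∧ pct1 > 0.25 ∧ p_adj < 0.05` with pct applied to the
target group only. Multiple testing uses Benjamini–Hochberg (configurable);
this choice is recorded in every output.

## HPV calling

From a per-base depth vector over a viral reference genome (HPV16 K02718.1
is 7,906 bp): coverage = covered length / genome length with "covered"
meaning depth ≥ 1; effective depth = total depth / covered length. A
sample is positive for a type iff coverage > 5% and effective depth > 50×,
both strict. Note a consequence of this definition pair: extra depth at an
already-covered base can only help, but a newly covered low-depth base
*dilutes* effective depth and can in principle flip a borderline call —
the two criteria are not jointly monotone in the depth vector. Inputs are
depth tables (2- or 3-column TSV), not alignments; alignment is out of
scope.

## IHC scoring and association tests

Composite score = positivity-bin score × intensity. Positivity bins are by
value: ≤5% → 0, (5, 25] → 1, (25, 50] → 2, (50, 75] → 3, >75% → 4
(fractional percentages land in the bin containing them); intensity 0–3.
The product ranges 0–12, categorized negative (0), weak (1–4), moderate
(5–8), strong (9–12), and dichotomized at ≥ 4. Associations between the
dichotomy and clinical covariates use the Pearson chi-square statistic
with the Yates continuity correction exactly on 2×2 tables (the
convention of the standard R test); rows with a missing covariate are
excluded per test. The bundled 71-sample contingency table reproduces its
six published p-values (0.012, 0.270, 0.007, 0.040, 0.030, 0.011) to
three decimals under exactly this convention — plain Pearson on the 3×2
stage table, Yates on the 2×2 tables — which is why it is the default.

## Synthetic data: what it emulates, and what it does not

Counts are negative binomial in the mean/dispersion parameterization
(var = μ + μ²/θ, Poisson as θ → ∞), drawn as a gamma–Poisson mixture;
θ = 2 throughout. The default universe has 2,000 genes (tests use ~400):
five cell types (cancer, fibroblast, myCAF, immune, glandular epithelial)
with 12 markers each (a few canonical names — SERPINB3, LAMA2, ACTA2,
POSTN, FAP, PTPRC, MUC5B — padded with synthetic ones), six 30-gene
metabolic pathway signatures and five 15-gene immune signatures. Baseline
means are log-normal (median 0.3, σ = 0.8); marker genes are floored at
0.5 because marker panels are in practice chosen among well-detected
genes — an unexpressed marker would make regional means shot noise rather
than a test of the method.

The chip generator places non-overlapping circular tumor blobs on a
jittered grid, draws a 1–3-spot-wide myCAF annulus around a chosen subset
(the annulus inherits the blob's area id), adds inflammation patches, and
fills the rest with stroma. Each spot draws NB counts at
`abundance · spot_depth · Σ_t composition(region, t) · μ_t`, so a spot is
a cell *mixture*, not a cell — mirroring the fact that an aggregated bin
is a mixture of cells. Default abundance factors make tumor three times
richer in RNA than stroma. Hyper areas multiply the 180 pathway-gene means
by `pathway_fold` (default 4). Region compositions are free parameters of
the generator, not estimates of real tissue.

One geometric constraint matters for the myCAF analyses: the analysis bin
must not be wider than the annulus. With a 2-spot annulus and 4-spot bins,
ring-majority bins are barely half ring spots and the 3× tumor RNA
abundance swamps the POSTN signal; at 2-spot bins the gate recovers the
planted annuli cleanly. The recovery experiments therefore use
`bin_size = 2`. The same ratio governs the real setting (bin edge vs
ribbon width in µm).

Not emulated: tissue images, read-level sequencing error, doublets,
ambient RNA, segmentation uncertainty, batch effects between modalities,
or spatial autocorrelation within a region beyond region membership.
Passing recovery tests therefore show the *pipeline logic* recovers
planted structure under the stated noise model — not that it would under
every real-data pathology.

The IHC cohort generator draws stage I/II/III at (0.40, 0.35, 0.25) and
makes `P(score ≥ 4)` logistic in the stage index with a chosen log-odds
`effect` (0 gives a calibrated null: type-I error ≈ 5% at α = 0.05; 2
gives > 80% power at n = 200). Score components are drawn uniformly among
the (positivity bin, intensity) pairs consistent with the high/low
outcome. Viral profiles place the covered bases as one contiguous block
(transcribed stretches are contiguous) with exactly `round(f·L)` covered
positions and per-base depth 1 + Poisson(mean − 1).

## Reproducibility and problem sizes

Every generator and every seeded analysis step takes an integer seed; a
single master seed is fanned out to stage-specific child seeds (< 2³¹) by
a splitmix64 step keyed on the stage name, so a stage re-run in isolation
matches the same stage inside a full pipeline run. Pipeline outputs are
TSV/JSON with a SHA-256 manifest.

The test suite and the acceptance script run desk-scale problems chosen to
exercise the statistics without bulk: ~400-gene universes, 96–120-spot
chips, 12 tumor areas for the metabolic split (k = 6), 5 blobs / 2 annuli
for the myCAF gate, 20 seeds for recovery suites (10 in the acceptance
script), 500 (resp. 200) seeds for the null-calibration rate. Exact
checks (geometry, hypergeometric tails, enumeration oracles, chi-square)
are size-independent.

## Known limitations

* The rank-based enrichment engine is not numerically interchangeable
  with kernel-density GSVA; only ordering-level conclusions transfer.
* Tumor "areas" from 8-connectivity are a proxy for expert annotation;
  two touching lesions merge.
* The positivity-bin mapping treats the published integer bins as value
  intervals; a lab using different rounding conventions at the 5%/25%/50%/
  75% boundaries would shift scores by one bin at most.
* `markers_for` truncates marker sets at 100 genes by log2FC; MIA
  p-values depend (weakly) on this cap through the set sizes.
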