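# Methods

This note documents the statistical models implemented in `scmr`, the
defaults and why they were chosen, what the synthetic data do and do not
emulate, and the numerical conventions.

## Single-cell quality control

Per-cell metrics are computed from the raw gene-by-cell count matrix:
`n_count` (total molecules), `n_feature` (genes with count > 0),
`percent_mt` and `percent_ribo` (100 × matched-gene counts over the
total; 0 for an empty cell, which the `n_feature` bound removes anyway).
Mitochondrial and ribosomal genes are identified by the case-insensitive
name prefixes `MT-` and `RPS`/`RPL`; both patterns are configurable
regular expressions, since annotation conventions vary across references.

Filtering uses one-sided median-absolute-deviation rules: a metric's upper
bound is

```
median(x) + n_mads × c × median(|x − median(x)|)
```

with `n_mads = 3` and `c = 1.4826` by default. The constant `c` is the
normal-consistency factor that makes the MAD estimate a standard
deviation; it is the prevailing convention in scRNA-seq QC but it is a
convention, so `c = 1` (the raw MAD) is a supported setting and the
hand-checkable oracle (`[1..9, 100] → bound 13.0`) uses it. The only
fixed lower bound is `n_feature > 200` (strict, so a cell at exactly 200
detected genes is removed); no lower MAD bounds are applied. Thresholds
are always computed on the full input population and recorded in the QC
report, and `apply_qc_filter` accepts a frozen threshold mapping so a
second pass reproduces the first pass's kept set exactly — without frozen
thresholds the rule is deliberately not idempotent, since re-estimating
bounds on a filtered population tightens them.

Doublet detection is out of scope; a precomputed doublet flag column can
simply be dropped from the metadata before the pipeline runs.

Normalization is `ln(1 + s·c/total)` per cell with `s = 10,000`
(counts-per-ten-thousand, log1p), which preserves zeros and within-cell
rank order. Highly-variable genes are the `k = 2,000` genes with largest
variance of the normalized values, ties broken lexicographically by gene
name so selection is deterministic; fancier mean-variance-trend statistics
exist, but plain variance is defensible, transparent, and sufficient for
a deterministic pipeline stage.

## Cluster contribution (FCscore)

Characteristic genes per cluster are one-vs-rest two-sided Wilcoxon
rank-sum markers. The test is exact (full enumeration over midranks) when
both groups have ≤ 8 observations and the normal approximation with tie
and continuity correction otherwise. Fold changes are computed on the
expression scale: group means are taken after `expm1` of the normalized
values, so `log2FC = log2((mean_in + ε)/(mean_out + ε))` measures an
actual expression ratio (a ratio of log-values would compress a 4-fold
change to ~0.4 log2 units and starve the 0.585 threshold). BH adjustment
is applied within each cluster's gene list, matching the per-cluster
marker-calling family, and both thresholds (`log2FC > 0.585`,
`padj < 0.05`) are strict.

`FCexp` is the linear-scale case/control mean ratio from the bulk table
with a configurable pseudocount (default ε = 0.01, needed because the
geometric mean requires strictly positive ratios). `FCprop(j)` is the
ratio of cluster j's cell-count share between cases and controls; a
cluster absent from one group gets a 0.5-cell continuity correction in
both groups. Per gene, `FCscore = √(FCexp × FCprop)`; a cluster's
contribution is the arithmetic mean over its markers that have a
non-missing FCexp. Genes absent from the bulk table are reported and
excluded from the average, never imputed — cross-dataset matching is by
exact symbol after uppercasing. Fold changes enter as-is (case/control
orientation); clusters with no scoreable marker are ranked last and
flagged rather than scored.

## Two-sample Mendelian randomization

Instruments are rows with `pval < 1e-8` (strict). Greedy LD clumping
visits variants in ascending p-value order (ties by variant id) and
accepts a variant iff its r² with every already-accepted variant on the
same chromosome within ±10,000 kb is below 0.001; a missing r² for an
in-window pair is a hard input error naming the pair, because silently
assuming independence there would defeat the prune.

Harmonization aligns the outcome effect to the exposure's effect allele:
identical alleles pass through, swapped alleles negate the outcome beta
(and reflect the frequency), complementary alleles are treated as a
strand flip and then re-checked. Palindromic variants (A/T, C/G) cannot
be resolved from alleles alone, so they are dropped whenever the effect
allele frequency is missing or lies in (0.42, 0.58) on either side, and
otherwise oriented by whether the two frequencies fall on the same side
of 0.5. Every drop is logged with its reason.

Estimators, on harmonized effects (γ̂ⱼ, Γ̂ⱼ) with outcome standard errors
σⱼ and weights wⱼ = 1/σⱼ²:

* **Wald ratio** (single instrument): β = Γ̂/γ̂, first-order delta-method
  standard error σ/|γ̂| (a second-order version is available by flag).
* **IVW**: weighted regression of Γ̂ on γ̂ through the origin, so
  β = Σγ̂Γ̂wⱼ / Σγ̂²wⱼ. Random-effects behaviour (the default) is
  multiplicative: the fixed-effect standard error is scaled by
  max(1, residual sd), the convention of the common two-sample MR
  packages. p-values are normal.
* **MR-Egger**: instruments are first oriented so γ̂ⱼ ≥ 0, then Γ̂ = α + βγ̂
  is fit by weighted least squares; both standard errors carry the same
  max(1, residual sd) scaling and p-values use t(nsnp − 2). The intercept
  α estimates average directional pleiotropy under InSIDE.
* **Weighted median**: per-variant ratios with weights γ̂ⱼ²/σⱼ²
  (equivalently inverse-variance weights of the ratios), cumulative
  midpoints pⱼ = Sⱼ − wⱼ/2, linear interpolation at p = 0.5. Standard
  error by seeded parametric bootstrap (default 1,000 resamples of γ̂, Γ̂
  from their sampling distributions).
* **Weighted mode**: argmax of the weighted Gaussian-kernel density of
  the ratios with bandwidth `mult × 0.9 × min(sd, 1.4826·MAD) × n^(−1/5)`
  (normal-reference rule, multiplier default 1); bootstrap standard error
  as above.

Egger, weighted median, and weighted mode require at least three
instruments and return a "method not applicable" missing result below
that, never an exception; IVW with one instrument delegates to the Wald
ratio. Cochran's Q uses the ratio parameterization
(Q = Σwⱼ(βⱼ − β̂)², wⱼ = γ̂ⱼ²/σⱼ²) with the fixed-effect IVW pooled value
and df = nsnp − 1, or deviations from the fitted Egger line with
df = nsnp − 2. Leave-one-out recomputes random-effects IVW dropping one
variant at a time plus an all-SNP row. Odds ratios are exp(β) with
exp(β ± z·se) confidence limits.

The panel driver runs selection → clumping → harmonization → all
applicable estimators → sensitivity per gene, then applies BH-FDR to the
primary (IVW/Wald) p-values across genes; genes with no surviving
instruments are reported with a `no_instruments` status and excluded from
the FDR family. The reverse panel swaps roles — disease liability as
exposure, each gene's expression as outcome — and forms its own FDR
family, mirroring the separate forward/reverse reporting convention.

## The synthetic data

`simulate_mr_study` draws, per gene with causal effect θ: true instrument
effects γⱼ uniform over `gamma_range` (default 0.1–0.3, strong
instruments by construction — real eQTL instrument strength is rarely
reported, so the defaults are chosen for testability), pleiotropic direct
effects αⱼ ~ N(mean, sd) on a configurable fraction of instruments, and
observed effects γ̂ⱼ ~ N(γⱼ, se_x²), Γ̂ⱼ ~ N(θγⱼ + αⱼ, se_y²) with
se_x = 0.01, se_y = 0.005. Exposure p-values are exact two-sided normal
p-values of γ̂/se. Alleles are single nucleotides; palindromic pairs (A/T,
C/G) appear with probability `p_palindromic` and outcome rows are
reported on the opposite strand (both alleles complemented, signed beta
unchanged) with probability `p_strand_flip`, exercising every
harmonization branch. Sample-size columns (31,684 exposure / 484,598
outcome) are metadata only. Three deliberate modelling choices:

* `gamma_sign` defaults to random, but directional-pleiotropy studies use
  `"positive"` (all instruments oriented to the exposure-increasing
  allele). This is not cosmetic: after Egger's γ̂ ≥ 0 orientation, a
  random-sign simulation flips the sign of αⱼ for half the variants, so
  "directional" pleiotropy averages to zero and neither the Egger
  intercept nor the IVW bias it should cause can be observed. Orienting
  to the expression-increasing allele matches how eQTL instruments are
  reported in practice.
* `m_outcome_instruments` adds disease-specific loci with direct outcome
  effects and null exposure effects. Without them a reverse analysis has
  only the eQTLs to instrument the disease, and the reverse ratio γ̂/Γ̂ ≈
  1/θ is huge rather than null; with them, the reverse panel behaves like
  the real design, where disease GWAS hits are mostly not eQTLs of the
  gene under study.
* Strand-flip flags are drawn from a dedicated child generator, so two
  simulations differing only in `p_strand_flip` share every other draw —
  this is what makes the strand-flip-invariance check exact.

`simulate_sc_counts` draws negative-binomial counts (dispersion 0.05)
over 500 genes (13 `MT-` genes — the mitochondrial protein-coding gene
count — and 10 ribosomal genes among them) at a depth (per-gene means
2–6) where healthy-cell QC metrics are approximately Gaussian, so the
3-MAD bounds cut well under 1% of healthy cells while planted outliers —
whose mitochondrial counts are set to three times their non-mito total,
i.e. percent_mt = 75 — are removed with certainty. One cluster carries a
case/control abundance ratio of exactly `proportion_shift` (default 2);
each cluster's markers are up-shifted by `marker_logfc` (default 2 log2
units) within the cluster, and in the bulk generator the shifted
cluster's markers carry a case/control ratio of `bulk_marker_fc`
(default 4). These defaults make the planted cluster's expected
contribution √(4 × 2) ≈ 2.8 against ≈ 0.7 for the others.

What the generators do **not** emulate: realistic LD (the LD model is
exact block-diagonal), cell-level library-size variation, batch effects,
doublets, winner's-curse in instrument selection, and sample overlap
between exposure and outcome studies. Passing tests therefore demonstrate
correctness of the algorithms under their stated assumptions, not
robustness to those real-data complications.

## Validation studies and problem sizes

The studies in `scmr.simstudy` (run by `tests/test_acceptance.py` with
fixed seeds and re-run from scratch by `scripts/acceptance.py` under the
caller's seed) use: 100 random instances for the IVW algebraic identity;
500 genes × 20 instruments for bias/coverage; 2,000 null replicates
(4,000 in the script, for tighter Monte-Carlo precision) for type-I error
and Q calibration; 1,000 replicates for Egger-intercept recovery of a
0.05 mean pleiotropic effect; 500–1,000 replicates for the
weighted-median robustness ordering; and 100 replicates of the full
single-cell + bulk FCscore pipeline at 200 cells per group and 120 genes.
The robustness study sets se_y = 0.002 (the large-GWAS regime): the
weighted median's tolerance of up to 50% invalid weight is a consistency
property that requires the valid ratios to concentrate near the truth;
with noisy ratios the median of the valid half is itself displaced and
the ordering against IVW is no longer informative about the estimator.

## Numerical conventions

Thresholds are strict where the rules say strict (`pval < 1e-8`,
`log2FC > 0.585`, `padj < 0.05`, `r² < 0.001`, `n_feature > 200`).
Estimates with zero standard error report p = 1 for a zero estimate and
p = 0 otherwise rather than dividing by zero. The weighted-mode density
is evaluated on a 512-point grid spanning the ratio range ± 3 bandwidths;
a zero-dispersion ratio vector short-circuits to the common ratio. All
bootstrap and simulation randomness flows from explicit integer seeds
through `numpy.random.default_rng`; panel bootstrap seeds are derived
per-gene from the run seed, so a rerun with the same configuration is
bit-identical (the manifest records per-file checksums to verify this).
Output tables are written in full double precision.

## Known limitations

* The bulk differential-expression step is a mean-ratio, not a
  moderated-variance model; with few bulk samples FCexp is noisy and the
  pseudocount matters.
* The weighted-mode bandwidth rule is one of several in circulation;
  estimates can shift within a bandwidth of the true mode.
* LD clumping assumes the supplied r² matrix is complete within windows;
  there is no reference-panel fallback.
* The MAD filter assumes unimodal metric distributions; strongly bimodal
  populations (e.g. mixed cell types with very different RNA content)
  would need per-population thresholds.
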