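# Methods

## Design under analysis

The pipeline targets a four-arm injury–rescue experiment: a normal control
(NC), an injury model (ADM — cells injured with adriamycin/doxorubicin),
and treatment arms (W1CC, W5CC) receiving the injury plus a candidate
protective compound, with three biological replicates per arm. Analysis
proceeds from a gene × sample integer count matrix; read-level processing
(trimming, alignment, transcript assembly) is upstream and out of scope.

Five contrasts are computed by default: ADM vs NC (the injury signature),
each treatment vs ADM (the rescue effect), and each treatment vs NC
(residual distance from normal).

## Count model and differential expression

Counts are modelled as negative binomial with mean μ and dispersion α,
Var = μ + αμ². Per-sample depth is removed by median-of-ratios size
factors: for genes with positive counts in every sample, factorⱼ is the
median of countⱼ/geometric-mean ratios, rescaled to geometric mean 1. When
no gene is expressed everywhere the caller may opt into total-count
ratios (`total_count_fallback`).

Dispersion is estimated per gene by the method of moments,
α̂ = (s² − μ̂)/μ̂², averaged over the two arms of the contrast on
normalized counts. A mean trend α(μ) = a₀ + a₁/μ is fitted by ordinary
least squares to the *untruncated* moment estimates (truncating negative
estimates at zero before fitting would bias the trend upward); the
working dispersion is max(gene estimate, trend, 10⁻⁸) — a deliberately
conservative shrinkage that protects against underestimated variance at
three replicates.

The test statistic is a two-sided Wald z on
log₂FC = log₂((μ̂_num + ½)/(μ̂_den + ½)), with the variance of each arm
mean taken from the NB model (Var(X/s) = μ/s + αμ²) and propagated by the
delta method. The pseudo-count of 0.5 normalized counts stabilizes fold
changes when one arm is near zero. Genes with zero counts in every sample
of both arms are reported with missing p and excluded from the
Benjamini–Hochberg ranking, so m reflects tested genes only. Measured
under the package's own null simulation (α = 0.1, 3 vs 3, 2000 genes),
the raw p < 0.05 fraction sits at 0.04–0.05 — slightly conservative, as
expected from the max-shrinkage rule.

A Wald test was chosen over the classical NB exact test deliberately: it
is transparent, fast, checkable against closed forms, and the
symmetric-in-arms invariant (swapping numerator and denominator flips
log₂FC and preserves p) holds exactly.

DEGs are genes with |log₂FC| ≥ 0.5 and FDR < 0.05 (the ≥ boundary is
intentional and differs from the strict > used by the call-back tiers
below; both conventions are exercised at their boundaries in the tests).

## Call-back classification

For each treatment, the injury table (ADM vs NC) and the rescue table
(treatment vs ADM) are combined per gene into one of three mutually
exclusive tiers, assigned in order 1 → 2 → 3:

* **Level 1**: |log₂FC| > 0.5 and FDR < 0.05 in both contrasts, with
  opposite signs.
* **Level 2**: the same with |log₂FC| > 0.1.
* **Level 3**: injury contrast unaltered (FDR > 0.05) but treatment
  contrast significant with |log₂FC| > 0.1.

Direction is *up-called-back* (injury down, treatment up) or
*down-called-back* for levels 1–2, and *treatment-up/down* for level 3.
Mutual exclusivity makes {level 1, 2, 3, none} a partition, so
cross-treatment intersections report disjoint per-level counts. Genes
untested in either contrast (all-zero counts) are classified *none*:
"unaltered" in the level-3 rule requires a tested, non-significant
result, not an absence of data. A gene whose injury FDR is exactly 0.05
satisfies neither FDR < 0.05 nor FDR > 0.05 and is likewise *none*.

Shared/unique sets across treatments are plain set intersections per
level and direction; UpSet-style tables report exclusive intersection
sizes over every combination of DEG lists, which sum to the union size.

## Gene-set enrichment

Over-representation of a query list (one tier × one direction) against
GMT-supplied gene sets uses the exact hypergeometric upper tail
P(X ≥ k) for X ~ Hypergeometric(N, K, n). The universe defaults to all
genes tested in the injury contrast and annotated to at least one term —
the background the query was actually drawn from. GO-style collections
are Bonferroni-corrected with m = number of terms having K ≥ 1 in the
universe; pathway-style collections use BH; the significance threshold is
corrected p ≤ 0.05 and both raw and corrected p are always emitted, since
which scale a downstream tool thresholds on varies. The rich factor k/K
accompanies every term for bubble-plot-style reporting.

## qPCR concordance

Relative expression is 2^−ΔΔCt: ΔCt = Ct_target − Ct_reference within the
same sample (pairing within sample means any per-sample shift — e.g.
input amount — cancels exactly), ΔΔCt subtracts the calibrator arm's mean
ΔCt, and amplification efficiency is fixed at the method's assumed 2.
The calibrator defaults to NC. Concordance with RNA-seq is the Pearson
correlation of log₂ fold changes over genes × contrasts — arms against
the calibrator plus treatments against the injury model, mirroring the
design's five contrasts — together with the sign-agreement fraction and a
descriptive correlation p-value.

## Synthetic data generator

`simdata` draws a full study dataset with known truth. Per gene: a
baseline mean 2^U(0, 14) (about four orders of magnitude, a realistic
bulk RNA-seq dynamic range — wide enough that within-arm replicate
correlations on log₂(FPKM+1) exceed 0.98 at low dispersion, the QC bar
real replicates of this design meet); an archetype; and arm means that
apply the archetype's true log₂ effects multiplicatively. Counts are NB
with dispersion α(μ) = a₀ + a₁/μ (default (0.05, 0) — a flat, moderately
low dispersion typical of cell-line replicates) and per-sample lognormal
depth factors (σ = 0.1) exposed in the output so size-factor recovery is
testable.

Archetypes and default fractions: fully restored up/down (0.15 each,
injury effect ∓1.5 log₂ units fully reversed by every treatment),
partially restored (0.10, random injury sign, 30% of the effect
reversed — deliberately inside the weak level-2 band), injury-only
(0.10), treatment-only (0.10, level-3 pattern), and null (0.40). The
fractions are a design choice — no real-data estimate of archetype
prevalence exists — picked so that DEG counts and call-back yields land
in a plausible regime while leaving a large null fraction for specificity
measurement. Each gene's expected level is a pure function of its true
effects (a true effect being "significant" exactly when nonzero) and is
stored in the truth table.

Gene sets are GMT-serializable draws from the gene universe; a stated
fraction are enriched by building 80% of their members from
restored-archetype genes, and those term ids are flagged as the
enrichment oracle. Ct tables follow Ct = 20 − log₂(relative expression) +
N(0, 0.2²) cycles, with a null-archetype gene required as the reference
(a non-constant normalizer is rejected). The simulated qPCR panel in the
full pipeline is the 13 most strongly expressed fully-restored genes —
the robust, validated DEGs a real panel targets.

What the generator does **not** emulate: GC/length biases, outlier
samples and batch effects, correlated genes (all genes are independent
given depth), isoform-level effects, and dispersion outliers. Passing
tests therefore demonstrate correctness of the statistical machinery
under the stated model, not robustness to every artefact of real
libraries.

## Numerical and degenerate-input choices

* Explicit seeds everywhere; no global RNG state. Fixed config + seed
  reproduces every output file byte-for-byte (floats are written with a
  fixed `%.10g` format); the run manifest's wall-clock fields are the one
  exception, being timing metadata rather than analysis output.
* Dispersion floor 10⁻⁸; size factors require ≥ 2 replicates per arm;
  PCA components are sign-canonicalized (largest-magnitude loading
  positive) so scores do not depend on the SVD implementation's sign
  convention.
* FPKM uses the matrix's own column totals as the per-sample library
  size; alignment-level "total mapped fragments" is unavailable at the
  count-matrix entry point, so FPKM values are internally consistent
  rather than comparable to alignment-derived ones.
* Replicate correlation is Pearson on log₂(FPKM + 1); zero-variance
  samples yield missing correlations with a warning rather than an error.
* Hypergeometric p at k = 0 is exactly 1; a term equal to the universe
  forces k = n and p = 1.

## Problem sizes

The test suite and the acceptance script run simulations at 2000 genes ×
12 samples with 5 seeds where averaging is needed — large enough for
stable rates (type-I fraction standard error ≈ 0.005) while keeping a
full run in seconds.

## Known limitations

* Two-group contrasts only; no GLM with covariates or paired designs.
* Conservative dispersion shrinkage trades a little power for type-I
  safety at n = 3; at larger n a regularized-likelihood estimator would
  dominate.
* No independent filtering before FDR beyond dropping all-zero genes.
* Enrichment treats terms independently: no hierarchy propagation or
  redundancy pruning.
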