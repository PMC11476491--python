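# rescueseq

Bulk RNA-seq analysis for **injury–rescue designs**: experiments with a
normal control arm (NC), an injury model arm (e.g. podocytes injured with
adriamycin, ADM), and one or more treatment arms in which a candidate drug
is tested for its ability to push the injured transcriptome back toward
normal. The package identifies **call-back genes** — genes the injury
shifts and a treatment shifts back — and quantifies how strongly each
treatment reverses the injury signature.

It is aimed at analysts working with count matrices from such designs who
want the full chain — normalization, differential expression, call-back
classification, gene-set enrichment, qPCR validation — as tested,
scriptable Python, plus a ground-truth simulator to validate every step.

## The model

Counts are negative binomial with Var = μ + αμ². For a two-arm contrast,
per-gene dispersions are method-of-moments estimates on size-factor
normalized counts (median-of-ratios normalization), shrunk conservatively
toward a fitted trend α(μ) = a₀ + a₁/μ by taking the maximum of gene
estimate and trend. Significance is a two-sided Wald test of
log₂FC = log₂((μ̂₁ + ½)/(μ̂₂ + ½)) with a delta-method standard error, and
Benjamini–Hochberg FDR control across genes. DEGs satisfy |log₂FC| ≥ 0.5
with FDR < 0.05.

Given the injury contrast (model vs NC) and a rescue contrast (treatment
vs model), each gene is assigned one of three mutually exclusive call-back
tiers per treatment:

| level | injury contrast | treatment contrast | pattern |
|-------|-----------------|--------------------|---------|
| 1 | \|log₂FC\| > 0.5, FDR < 0.05 | \|log₂FC\| > 0.5, FDR < 0.05, opposite sign | strong call-back |
| 2 | \|log₂FC\| > 0.1, FDR < 0.05 | \|log₂FC\| > 0.1, FDR < 0.05, opposite sign | weak call-back |
| 3 | FDR > 0.05 (unaltered) | \|log₂FC\| > 0.1, FDR < 0.05 | treatment-specific |

Genes suppressed by injury and restored upward are *up-called-back*; the
inverse pattern is *down-called-back*. Call-back lists are intersected
across treatments, tested for gene-set over-representation with the exact
hypergeometric upper tail (Bonferroni for GO-style sets, BH for
pathway-style sets; rich factor k/K reported), and validated against qPCR
relative expression computed by the 2^−ΔΔCt method against a reference
gene and calibrator arm.

The `simdata` module generates the whole study design — NC/ADM/W1CC/W5CC,
three replicates per arm — with known per-gene archetypes (fully restored
up/down, partially restored, injury-only, treatment-only, null), so the
pipeline's recovery of the truth is directly measurable.

## Worked example

```python
from rescueseq import (SimConfig, simulate_counts, size_factors, nb_test,
                       Contrast, classify_callback, call_degs)

config = SimConfig(n_genes=2000, seed=1)
counts, truth = simulate_counts(config)

factors = size_factors(counts, total_count_fallback=True)
injury = nb_test(counts, Contrast("ADM", "NC"), factors=factors)
rescue = nb_test(counts, Contrast("W1CC", "ADM"), factors=factors)

degs = call_degs(injury)
print(f"injury DEGs (|log2FC| >= 0.5, FDR < 0.05): {len(degs)}")

assign = classify_callback(injury, rescue)
levels = assign["level"].value_counts().sort_index()
print(f"W1CC call-back genes: level 1 = {levels.get(1, 0)}, "
      f"level 2 = {levels.get(2, 0)}, level 3 = {levels.get(3, 0)}")

well_measured = (
    truth["archetype"].isin(("restored_up", "restored_down"))
    & (truth["baseline_mean"] >= 50)
)
hit = assign.loc[well_measured, "level"].isin((1, 2)).mean()
print(f"fully rescued genes (baseline mean >= 50) recovered: {hit:.1%}")
```

Output:

```
injury DEGs (|log2FC| >= 0.5, FDR < 0.05): 828
W1CC call-back genes: level 1 = 503, level 2 = 0, level 3 = 222
fully rescued genes (baseline mean >= 50) recovered: 98.8%
```

828 of the 2000 simulated genes pass the DEG thresholds in the injury
contrast (the generator plants effects in ~60% of genes, but low-expressed
ones lack power at three replicates). Of the genes W1CC truly rescues,
503 reach the strong level-1 tier; 222 treatment-only genes land in level
3; and essentially every fully rescued gene that is well expressed
(baseline mean ≥ 50 counts) is recovered.

The same chain runs from the shell:

```sh
rescueseq run-all --config config.yaml --seed 1
```

with a YAML config holding either input paths (counts/sample-sheet TSVs,
GMT annotation, Ct table) or a `simulate:` block. Individual stages are
exposed as `simulate`, `validate`, `quantify`, `detest`, `callback`,
`enrich`, and `qpcr` subcommands; each writes deterministic TSVs that the
next stage reads back.

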