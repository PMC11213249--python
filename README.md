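# leafmix

Cell-type deconvolution of bulk leaf RNA-seq time series against a labelled
single-cell reference — with a simulated-mixture accuracy benchmark, temporal
and trait profiling of cell-type activity, group-mode cell-type expression
imputation, and context-filtered regulatory-network term enrichment.

## The problem

Bulk RNA-seq of a leaf mixes the transcripts of many cell types. Given a
labelled single-cell reference, the share of a bulk sample's transcripts
attributable to each cell type's expression program — its *transcriptional
activity* — can be estimated by signature-based deconvolution:

> **b** ≈ **S f**,  **f** ≥ 0,  Σₖ fₖ = 1

where **b** is the bulk expression vector over marker genes, **S** is the
signature matrix (per-type mean expression of marker genes, linear scale) and
**f** the cell-type fraction vector. Tracking **f** across diurnal and
developmental time series reveals when each cell type is transcriptionally
active; regressing bulk expression on fraction trajectories recovers
cell-type-level expression of gene sets of interest; and thresholding a
TF→target network by context-specific expression extracts the regulatory
subnetwork active in a chosen cell type, age and time of day, summarized as a
functional-term pair enrichment graph (an exact binomial upper tail per
ordered term pair).

The package is aimed at plant (and other) transcriptomics researchers who
have a clustered single-cell reference and bulk time series and want a
tested, scriptable pipeline for the whole path — including synthetic-data
generators with planted ground truth, so every stage can be validated before
touching real data.

## Worked example

Simulate the default 10-type leaf reference (three mesophyll groups and a
rare hydathode-like type whose expected profile is 80% mesophyll), split
cells 75/25 per type, build the signature on training cells, simulate 500
mixed pseudobulks (mean 600 cells; per-type proportions drawn from
Normal(p, p), negatives clamped to 0) from held-out cells, deconvolve, and
score:

```python
import leafmix as lm

ref = lm.simulate_reference(lm.leaf_reference_config(seed=1))
split = lm.split_train_test(ref.labels, seed=2)
signature = lm.build_signature(ref.counts[split.train_cells],
                               ref.labels.loc[split.train_cells])
print(f"signature: {signature.values.shape[0]} genes x "
      f"{signature.values.shape[1]} types, "
      f"condition number {signature.condition_number:.2f}")

mixed = lm.simulate_mixed_bulks(
    ref.counts[split.test_cells], ref.labels.loc[split.test_cells],
    reference_proportions=ref.labels.value_counts(normalize=True),
    n_samples=500, mean_cells=600, with_replacement=True, seed=3)
fractions = lm.deconvolve(mixed.counts, signature, method="nnls", n_perm=0)
report = lm.benchmark_report(mixed.realized_fractions, fractions.fractions)
print(report.per_type[["pearson_r", "slope"]].round(3))
```

Output:

```
signature: 305 genes x 10 types, condition number 9.70
                   pearson_r  slope
bundle_sheath          0.993  0.917
companion              0.993  0.953
epidermis              0.996  1.024
guard                  0.993  0.840
hydathode              0.311  0.245
mesophyll_1            0.958  0.800
mesophyll_2            0.994  0.841
mesophyll_3            0.992  0.987
phloem_parenchyma      0.991  0.948
vascular               0.993  0.909
```

Every separable cell type is recovered with Pearson r > 0.95 and a best-fit
slope near 1 (slope 1 means unbiased prediction). The rare hydathode-like
type, whose planted profile is deliberately confusable with mesophyll group
1, fails (r = 0.31) — its single-type pseudobulks are mostly classified as
mesophyll group 1, the known failure mode of leaf deconvolution references.

The same estimators compose with scikit-learn: `SignatureBuilder` and
`Deconvolver` are `BaseEstimator`s with `fit`/`predict` over cells × genes
and samples × genes matrices.

A `leafmix` console script exposes the pipeline for shell use:
`leafmix simulate reference|bulks|network`, `leafmix build-signature`,
`leafmix deconvolve`, `leafmix impute`, `leafmix bench mix|score`,
`leafmix temporal ...` and `leafmix atlas filter|pafway|scan|compare`.

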