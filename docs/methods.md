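# Methods

## Model

A bulk expression profile is modelled as a non-negative linear mixture of
cell-type expression programs: over the signature genes, `b ≈ S f` with
`f ≥ 0` normalized to sum 1. The recovered `f` is a *transcript share*, not a
cell count: a type with few but transcriptionally hyperactive cells receives
a large fraction. All computation is on the linear expression scale; quantile
normalization is deliberately not applied anywhere. The model assumes the
reference profiles are representative of the bulk tissue's cell states and
that cross-type spillover (ambient RNA, doublets) is negligible.

## Signature construction

1. **Gene pre-filter.** Genes with ln(total read count) outside [4, 10]
   (inclusive) are removed; zero-total genes always are. Very lowly expressed
   genes carry no stable cell-type signal; very highly expressed ones
   dominate least-squares fits.
2. **Depth normalization.** Counts-per-10,000 per cell. Scale-free across
   cells and linear, as the mixture model requires.
3. **Marker ranking.** Per type, a two-sided Wilcoxon rank-sum test of that
   type's cells against all others, Benjamini–Hochberg corrected; genes with
   q < 0.3 (default) and fold change > 1 form the candidate pool, ordered by
   fold change (ties broken by gene id, for determinism).
4. **Size selection.** For g across 50–150 (default), a candidate signature
   takes the top min(g, pool) markers of every type; the matrix of per-type
   mean expression over the union of selected genes whose 2-norm condition
   number is smallest is kept (ties → smaller g). A condition number above
   1e6 triggers an ill-conditioning warning (near-duplicate types).

The search range and q threshold are conventions of the signature-matrix
deconvolution family, exposed as parameters. On synthetic references whose
planted marker pools are smaller than g, the scan degenerates gracefully to
the full significant pool.

## Deconvolution engines

* **nnls** (default): non-negative least squares per sample. Deterministic,
  exact on noiseless mixtures, scale-invariant after row normalization.
* **svr**: linear-kernel ν-support-vector regression with ν ∈
  {0.25, 0.5, 0.75}, response and signature columns standardized per sample,
  negative coefficients clamped to 0, lowest-reconstruction-RMSE ν kept.
  C = 1 by default; the regularization makes it slightly conservative on
  extreme fractions, which is why nnls is the default for benchmarking.

**Fit significance.** Per sample, the Pearson correlation between the
observed bulk vector and its reconstruction is compared with fits on
gene-label-permuted signatures (default 100 permutations, shared across
samples for speed and determinism); p = (1 + #{r_perm ≥ r_obs}) / (n_perm +
1), so p ∈ (0, 1]. Under a gene-permuted null this is calibrated (measured
rejection 0.04 at α = 0.05 over 200 null samples).

**Group-mode imputation.** Types are ranked by mean fraction; the 9 most
abundant (default) are kept and the rest summed into "other". Per gene, the
across-samples system `bulk_gene ≈ F h` is solved by NNLS. This requires at
least as many samples as retained types and a full-rank fraction matrix
(rank deficiency is flagged, not fatal). Gene→type assignment uses an
α-of-max rule (α = 0.5 default): a gene belongs to every type whose imputed
value is at least α times its row maximum; the exact published assignment
rule is not documented anywhere we know of, so the rule is declared and
parameterized.

## Simulated benchmark

Cells are split 75/25 per type (round(0.75 n) training, ≥ 1 test cell).
Single-type pseudobulks sum two equal halves of a type's test cells. Mixed
pseudobulks draw, per sample and type, a proportion from Normal(p, p) — mean
*and* SD equal to the reference proportion — clamp negatives to 0, scale by
the target mean cell count (600) and round; the drawn cells' counts are
summed gene-wise. Scoring uses the *realized* fractions (cells actually
drawn): clamping and rounding make the intended draw vector unnormalized and
unattainable. Note the mean realized fraction is a ratio of clamped draws
and therefore not an unbiased estimate of p (Jensen); the per-type mean
*cell count* is calibrated and has the closed form
E[max(N(p,p),0)] = p·(Φ(1)+φ(1)).

At desk scale (≈500 test cells) a 600-cell target cannot be met without
reusing cells, so the benchmark is run with replacement; the operation's
default remains sampling without replacement with a logged cap at the
available pool.

Accuracy is reported per type as the Pearson correlation across samples
between realized and predicted fractions, the OLS slope (with intercept) of
predicted on true, and an argmax confusion matrix for single-type bulks
(ties → lexicographically first type id).

## Synthetic data generators

* **Reference**: per-type expected profiles are flat at `baseline_mean`
  (0.3 counts/gene/cell by default) with `markers_per_type` (25) marker
  genes raised `marker_fold_change`-fold (4×); counts are negative binomial
  with size `dispersion` (0.4 — strong overdispersion typical of UMI-free
  single-cell data). A confusable pair (a, b, w) replaces profile_b with
  (1−w)·profile_b + w·profile_a *before* sampling, so ground truth stays
  well-defined. The default leaf roster has 10 types — three mesophyll
  groups, epidermis, vascular, bundle sheath, companion, guard, phloem
  parenchyma, and a rare hydathode (60 of 2040 cells) mixed with w = 0.8
  toward mesophyll group 1. With these settings the hydathode's
  distinguishing signal is small relative to the sampling noise of its few
  training cells, so its signature column is noise-attenuated and NNLS
  shifts weight to the collinear mesophyll column — reproducing, by
  mechanism and not by fiat, the misclassification seen with real leaf
  references.
* **Bulk series**: per-type weight trajectories (sinusoid with 24 h period
  peaking at `phase_hours`; linear monotone trend; constant), normalized to
  fractions per timepoint, perturbed per replicate by Gaussian weight noise
  (clamped at 0, renormalized — fractions stay on the simplex); expected
  expression is the fraction-weighted profile mixture scaled to the
  sequencing depth, with Poisson count noise. Optional traits (pseudotime,
  biomass, leaf area) are monotone functions of the time axis plus small
  noise.
* **Network**: disjoint TF and target pools, edges sampled without
  replacement from the TF×target grid with planted (A, B, f) cells
  oversampled f-fold; each gene carries each term independently with
  `annotation_prob`. Planted A→B expectation is f·p0·N/(1+(f−1)·p0).

What the generators do **not** emulate: real gene identities, UMI chemistry,
doublets, ambient RNA, cell-cycle structure, library-size variation between
cells, or annotation correlation between functional terms. Passing tests
therefore demonstrate correctness of the pipeline's computations and its
behaviour under the modelled noise, not performance on any particular real
dataset.

## Functional-term network

For each ordered term pair (A, B), observed = edges whose source carries A
and target carries B; p0 = (fraction of the network's *source* genes
carrying A) × (fraction of its *target* genes carrying B); expected = N·p0;
p-value = exact binomial upper tail P(X ≥ observed). Frequencies are
computed over the genes of the (filtered) network, conditioned on role:
regulator pools are far smaller than target pools, and a role-blind pooled
frequency misstates the null edge probability badly enough to inflate the
type-I error fourfold in simulation. With role-conditional frequencies the
measured type-I error is 0.043 at α = 0.05 (200 null networks, grid density
0.033); a planted 5-fold-enriched pair with base expectation ≥ 2 is detected
in 100 % of 100 replicates. Raw p-values at 0.05 are the default criterion
(BH correction available behind a flag).

**Context filter.** A gene passes iff expression > sc_threshold (strict) in
≥ 1 selected cell type AND > bulk_threshold in ≥ 1 selected sample (the
quantifier is configurable to ALL); an edge survives iff both endpoints
pass; genes absent from a table fail conservatively. Raising either
threshold can only shrink the edge set, so threshold grids produce nested
networks; the scan flags local maxima (strictly greater than both
neighbours) and inflection points (sign change of the discrete second
difference) along each 1-D slice of the significant-edge count.

## Numerical conventions

* Sample (n−1) standard deviations throughout; constant columns z-score to
  zeros (detected by exact range, not by floating sd).
* z-scoring happens after replicate averaging, stated in output metadata.
* Spearman correlations use average ranks for ties; undefined statistics are
  reported missing (NaN), never zero.
* All randomness flows through `numpy.random.default_rng(seed)`; identical
  seeds give byte-identical outputs; no global RNG state.
* Matrix Market files are 1-based on disk, 0-based in memory; tables are
  written with 6 significant digits.

## Problem sizes

The benchmark suites run at: 10 types / 2040 cells / 3000 genes with 500
mixed pseudobulks for the headline benchmark; 5 types / 600 genes for the
permutation-calibration suite (200 null samples × 100 permutations); 200
replicate networks of 800 edges for the enrichment calibration; 6 types /
1200 genes, 12 timepoints × 4 replicates for the temporal-recovery suite.
These sizes make every planted effect comfortably detectable while keeping
the full suite fast on a laptop.

## Known limitations

* Group-mode imputation only; per-sample ("high-resolution") per-gene
  imputation is out of scope.
* No cross-platform/batch correction between reference and bulk.
* The SVR engine is a convention-compatible reimplementation, not a
  bit-level reproduction of any hosted service.
* The hydathode-confusion reproduction is a qualitative mechanism match;
  per-type accuracies on real references depend on their depth, cluster
  quality and cell counts.
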