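# Methods

This note documents the models, defaults and numerical choices behind
`netomics`, and what the synthetic-data experiments do and do not
demonstrate.

## Synthetic cohorts

`synthetic.SimulationConfig` defines the generative model every stage is
validated against. Each module *m* has an independent standard-normal
latent factor *E_m* per sample; a module gene is
`x = u·E_m + sqrt(1 − u²)·ε` with loading `u ~ Uniform(loading_range)`, so
`u` is the gene–factor correlation. Rows are standardized (mean 0, sd 1,
population convention) after noise injection. Metabolites reuse the *same*
factor values: `y = r·E_k + sqrt(1 − r²)·ε`, which plants exactly the
cross-omic correlation the integration stage must find. Defaults — 6
modules × 50 genes, 700 background genes, n = 60 samples, loadings
0.6–0.95, metabolites at r = 0.8 — are the reference study conditions:
sample sizes in the tens, module-scale gene counts, and cross-omic
correlations strong enough to be biologically reportable yet well below 1.
Within-module correlation strength of real tumor cohorts is not known
precisely; the 0.6–0.95 loading range is a choice, exposed in the config.

Survival times are exponential per group with independent exponential
censoring; the censoring hazard is `h·c/(1 − c)` so `censor_rate = c` is
the expected censored fraction. Subtype cohorts shift a block of marker
genes by +2 sd in samples of each class.

What the generator does **not** emulate: probe-level microarray artifacts,
batch effects, overlapping/correlated modules, heavy-tailed expression,
realistic NMR baseline drift beyond a low-order polynomial, or
non-proportional hazards. Passing tests therefore demonstrate correctness
of the algorithms under the stated model, not performance on real tissue
data.

## NMR quantification

The fit is a deterministic template regression, a desk-scale alternative
to MCMC-based Bayesian spectral deconvolution: unit-area templates (static
multiplet peak lists; J-coupling fine structure is baked into the peak
list rather than modelled) are combined nonnegatively with a sign-free
polynomial baseline (degree 3 by default) and per-metabolite shift offsets
searched on a grid (default ±0.01 ppm, step 0.001 ppm, one coordinate
pass in library order, ties toward smaller |Δ|). Because the current
solution is always a candidate, the objective is non-increasing across the
pass. Templates ship as JSON for lactate, creatine, glycine, choline,
phosphocholine and myo-inositol with literature chemical shifts.

Calibration pins the lactate methyl resonance to 1.310 ppm. The apex is
located among *candidate* peaks — maxima of contiguous runs above 80% of
the window maximum — and the candidate requiring the smallest axis shift
wins. This makes the choice between the two near-equal lines of the
lactate doublet robust to noise; a naive global argmax can jump 0.02 ppm
between lines on noise alone.

QC: a fit passes when `‖y − fit‖₂/‖y‖₂ ≤ 0.25` (configurable). Note the
residual of a *perfect* fit equals the injected noise, so on a dense grid
this threshold corresponds to roughly SNR ≥ 90; spectra at SNR 50 are
quantified accurately (≤ 10% error) yet flagged by the default threshold.
Set `qc_threshold` to the noise regime of the instrument.

Normalization follows the two-step scheme: per-sample division by DNA
concentration (tissue-amount correction), then scaling every sample so its
median equals the median of sample medians. After the second step all
column medians are exactly equal. Rescaling one raw column cancels out of
the composition *provided* the median-of-medians reference is unchanged;
a rescaling large enough to move the reference changes all columns — an
intrinsic property of median-reference normalization.

## Network construction

Pearson correlation on standardized expression (constant genes dropped
with a warning); unsigned adjacency `|cor|^β` by default, signed
`((1+cor)/2)^β` by flag. β is the smallest candidate whose scale-free fit
index (R² of log₁₀ p(k) vs log₁₀ k over 10 connectivity bins, signed
negative for positive slopes) reaches 0.8, falling back to the best
candidate with a warning.

TOM is computed by matrix products and verified in the tests against a
double-loop oracle; `TOM_ii = 1`, values clipped to [0, 1] and
symmetrized against floating-point drift.

Modules: average-linkage clustering of 1 − TOM with a *static* cut
(default height 0.95), clusters under 20 genes unassigned (label 0),
remaining modules numbered by decreasing size. The static cut is
deliberately simpler than dynamic tree-cut variants; its height default
was set by the module-recovery experiment on the reference cohort — at a
0.99 cut the background noise genes merge into modules well before the
cut (unsigned network, β ≈ 4–5, n = 60), while 0.95 cleanly separates
them (recovery ARI 0.92–1.0 across seeds). Both height and minimum size
are exposed.

Eigengenes are PC1 sample scores of the row-standardized module submatrix
(SVD), scaled to sd 1 and sign-oriented so the mean correlation with the
module's genes is positive. kME is the gene × module eigengene
correlation for **all** pairs, the standard module-membership definition;
GS (gene × metabolite correlation) is kept as a separate table. Both are
computed over the intersection of samples present in the two assays
(≥ 3 required) — transcriptome and metabolome cohorts rarely coincide
sample-for-sample, and intersection matching is the explicit contract.

## Integration

Module–metabolite correlation uses the exact t transform
`t = r·sqrt((n−2)/(1−r²))` with n−2 df for two-sided p-values, adjusted by
Benjamini–Hochberg across the entire matrix.

Cluster-of-clusters places modules and metabolites in one space: on the
magnitude matrix A = |r|, module–module similarity is the Pearson
correlation of A-rows, metabolite–metabolite of A-columns, and
module–metabolite is A itself; average linkage on 1 − similarity, cut to
k clusters (default 4; automatic mode picks k ∈ 2..8 by silhouette).
Working on |r| rather than r makes assignments exactly invariant to the
arbitrary sign of an eigengene and avoids a failure mode where two
modules' signed profiles are strongly *anti*-correlated by noise and a
|profile-correlation| similarity would merge them.

Key metabolite per cluster: argmax over the cluster's metabolites of
Σ |r| to the cluster's modules; ties break lexicographically with a
warning. Bipartite export keeps module–metabolite (optionally
gene–metabolite via GS) edges with |weight| ≥ threshold; node score =
weighted degree; hubs = nodes at or above the 0.9 score quantile.

## Enrichment

Pre-ranked GSEA: genes sorted by decreasing statistic (kME normalized by
the module's max |kME| — "normalized intramodule connectivity"; the
normalization convention is ours), running sum with hit increments
`|stat|^p / Σ_set |stat|^p` (default weight p = 1, exposed) and miss
decrements `1/(N − |S|)`; ES is the extremum of largest magnitude. The
null resamples random same-size gene sets (a pre-ranked list has no
phenotypes to permute); p uses the positively biased-safe
`(count + 1)/(n_perm + 1)` estimator, NES divides by the mean |permuted
ES| of the same sign, and FDR across sets is Benjamini–Hochberg.

Per-sample scores are an ssGSEA-style rank statistic (weighted in-set vs
out-of-set ECDF difference on within-sample ranks, exponent 0.25), a
deliberate stand-in for kernel-CDF estimators; scores depend on
expression only through ranks.

## Cohort analyses

Consensus clustering follows the Monti scheme: per k, resample 80% of
samples 100 times (defaults), cluster by average-linkage/Euclidean,
normalize co-membership by co-sampling counts. The consensus CDF area and
its relative increase choose k: best_k is the argmax of delta-area over
k ≥ 3 (k = 2 when kmax = 2) — an explicit rule in place of choosing k by
visual inspection of the CDF curves.

Kaplan–Meier and the log-rank test are implemented from their closed
forms (product-limit estimator; observed − expected with hypergeometric
variance, chi-square with groups − 1 df) so the textbook examples are
verifiable by hand, and the implementation is cross-checked against an
independent survival library in the tests. The Cox hazard ratio is fitted
by `lifelines` (partial likelihood), a standard-model step rather than a
contribution of this package. The subtype classifier is a scikit-learn
random forest; its published accuracy on external consortium training
data depends on that data and is not a target here.

## Problem sizes and determinism

Default experiment sizes (reference cohort of 1 000 genes × 60 samples;
50-seed recovery experiments; 20-seed spectral fits; 1 000 GSEA
permutations for signal, 200 for null calibration) were chosen so the
full validation runs in minutes on a laptop while leaving the measured
rates far from their thresholds. All randomness flows through explicit
`numpy.random.default_rng` seeds — there is no global RNG state — and the
full pipeline is byte-identical across reruns with the same seed.

## Known limitations

* The static dendrogram cut cannot rescue nested or overlapping modules;
  real cohorts may need dynamic tree cutting (out of scope).
* Template regression assumes the template list spans the spectrum;
  unmodelled resonances bleed into the baseline or inflate residuals.
* The gene-set permutation null in pre-ranked GSEA is known to be more
  liberal than phenotype permutation on correlated real data; on
  independent synthetic rankings it is calibrated (measured type-I
  ≈ 0.05).
* Automatic k selection (silhouette / delta-area) is heuristic; both
  interfaces accept a fixed k.
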