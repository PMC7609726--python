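# Methods

This note records the model, the numerical conventions and the design
choices behind `comira`, in the order the pipeline runs them.

## Network model and assumptions

The discovery stage assumes that co-regulated miRNAs share latent
expression programs that show up as correlation in log-scale intensity
data. The network is **unsigned**: similarity is the absolute Pearson
correlation, so anti-correlated members of one regulatory program are
treated as connected and land in the same module. Correlations use
pairwise-complete samples; a feature pair with fewer than 3 complete
pairs is a hard error, and zero-variance features are dropped before
network construction. Input is assumed to be on a log scale already
(array export convention, features × samples); no normalisation is
applied.

## Soft thresholding

The similarity is raised elementwise to an integer power β ∈ {1..20}.
For each candidate, connectivities k_i (diagonal excluded) are binned
into 10 equal-width bins; log10(per-bin frequency) is regressed on
log10(per-bin mean k) over non-empty bins with positive mean, and the
signed fit index is −sign(slope)·R², so a decreasing power-law-like
relationship scores positive. Fewer than 3 usable bins (e.g. a regular
graph) marks the fit invalid (NaN) rather than raising. The selected β
is the smallest candidate with index ≥ 0.80; when nothing passes, the
argmax is returned with a warning. The 0.80 target and the 10-bin
equal-width scheme are conventional defaults for this fit; the index is
a diagnostic, not a hypothesis test.

## Topological overlap

TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij) with
l_ij = Σ_{u≠i,j} a_iu·a_uj; the adjacency diagonal is treated as zero
inside the formula (no self-overlap inflation), TOM_ii = 1, and the
clustering distance is 1 − TOM. Entries are symmetrised and clipped to
[0, 1] to absorb float noise; the matrix implementation is tested to
1e-12 against a naive triple loop.

## Module detection

Average linkage (UPGMA) on 1 − TOM builds the dendrogram
(scipy's implementation; heights are monotone for average linkage on a
proper dissimilarity). The branch cut is deterministic:

1. cut the tree at `min + cut_quantile·(max − min)` of the merge-height
   range (default `cut_quantile = 0.99`);
2. every resulting branch with ≥ `min_size` (default 5) leaves becomes
   a module; smaller branches go to grey;
3. a PAM-like rescue stage reassigns each grey leaf to the module with
   the smallest average dissimilarity to its members, provided that
   average is below the grand mean of within-module dissimilarities
   (pooled over modules) — genuinely unconnected features stay grey.

The cut height is a fraction of the height *range* rather than an
empirical quantile of the merge heights: with average linkage on 1−TOM
the inter-module merges crowd into the top percentile of heights, and an
empirical-quantile cut there collapses the tree into one branch. The
range-fraction rule places the cut just below the top merges and
recovers planted modules reliably (reference scenario below: mean
adjusted Rand index 0.91–0.96 over 20 simulations). This cut is a
deterministic variant of dynamic tree cutting; equivalence with any
particular reference implementation is not promised — correctness is
assessed by planted-module recovery.

Module eigengenes are the first right-singular vector of the
standardized (per-feature zero mean, unit variance) module submatrix:
unit norm over samples, sign aligned so the correlation with the mean
standardized member profile is non-negative (making module–trait
correlation signs reproducible), with variance explained =
σ₁²/Σσ². Zero-variance members are dropped with a warning; a singleton
module's eigengene is its own standardized profile.

Modules whose eigengenes correlate above `merge_similarity`
(default 0.75, i.e. cut height 0.25 on 1 − cor) are merged iteratively
— eigengenes recomputed after every pass — until no pair merges; the
module count strictly decreases each pass, so the loop terminates.
Colors follow the canonical palette (turquoise, blue, brown, ...) by
decreasing module size, ties broken by first appearance; grey is
reserved for unassigned features and never merges.

## Module–trait analysis and hub ranking

Eigengene–trait and member-level correlations use Pearson r on
pairwise-complete samples with the Student transform
t = r√((n−2)/(1−r²)) on n−2 degrees of freedom (two-sided); |r| within
1e-12 of 1 returns p = 0 by convention. Raw p-values are reported by
default, matching the per-correlation p < 0.05 module-selection rule;
an optional, clearly-labelled Benjamini–Hochberg column is available
because many modules × many traits invites false positives. GS is
stored signed (the absolute value is a view): candidate ranking splits
members by GS sign and orders each side by GS p ascending, ties broken
by |GS| descending then feature id. Survival enters the discovery stage
as a plain numeric trait (observed months, censoring ignored) — a
deliberate simplification of discovery practice; censoring is honoured
only in the validation stage.

## Validation statistics

* **Pfaffl ratio** — E_t^ΔCq,t / E_ref^ΔCq,ref with ΔCq =
  Cq(calibrator) − Cq(sample); replicates are averaged (arithmetic
  mean) first; efficiencies default to 2.0 (exact 2^−ΔΔCq) when a Cq
  table carries none; the default calibrator is the sample-mean Cq,
  which rescales all ratios by a common factor and leaves
  between-sample comparisons untouched.
* **Mann–Whitney U** — exact by enumeration of all C(n_a+n_b, n_a)
  rank assignments (valid under ties, two-sided by deviation of U from
  its mean) when the pooled size is ≤ 12 in auto mode; otherwise the
  normal approximation with tie and continuity corrections. All values
  identical across both groups gives p = 1.
* **OS bins** — [0, 12), [12, 24], (24, ∞) months: the middle bin is
  closed on both ends so boundary ties fall inside it. Three-group
  expression comparisons report all three pairwise Mann–Whitney tests
  plus a Kruskal–Wallis omnibus, each labelled, rather than a single
  unexplained p.
* **Dichotomization** — the published "mean of the low expression
  group" cut-off is circular as printed; here the overall median
  defines a provisional low half, the cut-off is that half's mean, and
  the final split is high = value > cut-off. This is flagged as an
  interpretation. Under a no-effect generator the full
  dichotomize → log-rank chain rejects at ≈ 0.06–0.07 at nominal 0.05 —
  the selection-induced inflation is documented (bounded at 0.10 in the
  tests), not hidden.
* **Kaplan–Meier / log-rank** — product-limit estimator with events
  preceding censorings at tied times; two-group log-rank over pooled
  risk sets with the hypergeometric variance; HR = (O₁/E₁)/(O₂/E₂) and
  CI = exp(log HR ± 1.96√(1/E₁ + 1/E₂)). This is a risk-set summary,
  not a fitted proportional-hazards model; it recovers a planted HR of
  2 to within ±0.2 at 500 patients/arm and inverts exactly under label
  swap.

## Synthetic data

The generator is a Gaussian latent-factor model: factor f_m ~ N(0, I)
per module over samples; member i of module m has
x_i = w_i f_m + √(1−w_i²) ε_i, so E[cor(x_i, x_j)] = w_i w_j; background
features are pure noise. A quarter of each module's members get
negative loadings by default, exercising the unsigned network. Traits
are t = ρ f_m + √(1−ρ²) z; survival is exponential with hazard
λ₀ exp(γ f_m), censored at a fixed time, so exp(γ) is the true hazard
ratio for a one-SD factor contrast; Cq values follow
Cq = cq0 − log(x)/log(E) plus Gaussian noise, emitted in duplicate.
An optional factor correlation matrix (Cholesky mixing) plants module
hierarchies for merge tests. All draws are deterministic under the
design seed.

Two presets define the tested conditions:

* **reference**: 5 modules of sizes 20/16/12/10/8, loading 0.8,
  50 samples, 50 background features — the module-recovery benchmark.
* **paper-scale**: 274 features, 20 samples, 16 modules with sizes
  spanning 5–46 (7 background features), per-member loadings drawn
  U(0.6, 0.9) — a realistic spread for serum array data — with the
  size-16 module linked to survival (ρ = −0.59), albumin (−0.52),
  CRP (0.61), AFP (0.51) and nodule count (0.43), three pure-noise
  traits, and an exponential survival link with γ = log 2, baseline
  rate 1/24 per month and administrative censoring at 48 months.

What the generator does **not** emulate: array probe-level noise, batch
effects, heavy-tailed intensities, missing-at-random structure tied to
expression level, or correlated censoring. Passing tests therefore show
that the pipeline recovers correlational structure of the planted kind,
not that it is robust to every artefact of real array data.

## Known limitations

* At the paper-scale preset's 20 samples, eigengene–trait correlations
  are noisy: a planted |ρ| = 0.59 link is the top-ranked module in only
  ~70–80% of simulations, because the maximum over 15 competitor
  modules' null correlations (each ~|N(0, 0.23)|) regularly reaches
  0.5–0.6. This is an intrinsic small-sample limit of the design, and
  the end-to-end checks report the measured rate honestly.
* Dense matrices throughout: intended for a few hundred to a few
  thousand features, not 10⁴+ (no blockwise/sparse TOM).
* Unsigned networks and Pearson correlation only; no signed variant,
  no rank-based correlation options.
* The log-rank O/E hazard ratio is mildly conservative for large
  effects; no covariate-adjusted (Cox) modelling is provided.

## Problem sizes in the tests

Unit and end-to-end tests run at the preset scales above (≤ 274
features, ≤ 20 pipeline simulations, 10,000-replicate Monte-Carlo
calibrations, 500 patients/arm survival recovery); the whole suite
completes in well under a minute on one CPU.
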