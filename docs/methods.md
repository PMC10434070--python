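# Methods

## Scope and data model

`lakeco` analyses taxa × samples integer count tables (ZOTU-table
orientation: rows are taxa, so prevalence filters and niche-breadth sums are
row-wise), per-sample metadata (lake, salinity in %, climate covariates), a
rooted ultrametric phylogeny over the taxa, and a trophic annotation mapping
every taxon to one of six guilds (consumer, saprotroph, parasite,
photosynthetic, mixotroph, unclassified). Water classes derive from salinity
with configurable cutoffs, default freshwater < 1 %, brackish [1, 5),
subsalt [5, 10), salt ≥ 10 % — the literature gives category examples rather
than exact interval edges, so the edges are configuration, not science.
Missing covariates stay missing (NaN); nothing is imputed silently.

All file exchange is plain TSV/newick; downstream modules consume only the
in-memory types, never paths.

## Synthetic community generator

The generator emulates the study design the statistics assume: `n_lakes`
(default 8) × `samples_per_lake` (default 10) surface-water samples, one
mean salinity per lake (default levels 0.3–11.3 %, five freshwater lakes,
one brackish, one subsaline, one salt), per-sample salinities jittered
multiplicatively (lognormal, sd 0.05 on the log scale).

Taxon salinity optima evolve by Brownian motion along a pure-birth (Yule)
tree rescaled to height 1, so selection carries phylogenetic signal — the
premise that makes βNTI informative. Defaults: root optimum 2.5 %, Brownian
rate 3.5 % per unit branch, optima clipped to [0, 15] %. These yield a
predominantly freshwater-adapted regional pool in which salt tolerance is a
derived minority state, matching inland-lake systems where the salt-lake
community is a small, strongly filtered subset; they also make per-sample
richness fall from fresh to salt lakes. Regional (metacommunity) abundances
are i.i.d. lognormal (log-sd 1.5, the usual heavy-tailed species-abundance
shape).

Sampling weight of taxon *j* in a sample at salinity *s* is

    regional_j · exp(−(s − optimum_j)² / (2 σ_niche²))^w

with Gaussian niche width σ_niche = 1.5 % on the raw salinity axis (simplest
unimodal filter) and filtering strength `w` the central knob: `w = 0` is
neutral assembly (identical expected composition everywhere), large `w`
species sorting. The default `w = 3` represents a selected regime; the true
effect size in any real system is unknowable from published summaries, so
regime comparisons in the tests are ordinal (selected vs neutral), never
calibrated to published percentages. Counts are multinomial at fixed depth
(default 10,000), i.e. tables arrive on the post-rarefaction scale the
pipeline assumes.

The Yule simulator is in-package: after the last birth event all tips are
extended by one further exponential holding time, so pendant edges are
strictly positive and patristic distance is a metric on tips (off-the-shelf
birth–death simulators can emit zero-length pendant edges at the stopping
boundary, which breaks nearest-taxon logic).

All randomness descends from one master seed via `SeedSequence` spawning;
identical configurations are bit-reproducible.

What the generator does **not** emulate: sequencing error, chimeras, PCR and
copy-number bias, compositional coupling beyond the multinomial, temporal
dynamics, dispersal limitation by geography (space enters only through
lake-level covariates), and taxon–taxon interactions. Passing tests
therefore show the statistics behave correctly under species sorting on an
environmental gradient — not that any particular real community assembled
that way.

## Diversity and permutation statistics

Rarefaction subsamples each sample without replacement
(`multivariate_hypergeometric`) to the minimum sample total by default;
shallower samples either error or drop by policy. Shannon entropy uses the
natural log (base configurable). Bray-Curtis comes from
`scipy.spatial.distance`.

PERMANOVA is the one-way Anderson pseudo-F with free permutation of sample
labels (no strata — the sampling design gives no blocking), p = (1 +
#{F_perm ≥ F_obs}) / (1 + n_perm), so p never reaches zero. It is
implemented in-package so the permutation stream is seed-deterministic; the
statistic is cross-checked against scikit-bio's PERMANOVA in the tests and
against exhaustive relabeling on 8 samples.

Distance-decay fits are OLS over the n(n−1)/2 upper-triangle pairs with a
Mantel-style p (one matrix's ids permuted jointly, preserving the pair
dependence structure), two-sided on the Pearson correlation. The partial
Mantel uses the first-order partial correlation formula and permutes the
first matrix; |r| = 1 with the covariate is rejected as degenerate.

Differential abundance deliberately does not reimplement negative-binomial
Wald machinery: the reported quantity is the log₂ fold change of group mean
relative abundances (salt vs freshwater reference) with pseudo-fraction
c = half the smallest nonzero relative abundance (configurable), a
two-sided group-label permutation test on the difference of means, and
Benjamini-Hochberg adjustment (via statsmodels) across features. Fold
changes computed on relative abundances differ from normalized-count fold
changes whenever library compositions shift strongly; this is a documented
deviation from count-model approaches.

## Assembly processes

βMNTD is abundance-weighted by default (flag exposed): each taxon's
relative abundance weights its patristic distance to the nearest taxon of
the other sample. The implementation precomputes, per sample, every taxon's
nearest-taxon distance into that sample, reducing all pairs to two matrix
products; it agrees with a naive double loop to 1e-10 in the tests.

βNTI shuffles taxa across the tips of the tree — one uniform permutation of
the patristic matrix per null iteration, shared by all sample pairs (the
`comdistnt` convention) — with n_null = 999 by default (99 minimum). Pairs
with zero null sd are reported NaN and excluded downstream with a log entry.
A practical calibration point: βNTI centres on the null only when the
regional pool is large. With few taxa (~100) the realised pool's own
phylogenetic structure shifts all pairs of a given simulation coherently by
a random offset; the calibration test therefore uses a 1,000-taxon pool, the
generator's default scale.

RC_Bray nulls preserve each sample's observed richness (taxa drawn without
replacement with probability ∝ occupancy frequency across samples) and
total abundance (one individual per drawn taxon, the remainder multinomial
∝ metacommunity relative abundance among the drawn taxa). The observed
Bray-Curtis is ranked within the null distribution (ties counted half) and
rescaled to [−1, 1]. Each pair's null stream is seeded from (master seed,
i, j), so results are independent of evaluation order and trivially
parallelisable.

Process calls per pair: βNTI > 2 heterogeneous selection, < −2 homogeneous
selection; otherwise RC_Bray > 0.95 dispersal limitation, < −0.95
homogenizing dispersal, else undominated. Boundary values (exactly ±2,
±0.95) fall to the weaker class — strict inequalities as conventionally
printed. Fractions are taken over classified pairs; whether to restrict
pairs within sample groups is left to the caller as a post-filter.

Levins breadth normalises each taxon's distribution **across samples**
(P_ij = count in sample i / taxon total), the standard resource-use reading,
which bounds B in [1, N]; the per-sample community value Bcom averages B
over taxa present in that sample. All-zero taxa are dropped with a log
entry.

## Networks

Construction: prevalence filter (≥ ceil(0.4 · n_samples) occurrences by
default), Pearson correlation of ln(count + 1) (the offset makes the
transform total; zero-variance taxa are dropped with a log entry), then an
|r| threshold. Thresholding can be fixed or RMT-guided: for each candidate
cutoff the largest connected component's adjacency spectrum is unfolded
with a low-order polynomial fit to the empirical cumulative spectral
function (near-degenerate eigenvalues collapsed at 1e-8), and the
nearest-neighbour spacing distribution is compared by χ² over 20 bins on
[0, 3] to the Poisson law e^(−s) and to the GOE Wigner surmise. The smallest
threshold where Poisson fits better and χ²_Poisson < 1.5 wins; if no
candidate qualifies, a configurable fallback (default 0.8) is returned with
a warning. The exact unfolding used by the canonical pipeline is unpublished
detail, so these numerical choices are ours and are exercised against
planted two-block correlation structure and GOE spectra in the tests.

All topology and stability metrics run on the unweighted adjacency (the
panel's definitions are stated for unweighted graphs); signed correlation
weights stay as edge attributes. Geodesic conventions: average path distance
over connected pairs only; harmonic geodesic distance = harmonic mean of
finite geodesics; efficiency = mean of 1/d over *all* pairs with
disconnected pairs contributing 0; connectedness = fraction of pairs joined
by a path. The degree power-law R² is the OLS fit of log P(k) on log k over
observed degrees.

Module detection is seeded Louvain (networkx `louvain_communities`,
unweighted), with Newman-Girvan Q reported. Maslov-Sneppen rewiring is
implemented directly (~25 lines): double-edge swaps rejecting self-loops
and parallel edges, 100 proposals per edge by default; graphs admitting no
valid swap (e.g. stars) are returned unchanged with a warning rather than
raising. Robustness removes ⌊f·N⌋ uniformly random nodes per replicate over
f = 0…0.8 (step 0.05, 100 replicates), tracking the largest-component
fraction of remaining nodes and natural connectivity; the scalar robustness
is the area under the mean largest-component curve. Natural connectivity is
computed with a max-eigenvalue shift for overflow safety. Zi uses the
population sd within the module (sd = 0 → Zi = 0, logged); isolated nodes
have undefined Pi and are reported peripheral.

## Biomarker models

Features are per-sample relative abundances at ZOTU, order or class rank
(missing labels pooled as "unassigned", columns renormalised). The workflow
mirrors the `rfcv` idiom: rank features by importance from one fit on the
full data, evaluate 10-fold CV error (five repeats) along a halving
schedule of feature-set sizes, and pick the smallest size within 5 %
(relative) of the minimum error — the published workflow names an "optimum
size" without a rule, so the tolerance rule is ours. Evaluation refits on a
random 70/30 split and reports "prediction accuracy" as 100·(1 −
MSE_test/Var(y_test)), i.e. test-set explained variance in percent. A
regression "accuracy" has no standard definition; this one is monotone in
test error, equals 100 for perfect prediction, and goes negative for
worse-than-mean prediction (reported unclipped). The regressor is
injectable (anything with the sklearn API plus `feature_importances_`);
the default is a 1,000-tree random forest, and the test suite uses a
deterministic linear stub where only the pipeline logic is under test.

## Problem sizes

The test suite and the acceptance script run at desk scale, chosen as the
smallest designs at which each property is statistically stable: regime
comparisons use 8 lakes × 2–12 samples with 140–1,000 taxa at depths
2,000–5,000; null-model runs use 199 draws (999 for the βNTI calibration
check and the Raup-Crick dual-implementation check); permutation-type-I
calibrations use 1,000 simulations of 99-permutation tests; the biomarker
benchmark uses 80 samples × 300 taxa with 500 trees. The acceptance script
reports every quantity with the problem size (`n`) it was computed at.

## Known limitations

- Correlation networks are built on Pearson after log(count+1); no
  compositional correction (SparCC-style) is attempted, and within-group
  environmental gradients can induce dense environmentally-driven edges —
  visible in the generator as a high positive-edge fraction in salt-lake
  networks.
- The RC_Bray null is the occupancy/abundance-preserving recipe only; other
  null algorithms (independent swap, trial swap) are out of scope.
- The differential-abundance test is a mean-difference permutation test on
  relative abundances; it does not model dispersion and will differ from
  count-model results on strongly compositional data.
- PERMANOVA is one-way with free permutations; nested or stratified designs
  are not supported.
- The generator's lakes differ only in salinity; geographic distance decay
  beyond salinity structure cannot be recovered from it.
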