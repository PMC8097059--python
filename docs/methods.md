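# Methods

This note documents the statistical model behind each stage of `kinsig`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions that make runs
reproducible.

## Data model

All quantification is on the log2-intensity scale. A `QuantMatrix` is a
features × samples table (proteins or phosphosites) with missing cells
allowed; a `SampleDesign` maps samples to conditions and replicates.
Phosphosites use the identifier dialect `PROTEIN_S123` (residue S/T/Y,
1-based position); a site is "class I" when its localization probability
exceeds 0.75. The kinase–substrate network is an edge list mixing curated
relationships (no score) with predictions that carry a non-negative score;
duplicate (kinase, site) pairs collapse to a single edge with curated
provenance winning. All tables are TSV with a header; missing values are
empty cells (or `NA` on input). Readers parse floats in round-trip mode so
a write/read cycle preserves values bit-identically.

## Preprocessing

Per-sample **median centering** subtracts each column's median over
observed entries, the standard normalization for single-batch isobaric or
label-free designs; it removes per-replicate loading differences and makes
downstream fold-changes comparable across samples. The **completeness
filter** keeps features observed at least `min_per_group` times in every
tested group (default in the shipped configs: 2 of 3 replicates; a
5-to-6-replicate in vivo design would typically use 3). **Row z-scaling**
(mean 0, SD 1 per feature) is for display and clustering only — tests
always run on centered, unscaled values, since z-scaling destroys
effect-size information. PCA uses complete rows only (rows with any
missing value are dropped and counted); imputation is deliberately avoided
because the tests make no missingness model assumption either.
Hierarchical clustering uses Canberra distance on rows and 1 − Pearson
correlation on columns with average linkage — the common heatmap
convention for intensity matrices; the linkage choice is ours since only
the metrics are standard.

## Differential testing

**Two-class SAM-style test.** d = (mean_case − mean_control)/(se + s0)
with the pooled-variance standard error and a fixed additive fudge factor
s0 = 0.1 (log2 units). The fixed-s0 convention (rather than the
percentile-optimized s0 of the original SAM formulation) matches how the
statistic is used in mainstream proteomics software. s0 = 0 reduces
exactly to the Student t statistic.

**Permutation FDR.** For a cutoff c on |d|, the estimated FDR is

    FDR(c) = mean over permutations of #{|d_perm| ≥ c}  /  #{|d_obs| ≥ c}

with π0 = 1. A feature's q is the minimum FDR over all cutoffs that admit
it, capped at 1, which makes q monotone non-increasing in |d|; ties in |d|
are broken by feature id for a reproducible significant-set boundary.
Permutations are distinct case/control relabelings: enumerated
exhaustively when at most B = 250 exist (e.g. all 3-vs-3 designs), else B
seeded random draws. Two conventions here deserve justification, because
small designs make them consequential:

* The *observed labeling is excluded* from the permutation set, as is its
  group-swap mirror when group sizes are equal (the mirror reproduces the
  observed |d| exactly). Both carry the alternative hypothesis, not the
  null; in a 3-vs-3 design they are 2 of only 20 relabelings, enough to
  put a hard floor of 0.1 under every FDR estimate and make the procedure
  blind to even arbitrarily strong effects.
* The *mean* (not median) of permuted exceedance counts is used. With
  ~20 permutations the median of small counts is frequently exactly 0,
  which declares FDR = 0 for any feature that happens to top the permuted
  values — on fully null simulated data that miscalls in roughly a third
  of datasets. The mean degrades gracefully: simulations under the
  generator's null give a realized false-discovery proportion consistent
  with the 0.05 target, while planted log2 fold-changes of 2 at noise
  SD 0.3 are recovered essentially always.

**One-way ANOVA** is the plain F test per feature with BH adjustment
(default FDR 0.01); no variance moderation is applied, because a
moderated ANOVA with an additive s0 is not well defined. Features with no
variance at all return a missing p and are excluded from the BH family.

**One-sample moderated t** on log2-ratio matrices uses d = mean/(SD/√n +
s0) with a two-sided p from the t distribution with n − 1 degrees of
freedom evaluated at d. This is an approximation — the moderated statistic
is not exactly t-distributed — but it is conservative in the direction
that matters (s0 shrinks |d|) and keeps the BH machinery applicable.

**Volcano selection.** The fold-change threshold is 3× the (n − 1)-SD of
the log2 fold-changes, computed over *all* features separately for the
positive and negative sides before any FDR filtering; selection requires
q below the configured FDR *and* strictly exceeding the side's threshold.
A side with fewer than two fold-changes has no defined threshold and
yields no calls. A selected site is flagged `proteome_regulated` when its
parent protein is selected in the same direction by the same two-part rule
applied to the proteome's own fold-change distribution; unquantified
parents give flag False with provenance `protein not testable`. Functional
prioritization keeps selected sites with functional score strictly above
0.5; unscored sites are excluded with provenance `unscored`.

## Kinase inference

KSEA scores kinase k with m quantified substrate sites as
z = (mean_s − mean_p)·√m/δ, where mean_p and δ are the mean and SD of
*all* quantified sites' fold-changes in the comparison (not only
network-mapped ones — the convention of the reference KSEA tooling).
Two-sided p = 2(1 − Φ(|z|)), BH-adjusted across scored kinases. The
substrate network keeps curated edges unconditionally and predicted edges
with score ≥ 3 (inclusive); kinases with m < 4 are excluded, applied per
comparison. Sites annotated to several kinases contribute to each. z is
invariant to shifting all fold-changes by a constant or scaling them by a
positive factor, since mean_p and δ absorb both.

The cross-comparison signature retains kinases significant (q < 0.05) in
at least 3 comparisons (of the shipped 5); kinases scored in fewer
comparisons than the threshold can never be retained and are reported with
provenance instead of silently dropped. Retained rows are clustered by
k-means (k = 3, Euclidean distance on z, 10 seeded restarts keeping the
best within-cluster sum of squares); missing z cells are imputed as 0 for
clustering only, and cluster labels are canonicalized by descending mean z
so label 0 is always the most-activated cluster.

## Set enrichment and connectivity

Over-representation is the one-sided upper hypergeometric tail of the
foreground/set overlap against the full quantified background (sets are
intersected with the background first), BH-adjusted across sets; one-sided
because the question is over-representation, not depletion. Ranked query
lists (top-100 for regulator-enrichment queries, top-150 per side for
connectivity queries) sort by fold-change or statistic with lexicographic
id tie-breaking. Enrichment heatmaps transform FDR values by −log10 and
z-scale per row with the n − 1 denominator; zero FDRs must be floored by
the caller since the log is undefined.

The connectivity score is the unweighted two-sided KS statistic: for each
query list the signed maximum deviation of a running sum that steps +1/n
on hits and −1/(N − n) on misses down the reference ranking; the combined
score is (ES_up − ES_down)/2 when the two have opposite signs, else 0.
Positive means the up list concentrates at the top and the down list at
the bottom of the reference. This is a local, unnormalized stand-in for
service-side connectivity scoring: comparable in sign and rank ordering,
not in absolute magnitude, to scores produced with permutation-normalized
pipelines.

## Dose-response and synergy

The 4PL model y = bottom + (top − bottom)/(1 + (x/IC50)^hill) is fitted by
unweighted least squares on log10 dose with multi-start initialization
(IC50 at the dose quartiles, hill at ±1), IC50 bounded within 10^±4 of the
observed dose range and the hill slope unconstrained in sign. At least 4
distinct doses are required; a response range below 0.02 raises "no dose
dependence", and non-convergent fits are flagged without an IC50. IC50
comparison between arms uses the ratio of geometric means and a two-sided
t test on log IC50s (with < 2 replicates per arm, fold-change only).

The Bliss index is S_A·S_B − S_AB on surviving fractions normalized to
vehicle control: 0 is additive, positive synergy (the combination kills
more than independence predicts), negative antagonism. Fractions slightly
above 1 (≤ 1.2) are tolerated for assay noise. The sign convention is
fixed this way so that the verbal rule "synergy when S_AB < S_A·S_B" and
the sign read-out ("index > 0 ⇒ synergy") agree; the additive case is 0
under any convention.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes: a
multi-condition replicate design (defaults: 2 conditions × 3 replicates;
the shipped five-comparison config uses 5 conditions × 3), protein
baselines N(25, 2²) on the log2 scale, i.i.d. Gaussian replicate noise
(default SD 0.3; Student-t(3) noise available as a config flag),
5% differential proteins with |log2FC| uniform on [0.5, 2] and random
sign, phosphosites attached to parent proteins with N(0, 1) site offsets,
planted kinases whose δ shifts all their substrate sites in their active
conditions, a configurable fraction of "protein-driven" sites that inherit
their parent's planted fold-change, missing-completely-at-random cells
(default 5%; an intensity-dependent option exists because real
missingness is abundance-biased), uniform [0, 1] functional scores,
predicted-edge scores uniform on [0, 10] so the score-3 retention filter
actually removes edges, and gene sets with planted enriched sets (80% of
members drawn from the differential proteins). Planted-kinase edges are
emitted as curated so the planted truth is invariant to the prediction
threshold; decoy kinases carry the curated/predicted mixture. Effect-size
defaults are field conventions, not estimates from any particular dataset.

Under the generator, the expected KSEA score of a planted kinase is
δ√m/δ_all with δ_all the SD of all site fold-changes; the acceptance
checks place a planted kinase exactly at the z ≈ 4 detection boundary
(δ = 1, m = 16, replicate noise sized so δ_all ≈ 1) and at that boundary
it reaches q < 0.05 in ≥ 90% of seeds.

What the generator does *not* emulate — and therefore what passing tests
do not demonstrate about real data: peptide-level quantification and
roll-up, isobaric-label ratio compression, retention-time or batch
structure, correlated noise between sites on the same protein beyond the
shared baseline, realistic (non-uniform) functional-score and
prediction-score distributions, and abundance-dependent missingness unless
explicitly enabled. Calibration results transfer to real data only to the
extent that log2 replicate noise is approximately Gaussian and
independent across features.

Randomness: one global seed feeds named `SeedSequence` child streams
(baseline, structure, effects, network, noise, missing, functional, sets —
spawned in that fixed order), so adding a stage never perturbs earlier
draws and identical (config, seed) pairs are bit-identical.

## Pipeline

The run order is: completeness filter → median centering → per-comparison
tests → volcano + proteome correction + functional prioritization → KSEA
per comparison → cross-comparison signature + k-means → over-representation
of significant proteins → connectivity query export → optional synergy
analysis. Filtering precedes centering so sample medians are computed on
the features actually analyzed; the reverse order differs only marginally
at the default missingness. Every output file is stamped with the config
hash and seed; reruns with the same config and seed reproduce every file
checksum. Stage failures abort with the stage name. The default synthetic
scale in the shipped example config (400 proteins, 800 sites, 5
comparisons, exhaustive 3-vs-3 permutations) runs in a few seconds on one
CPU; the test-suite simulations use 50-seed batches at similar scale,
chosen to keep Monte-Carlo error on rates near ±3% while remaining quick.

## Known limitations

* The permutation FDR is coarse in tiny designs: with 18 usable
  relabelings the smallest nonzero FDR step is 1/18 per observed feature
  count, so q-values are granular and mildly conservative.
* The one-sample p-value treats the moderated statistic as t-distributed;
  for n ≤ 3 this approximation is rough.
* KSEA treats substrate sites as exchangeable and ignores site-level
  weighting (no functional-score weighting, no per-site variance).
* The connectivity score is not comparable in magnitude across references
  of different lengths.
* k-means label canonicalization by mean z is stable only when cluster
  means are distinct; exactly tied means would make labels arbitrary.
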