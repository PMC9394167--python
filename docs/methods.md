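# Methods

## Model and procedure

The analysis treats a branched selection as a per-sample multinomial
read-out of an underlying aptamer pool. For aptamer *i* in sample *s*
belonging to clinical group *g(s)* ∈ {C, Ta, T2T4}, observed counts are

    c·,s ~ Multinomial(N_s, p·,s),   p_{i,s} ∝ b_i · m_{i,g(s)} · ε_{i,s}

where `b_i` is the aptamer's baseline pool fraction, `m_{i,g}` a
group-specific binding/enrichment multiplier (1 for most aptamers) and
`ε_{i,s}` multiplicative patient-to-patient noise. The analysis never
fits this generative model directly; it is the assumption that justifies
(a) normalizing counts to pool fractions, (b) dividing by the
per-aptamer mean to put aptamers on a common scale, and (c) testing for
group effects with a linear model on those relative levels.

### Read processing

Demultiplexing assigns a read pair to the unique barcode within
`max_barcode_mismatch` (default 0) of the read-1 prefix; a barcode set
with any pair within twice that radius is rejected outright because
assignment would be ambiguous by construction. Pair-mate joining
reverse-complements read 2 and selects the overlap offset (≥ 10 bases)
with the fewest mismatches, accepting mismatch fractions up to 0.1 and
resolving disagreements toward the higher base quality (ties keep
read 1). Candidate offsets are proposed by exact 12-mer seeding with an
exhaustive fallback whenever no seeded offset is acceptable, so
rejection decisions are identical to a full scan. The variable region
is the substring between the two constant flanks, each located with at
most 1 substitution, and must be 30–42 nt (the designed length is 36).

Dereplication is exact counting. The minimum-count filter (≥ 4
observations) applies per sample *before* the cross-sample union; a
sequence can be retained in one sample and zeroed in another. The
normalization denominator is the sample's total of *all* dereplicated
reads, kept as metadata through filtering, because rare discarded reads
still belong to the pool the fraction refers to.

### Clustering

Sequences descending from a common ancestor by PCR/sequencing artifacts
or point mutation are merged with a greedy abundance-ordered centroid
pass: visiting sequences by descending total count (lexicographic
tie-break), each joins the first centroid within edit distance 3
("distance < 4"), else founds a centroid. Centroid linkage, not single
linkage: a chain A–B–C where C is near B but far from A yields two
clusters. The distance is the restricted Damerau–Levenshtein (optimal
string alignment, OSA) distance — substitutions, insertions, deletions
and adjacent transpositions, no substring edited twice — matching what
common string-distance packages compute under the "Damerau–Levenshtein"
name; the ("CA","ABC") → 3 case pins the variant, and a plain
Levenshtein mode is config-switchable. Clustering uses a banded
dynamic program capped at the cutoff plus a base-composition lower
bound (one substitution moves two composition counts, an indel one, a
transposition none), both property-tested against the full DP.

### Differential enrichment

Relative levels are `y_{i,s} = f_{i,s} / mean_s f_{i,s}` over the
training cohort, so every aptamer has mean 1 and a coefficient of 0.5
means "half a typical level". One three-group indicator model is fit
per aptamer over all 96 training samples; least squares makes each
coefficient a difference of group means, the standard error uses the
residual variance pooled across the three groups (df = n − 3), and
re-leveling on Ta gives the stage contrast with the same pooled
variance. A pairwise two-group mode (df = n₁ + n₂ − 2) is available
behind `ols_mode="pairwise"` because a per-comparison reading of the
original description is also defensible; coefficients agree between
modes, standard errors differ slightly.

P-values are Benjamini–Hochberg adjusted within each comparison (m =
aptamers tested in that comparison, not pooled across comparisons,
matching per-comparison volcano plots). The significance gate is
adjusted p < 0.01; coefficient gates are |β| > 0.5 against control and
|β| > 0.25 for Ta vs T2–T4, applied to the absolute value with the sign
reported as direction (depleted/increased).

Family grouping of the selected aptamers is a deliberate surrogate for
the original (unpublished) motif analysis: single-linkage clustering at
OSA distance ≤ 8, components of size ≥ 2 labeled A, B, … by decreasing
size. It recovers "families = chains of similar sequences" but not
motif alignment.

### Classification

The validation cohort's relative levels (recomputed against
validation-sample means) on the discriminatory aptamers feed a PCA
(samples × aptamers, columns centered, unscaled — the conventional
default of the fitting function named by the original description;
both flags are config-exposed). Principal axes are sign-ambiguous, so
components are oriented on the labels: PC1 flipped if the cancer-group
mean score is negative, PC2 flipped if the T2–T4 mean is negative.
Classification is then a sign rule: PC1 > 0 ⇒ cancer (exactly 0 ⇒
control, the documented tie-break), and among true cancer samples
PC2 > 0 ⇒ T2–T4. Heatmap columns are ordered by complete-linkage
hierarchical clustering under Euclidean distance (the linkage is
specified by the source analysis, the metric is our conventional
choice, both configurable); rows stay in family order.

## Synthetic data: what it emulates, what it does not

`generate_pool` draws family ancestors and singletons uniformly over
{A,C,G,T}³⁶, mutates family members i.i.d. per base (default rate 0.03,
≈ 1 substitution per member), and assigns log-normal abundance weights.
Family members that coincide with their ancestor (certain at mutation
rate 0) collapse into a single pool row with summed weight. Only the
log-normal σ matters after normalization; σ = 1.8 was calibrated by
Monte Carlo (40 seeds) so the most abundant aptamer averages ≈ 10% of
the pool while > 90% of aptamers individually hold < 1% — the shape of
a late-round selection pool. Log-normal was preferred over Zipf for
having two interpretable parameters and matching the "few dominant,
long tail" shape.

Planted effects multiply a chosen aptamer's abundance in the affected
group(s); sampling renormalizes, so large planted aptamers would leak
effect into every other aptamer. Plantable aptamers are therefore drawn
from baseline fractions in [1e-4, 1e-2] — reliably observed at depth
10⁵ yet individually too small to distort the pool — and from
singletons only, because distance-< 4 clustering merges close family
members into one centroid, which would blur planted/selected
accounting. Noise is multiplicative log-normal per aptamer per sample
(σ = 0.3 by default, the magnitude stated for the recovery
conditions). Read emission writes each counted molecule once as a
barcoded 2×100 pair with constant Phred quality (default 37) and an
optional uniform substitution error rate; there is no PCR bias,
round-to-round evolution, or instrument-specific quality profile, and
depths are scaled down (10⁵ vs millions of reads per sample in a real
experiment).

Consequences for interpretation: passing tests show the *analysis*
recovers planted effects of the simulated magnitude under multinomial +
log-normal noise; they do not certify performance under real selection
noise (PCR jackpots, round-to-round drift, correlated patient
covariates). With σ = 0.3 the simulated validation PCA concentrates
≈ 35% of variance on PC1 — real cohorts showed much higher
concentration (78–94%), i.e. lower effective noise relative to effect —
while sign-rule accuracies land in the 90–100% range either way.

## Named scenarios and problem sizes

* `recovery_scenario`: 500 singletons, 10 planted (5 × 0.5 in both
  cancer groups, 5 × 2.0 in T2–T4), 32 samples/group, depth 10⁵.
* `study_scenario`: 20 families × 5 + 400 singletons; 15 aptamers
  × 0.5 in both cancer groups, 15 × 1.25 T2–T4 / 0.8 Ta, 3 reversed —
  mirroring the published 15/18 class structure with stage contrasts
  (expected |β| ≈ 0.45) deliberately below the 0.5 against-control
  gate; 96 training + 22 validation samples.
* `null_scenario`: the recovery pool with no planted effects.

These sizes keep a full pipeline run under a second while leaving
comfortable statistical margins (expected against-control |β| = 0.75
vs threshold 0.5 at SE ≈ 0.07–0.09).

## Numerical choices and degenerate inputs

* Zero-mean aptamer rows cannot be rescaled to relative levels and are
  dropped with a warning; zero-variance fits report p = 0 with a
  `degenerate` flag; a zero read total is an error naming the sample.
* Abundance-ranking and clustering ties break lexicographically by
  sequence; PCA base signs follow a largest-|loading|-positive
  convention before label orientation; dendrogram ties follow the
  deterministic scipy ordering by column index.
* All pipeline outputs are plain text without timestamps, so identical
  inputs + config + seed reproduce files byte-for-byte.
* All randomness flows from explicit `numpy` Generators derived from a
  single seed; no global random state is touched.

## Known limitations

* The family surrogate is not motif discovery; families agreeing in a
  conserved core but diverging elsewhere may exceed the edit-distance
  cutoff.
* Whether the original min-count filter and clustering were applied per
  sample or across the pooled union is ambiguous in the source
  description; this implementation filters per sample and clusters the
  union, and exposes both thresholds.
* The OLS model assumes homoscedastic residuals across groups; strongly
  depleted aptamers violate this mildly (level-proportional noise), so
  pooled standard errors are approximate.
* Classification requires labeled samples to orient components; an
  unlabeled cohort keeps the arbitrary SVD orientation and the sign
  rule is then meaningless.
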