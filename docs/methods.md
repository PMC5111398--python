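# Methods

`mitopool` implements a mitogenomic "resequencing" workflow for identifying
and quantifying species in bulk invertebrate samples (the motivating system
is wild-bee monitoring from pan-trap catches): shotgun reads from a
homogenised bulk sample are mapped against a library of reference
mitochondrial genomes, species are called present from read coverage, and
normalised read counts are carried into biomass regression, ordination and
richness analyses.  This note records the model, the numerical choices, and
what the bundled synthetic studies do and do not demonstrate.

## Mapping contract

The identification step hinges on a strict mapping criterion — full-length
alignment at 99% identity, unique to one reference:

* A **hit** is an ungapped, end-to-end alignment of the whole read against a
  circular reference on either strand with at most `floor(L × 0.01)`
  mismatches (one mismatch for 100-bp reads).  Indels are excluded: the
  criterion is formalised as the strictest (and exactly checkable) reading
  of "100% read coverage at 99% identity".  `N` counts as a mismatch
  everywhere, on both sides.
* **Uniqueness is at the reference (species) level.**  A read placed at
  several positions of one mitogenome (repeats) is still unique to that
  species; a read within budget on two references is `multi_reference` and
  discarded.  The quantity consumed downstream is per-species read count,
  so reference-level uniqueness is the right granularity.
* Candidate placements come from **pigeonhole seeding**: the read is split
  into `m + 1` blocks (`m` = budget), so any within-budget alignment
  contains an exact block.  Blocks are located in a sorted table of modular
  polynomial hashes (26-bit modulus) of every reference window; hashing can
  only *add* candidates (collisions are removed at verification), never lose
  a true hit, so the seeded mapper is exactly equivalent to exhaustive
  scanning — a property the test suite asserts against an independent
  brute-force oracle on >10⁴ reads.
* Circularity is handled by logically extending each reference by
  `read_length − 1` wrap bases; reported positions are forward-strand
  starts modulo the achieved length.  Ties are broken deterministically
  (fewest mismatches, then smallest position, then `+` strand) so depth
  vectors are reproducible.
* Per-base depth is accumulated only from unique reads, at their best hit.

## Profiling and detection

For species *s* in sample *j*:

* `coverage_fraction` = fraction of reference positions with depth ≥ 1.
* `normalized_reads` = `raw / (achieved_length / 16000)` — species with
  incomplete reference assemblies are scaled up to the 16-kb canonical
  mitogenome length.
* `corrected_reads` = `normalized / mito_fraction`, where `mito_fraction`
  is the species' mitochondrial share of total shotgun reads (measured once
  per species when its reference was sequenced).  This corrects the ~250-fold
  between-species differences in mitonuclear ratio.
* **Present ⇔ coverage_fraction > 0.10 (strict).**  Coverage is computed
  over the achieved assembly length (the denominator that exists).  The
  threshold is configurable because the detection calls are insensitive to
  it: in practice true positives sit far above (typically ≥ 29%) and true
  negatives far below (≤ 8%) — the bimodal coverage separation the
  threshold sweep in `evaluate` makes visible.

Every reference species appears in every sample as an explicit row (zeros
included): the confusion matrix needs true negatives, and profiling success
is defined over the full grid.

## Biomass regression

Within each sample, corrected read counts and truth biomasses are converted
to frequencies and z-transformed (mean 0, sd 1 across the species present in
that sample), correcting for sample-size differences; points are pooled over
species × sample.  Two fits are reported:

* **OLS** with `R² = 1 − SSE/SST` and a slope t-test.
* **GLS with an exponential variance function** (varExp):
  `y = a + bx + ε`, `sd(ε) = σ·exp(δx)`, by maximum likelihood.  For fixed
  δ the weighted LS solution is closed-form (weights `exp(−2δx)`), so the
  profile log-likelihood is one-dimensional in δ and maximised by bounded
  scalar search (bounds ±20, tolerance 1e−8).  ML (not REML) keeps
  likelihoods comparable across normalisation variants.  `fix_delta=0`
  reduces the model exactly to OLS — a tested identity.  The fit is
  verified against frozen reference values from an independent ML varExp
  implementation.

The varExp covariate is the same x entering the mean model (the z-scored
biomass frequency).  The z-transform scope is per-sample by default, with a
global scope behind a flag.

`biomass_to_counts` closes the monitoring loop: read frequencies ×
total sample biomass ÷ species-specific biomass per individual = estimated
counts (real-valued; rounding is the caller's decision).

## Community statistics

* **Jaccard**: binary `1 − |A∩B|/|A∪B|`; quantitative is the Ružička form
  `2B/(1+B)` over Bray–Curtis `B` — the classical behaviour of the
  community-ecology `vegdist` routine, verified against frozen values.
* **NMDS** minimises Kruskal stress-1 with isotonic (pool-adjacent-violators,
  tie-averaging) disparities, via SMACOF with a metric (PCoA) start plus
  random restarts (default 20, k = 2, tolerance 1e−7, max 500 iterations).
  Stress-1 is recomputed in-package from the final configuration.
  Non-convergence is flagged, never raised.  When two ordinations are to be
  compared (read-based vs biomass-based), both run from identical restart
  initialisations — common random numbers — so that configuration
  differences reflect the data rather than which equal-stress basin each
  restart set happened to find.
* **Procrustes / protest**: both configurations centred and scaled to unit
  sum of squares, rotation from the SVD of the cross-product;
  `m² = 1 − (Σ singular values)²`, `r = √(1 − m²)`; the permutation p-value
  uses the add-one rule `(b+1)/(B+1)` (so p is never 0 and the minimum at
  9 999 permutations is 0.001).
* **Chao2**: bias-corrected by default,
  `S_obs + ((m−1)/m)·q1(q1−1)/(2(q2+1))`, with the matching variance;
  `variant="classic"` exposes the legacy estimator (`q1²/(2q2)` with its
  variance), which is what the classical species-pool routine computes —
  both variants are frozen-oracle-tested.
* **Welch's t-test** on two richness estimates uses per-group degrees of
  freedom `m − 1` with m = the number of samples behind each estimate; this
  convention reproduces the worked examples the test suite pins.

## Synthetic study generator

The generator produces the full study design end-to-end and is itself
first-class, tested code.

* **References**: each species' mitogenome descends from one random
  ancestor with independent per-site substitutions (default rate 0.05),
  lengths uniform in 14.5–16 kb (most assemblies complete, some short).
  At that divergence, homologous 100-bp windows occasionally remain within
  one mismatch of each other by chance, so the generator *repairs* them —
  targeted extra substitutions until every pair window differs at ≥ 2 sites
  (checked exactly, circularly).  The mapper's reference-uniqueness
  guarantee therefore holds by construction, and the tests verify it by
  exhaustive cross-window comparison.
* **Metadata**: `mito_fraction` uniform over [0.005%, 1.319%] (the observed
  range; it spans ~260-fold), `biomass_per_individual` log-normal
  (median 50, log-sd 0.4, arbitrary units).
* **Communities**: 10 samples, 3–11 species and 13–51 individuals each.
  Samples are grouped into 4 regions along a latent niche gradient
  (`niche_width` 0.08, region jitter 0.03): samples from the same region
  share species while regions turn over.  This mirrors the multi-landscape
  field design in which samples cluster by region, and it is what makes
  2-D ordinations well determined — with structureless random communities
  the NMDS embedding of 10 samples is genuinely non-unique (equal-stress
  layouts), and ordination congruence would be ill-posed no matter how low
  the noise.
* **Reads**: species *i* contributes mitochondrial reads with expectation
  `total_reads × w_i`, `w_i ∝ biomass_i × mito_fraction_i`, normalised
  together with a nuclear pseudo-source of weight
  `Σ biomass_i (1 − mito_fraction_i)`.  Mitochondrial reads are 100-bp
  windows drawn uniformly over the circular reference on a random strand
  with iid substitution errors (default 0.002/base, the post-filter scale
  of cleaned short reads); the nuclear background is uniform random DNA,
  which is unmappable at 99% identity against ≤ 20 kb references
  (collision probability negligible, asserted in tests).  Reads can be
  generated in streamed chunks so deep samples never materialise in memory.
* **Sequencing-depth design rule.**  Because the mitochondrial fractions
  are tiny, the nuclear source takes ~99% of reads, and a fixed shallow
  depth would leave weak species (low biomass × low mito-fraction)
  undetectable — exactly why the real study sequenced 5–6 Gb per sample.
  `required_depth` right-sizes each sample's depth so the weakest present
  species expects 50 mappable mitochondrial reads
  (expected coverage `1 − exp(−n·L_read/L_ref)` ≈ 27%, comfortably above
  the 10% threshold even after Poisson noise), floored at 5×10⁴ reads.
  Typical designed depths are 10⁶–10⁷ reads per sample.
* **Contamination**: cross-sample contamination is modelled as a handful of
  error-free reads from an absent species (default 10 per contaminant,
  far below 0.5% of any sample).  Ten 100-bp reads cover at most 1 kb =
  6.25% of a 16-kb reference — deterministically below the detection
  threshold, and on the scale of the observed true-negative coverages
  (0–7.7%).
* All randomness flows from one seed through a single generator hierarchy;
  identical arguments + seed give byte-identical outputs.

### What the synthetic studies show — and what they do not

Passing end-to-end tests show the pipeline is *internally correct*: the
mapper is exact under its contract, normalisation undoes the distortions
the generator injects, detection separates present from absent species at
the designed depth, and the downstream statistics recover the structure put
in.  They do not show field performance: real data add numts, within-species
polymorphism and reference/sample mismatches, indels and quality-dependent
errors, PCR/library biases, and morphological misidentification in the
truth data — none of which the generator emulates.  The empirical
coefficients of the motivating study (e.g. its regression R² ≈ 25% and its
specific Chao2 values) depend on its real per-cell table, which is not
reproducible from summary statistics; the synthetic studies reproduce the
qualitative claims (positive significant biomass–read slope, ordination
congruence r > 0.95, clean coverage bimodality) rather than those numbers.

## Problem sizes used in validation

The shipped validation runs use: 48 reference species and 10 samples per
study; 20 independent seeds for the read-level detection study (~2×10⁷
reads per seed under the depth design rule); 10⁴ reads for mapper–oracle
equivalence; 50 replicates of n = 1000 for GLS recovery; 100 count-level
studies for regression significance and 20 for ordination congruence.
Count-level studies use the same weight model but draw multinomial read
counts directly, with coverage at its expectation — appropriate for claims
that do not depend on base-level reads.

## Known limitations

* Ungapped alignment only; reads containing indels (not generated) would be
  lost, slightly deflating counts on real data.
* Single-end reads; mate-pair information is ignored by design.
* The mitonuclear correction assumes `mito_fraction` is a stable species
  property; in reality it varies with tissue condition and DNA quality.
* Chao2 variance (and hence the Welch test) assumes independent samples.
* NMDS at 10 samples is near the lower size limit for stable 2-D
  embeddings; the ordination utilities report stress and convergence so
  degenerate cases are visible.
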