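# mitopool

Mitogenomic profiling of bulk invertebrate samples: who is in the trap, and
how much of each?

Biodiversity monitoring needs species lists (and ideally abundances) from
bulk samples — e.g. hundreds of wild bees from pan traps — without
per-specimen morphological identification.  `mitopool` implements the
PCR-free *mitogenomic resequencing* approach: shotgun-sequence the total DNA
of the homogenised sample, map the reads against a library of reference
mitochondrial genomes, and read both the species list and the biomass
composition off the mapping profile.  The package is aimed at molecular
ecologists building or evaluating such pipelines; it ships a complete
synthetic-study generator so every stage can be validated end-to-end against
known ground truth.

## The method

**Mapping contract.**  A read is assigned to a species only if it aligns
end-to-end (ungapped, circular references, either strand) with at most
`⌊L × (1 − 0.99)⌋` mismatches — "100% read coverage at 99% identity" — and
only if all such hits fall on a single reference.  Candidate placements come
from pigeonhole seeding (split a read into `m+1` blocks; any alignment with
≤ m mismatches contains an exact block), which makes the mapper provably
equivalent to exhaustive scanning; the test suite asserts that equivalence
against a brute-force oracle.

**Detection.**  Species *s* is present in a sample iff its read coverage
(fraction of reference positions hit by ≥ 1 uniquely mapped read) exceeds
10%.  Real positives sit far above this threshold and contaminants far
below, so the calls are insensitive to the exact cutoff.

**Quantification.**  Mapped read counts are normalised by
`achieved_length / 16000` (incomplete assemblies) and divided by the
species' mitochondrial read fraction (mitonuclear correction), yielding
within-sample read frequencies.  These are regressed on biomass frequencies
(z-transformed per sample) by OLS and by a generalised least squares model
with an exponential variance function, `sd(ε) = σ·exp(δx)`, fitted by
profile maximum likelihood.

**Community statistics.**  Jaccard (binary) and Ružička (quantitative)
dissimilarities, non-metric MDS (Kruskal stress-1, SMACOF with PCoA +
random restarts), symmetric Procrustes with a permutation test, Chao2
richness (`S_obs + ((m−1)/m)·q1(q1−1)/(2(q2+1))` with SE), and Welch's
t-test on richness estimates.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```python
from mitopool.study import run_synthetic_study, contaminant_coverages

res = run_synthetic_study(seed=7)   # 48 ref species, 10 bulk samples
c = res.confusion
print(c.tp, c.tn, c.fp, c.fn, c.detection_rate, c.profiling_success)
```

prints `73 407 0 0 1.0 1.0`: of the 480 species × sample cells, all 73
truth-present populations are detected (every present species' mitogenome
ends up > 10% covered; the weakest reaches 19.6%) and all 407 absences are
called correctly.  Injected cross-contamination (10 stray reads per sample)
peaks at 6.9% coverage — below the threshold, so it is rejected:

```python
print(contaminant_coverages(res, n_reads=10, seed=7).max())   # 0.069
```

Quantification on the same study (`examples/03_biomass_regression.py`):

```
OLS:  read_z = -0.0000 + 0.9849 * biomass_z   R^2 = 97.0%  (n = 72 points)
GLS (varExp): slope = 0.9864, delta = -0.063, p = 2.25e-56
```

a slope near 1 with tiny p: corrected read frequency tracks biomass
frequency almost one-to-one under the generator's assumptions.  The
community layer (`examples/04_community_analysis.py`) superimposes the
read-based and biomass-based NMDS ordinations with Procrustes r = 0.999
(p = 0.001, 999 permutations) and extrapolates identical Chao2 richness
(54.5 ± 7.9 from S_obs = 41) from both tables.

Each script in `examples/` demonstrates one capability (simulation+mapping,
detection, regression, community analysis, and the shell pipeline); the
`mitopool` CLI exposes the same stages as subcommands
(`simulate`, `map`, `profile`, `quantify`, `community`, `evaluate`, `run`).

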