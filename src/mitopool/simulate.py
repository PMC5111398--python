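"""Synthetic study generator: reference mitogenomes, species metadata,
bulk-sample compositions and shotgun reads with known ground truth.

The generator emulates a bulk-arthropod mitogenomic resequencing study:

* a reference library of circular mitogenomes (~16 kb, possibly incomplete)
  derived from a common ancestor with per-species substitutions, post-processed
  so that no 100-bp window of one species matches a window of another within
  the mapper's mismatch budget;
* per-species metadata: the fraction of a species' shotgun reads that are
  mitochondrial (mitonuclear ratio, spanning 0.005%-1.319% by default) and a
  biomass per individual;
* bulk samples of 3-11 species and 13-51 individuals whose shotgun reads mix
  mitochondrial windows (uniform over the circle, either strand, iid
  substitution errors) with an unmappable nuclear background of uniform
  random DNA.

Species *i* contributes mitochondrial reads with expectation
``total_reads * w_i`` where ``w_i`` is proportional to ``biomass_i *
mito_fraction_i``, normalised together with a nuclear pseudo-source of weight
proportional to ``sum_i biomass_i * (1 - mito_fraction_i)``.  Because the
mitochondrial fractions are tiny, the nuclear source takes ~99% of reads:
detecting every species present therefore requires depth, exactly as in a
real study.  :func:`required_depth` computes the per-sample depth at which
the weakest present species still expects enough mappable reads to exceed
the 10% coverage detection threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from ._seq import decode, encode, revcomp

__all__ = [
    "MitoReference",
    "ReferenceLibrary",
    "BulkSampleTruth",
    "ReadSet",
    "simulate_reference_library",
    "simulate_truth",
    "simulate_bulk_sample",
    "simulate_bulk_sample_chunks",
    "simulate_read_counts",
    "inject_contamination",
    "required_depth",
    "mappable_fraction",
    "truth_matrices",
    "DEFAULT_MITO_FRACTION_RANGE",
]

# mirrors the observed range of mitochondrial read fractions, 0.005%-1.319%
DEFAULT_MITO_FRACTION_RANGE = (0.00005, 0.01319)
CANONICAL_LENGTH = 16_000


@dataclass
class MitoReference:
    """A circular reference mitogenome; ``sequence`` is kept encoded (uint8)."""

    species_id: str
    sequence: np.ndarray
    achieved_length: int

    def __post_init__(self) -> None:
        self.sequence = np.asarray(self.sequence, dtype=np.uint8)
        if self.achieved_length != self.sequence.size:
            raise ValueError(
                f"{self.species_id}: achieved_length {self.achieved_length} "
                f"!= sequence length {self.sequence.size}"
            )

    @property
    def sequence_str(self) -> str:
        return decode(self.sequence)


class ReferenceLibrary(list):
    """List of :class:`MitoReference` with id-based lookup."""

    def get(self, species_id: str) -> MitoReference:
        for ref in self:
            if ref.species_id == species_id:
                return ref
        raise KeyError(species_id)

    @property
    def species_ids(self) -> list[str]:
        return [r.species_id for r in self]


@dataclass
class BulkSampleTruth:
    """Known composition of one bulk sample."""

    sample_id: str
    counts: dict[str, int]
    biomass: dict[str, float]

    @property
    def total_biomass(self) -> float:
        return float(sum(self.biomass.values()))


@dataclass
class ReadSet:
    """A batch of equal-length reads as an encoded (n, L) uint8 matrix."""

    sequences: np.ndarray
    ids: list[str] | None = None
    sample_id: str | None = None

    def __len__(self) -> int:
        return self.sequences.shape[0]

    def with_ids(self, prefix: str = "read") -> "ReadSet":
        ids = [f"{prefix}_{i}" for i in range(len(self))]
        return ReadSet(self.sequences, ids, self.sample_id)


# -- reference library --------------------------------------------------------


def _pairwise_repair(seqs: list[np.ndarray], window: int, min_diffs: int,
                     rng: np.random.Generator, max_sweeps: int) -> None:
    """Ensure every homologous circular window between every species pair has
    >= ``min_diffs`` substitutions, adding targeted substitutions in place.

    Only homologous (same-offset) windows need checking: non-homologous
    windows of independently mutated sequences are ~75% divergent.
    """
    n = len(seqs)
    L = min(s.size for s in seqs)
    for _ in range(max_sweeps):
        dirty = False
        for a in range(n):
            for b in range(a + 1, n):
                la, lb = seqs[a][:L], seqs[b][:L]
                diff = (la != lb).astype(np.int64)
                circ = np.concatenate([diff, diff[: window - 1]])
                c = np.concatenate([[0], np.cumsum(circ)])
                wsum = (c[window:] - c[:-window])[:L]
                bad = np.nonzero(wsum < min_diffs)[0]
                if bad.size == 0:
                    continue
                dirty = True
                # mutate one matching site inside each offending window
                for start in bad:
                    idx = (start + rng.integers(0, window)) % L
                    # pick a site where the two still agree
                    for probe in range(window):
                        j = (start + probe) % L
                        if seqs[a][j] == seqs[b][j]:
                            idx = j
                            break
                    old = seqs[b][idx]
                    seqs[b][idx] = (old + 1 + rng.integers(0, 3)) % 4
        if not dirty:
            return
    raise RuntimeError(
        "could not make reference windows unique within the repair budget; "
        "raise min_divergence or shorten the references"
    )


def simulate_reference_library(
    n_species: int = 48,
    length_range: tuple[int, int] = (14_500, 16_000),
    min_divergence: float = 0.05,
    seed: int | np.random.Generator = 0,
    mito_fraction_range: tuple[float, float] = DEFAULT_MITO_FRACTION_RANGE,
    biomass_lognormal: tuple[float, float] = (np.log(50.0), 0.4),
    read_length: int = 100,
    mismatch_budget: int = 1,
) -> tuple[ReferenceLibrary, pd.DataFrame]:
    """Generate a reference library and per-species metadata.

    Sequences descend from a common random ancestor with independent
    per-species substitutions at rate ``min_divergence``; homologous windows
    that remain within ``mismatch_budget`` mismatches of each other are
    repaired by targeted extra substitutions, so every ``read_length`` window
    is unique to its species under the mapping contract.

    Metadata columns: ``mito_fraction`` (uniform over
    ``mito_fraction_range``) and ``biomass_per_individual`` (log-normal,
    arbitrary mass units; default median 50).
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    if not (8_000 <= lo <= hi <= 20_000):
        raise ValueError("length_range must lie within [8000, 20000]")
    ancestor = rng.integers(0, 4, size=hi, dtype=np.uint8)
    lengths = rng.integers(lo, hi + 1, size=n_species)
    seqs: list[np.ndarray] = []
    for k in range(n_species):
        s = ancestor[: lengths[k]].copy()
        mut = rng.random(s.size) < min_divergence
        s[mut] = (s[mut] + 1 + rng.integers(0, 3, size=int(mut.sum()), dtype=np.uint8)) % 4
        seqs.append(s)
    _pairwise_repair(seqs, read_length, mismatch_budget + 1, rng, max_sweeps=20)

    ids = [f"sp{k + 1:02d}" for k in range(n_species)]
    library = ReferenceLibrary(
        MitoReference(ids[k], seqs[k], int(lengths[k])) for k in range(n_species)
    )
    mf_lo, mf_hi = mito_fraction_range
    meta = pd.DataFrame(
        {
            "mito_fraction": rng.uniform(mf_lo, mf_hi, size=n_species),
            "biomass_per_individual": rng.lognormal(*biomass_lognormal, size=n_species),
        },
        index=pd.Index(ids, name="species_id"),
    )
    return library, meta


def simulate_truth(
    library: ReferenceLibrary,
    meta: pd.DataFrame,
    n_samples: int = 10,
    species_range: tuple[int, int] = (3, 11),
    individuals_range: tuple[int, int] = (13, 51),
    seed: int | np.random.Generator = 0,
    niche_width: float | None = 0.08,
    n_regions: int = 4,
    region_jitter: float = 0.03,
) -> list[BulkSampleTruth]:
    """Draw bulk-sample compositions: per sample, a species subset and
    individual counts whose total falls in ``individuals_range``.

    Samples are grouped into ``n_regions`` regions along a latent
    environmental gradient (mirroring a multi-landscape field design): each
    species gets a niche position in [0, 1], each sample sits near its
    region's position, and species are drawn with weight
    ``exp(-(u - v)^2 / (2 * niche_width^2))``.  Samples from the same region
    therefore share species while regions turn over — the clustered
    community structure field studies show, and what makes their
    ordinations well determined.  ``niche_width=None`` disables the
    gradient (uniform species draws).
    """
    rng = np.random.default_rng(seed)
    ids = library.species_ids
    niche = rng.uniform(0.0, 1.0, size=len(ids))
    out = []
    for s in range(n_samples):
        k = int(min(rng.integers(species_range[0], species_range[1] + 1), len(ids)))
        if niche_width is None:
            p = None
        else:
            region = s * n_regions // n_samples
            v = (region + 0.5) / n_regions + rng.normal(0.0, region_jitter)
            w = np.exp(-((niche - v) ** 2) / (2 * niche_width**2))
            p = w / w.sum()
        chosen = list(rng.choice(ids, size=k, replace=False, p=p))
        lo, hi = individuals_range
        for _ in range(1000):
            counts = 1 + rng.poisson(max(0.0, (lo + hi) / 2 / k - 1), size=k)
            if lo <= counts.sum() <= hi:
                break
        else:
            raise RuntimeError("could not draw a composition within the individuals range")
        counts_d = {sp: int(c) for sp, c in zip(chosen, counts)}
        biomass_d = {
            sp: float(c * meta.loc[sp, "biomass_per_individual"]) for sp, c in counts_d.items()
        }
        out.append(BulkSampleTruth(f"sample{s + 1:02d}", counts_d, biomass_d))
    return out


# -- read simulation ----------------------------------------------------------


def _weights(meta: pd.DataFrame, truth: BulkSampleTruth) -> tuple[list[str], np.ndarray]:
    """Per-source probabilities: present species then the nuclear pseudo-source."""
    species = sorted(truth.counts)
    w = []
    for sp in species:
        w.append(truth.biomass[sp] * float(meta.loc[sp, "mito_fraction"]))
    nuclear = sum(
        truth.biomass[sp] * (1.0 - float(meta.loc[sp, "mito_fraction"])) for sp in species
    )
    w.append(nuclear)
    w = np.asarray(w, dtype=float)
    return species, w / w.sum()


def mappable_fraction(read_length: int, error_rate: float, budget: int = 1) -> float:
    """Probability that a read's substitution errors stay within the mapping
    budget (binomial tail)."""
    from scipy.stats import binom

    return float(binom.cdf(budget, read_length, error_rate))


def required_depth(
    truth: BulkSampleTruth,
    meta: pd.DataFrame,
    read_length: int = 100,
    error_rate: float = 0.002,
    target_min_reads: int = 50,
    floor: int = 50_000,
) -> int:
    """Sequencing-depth design rule: the total read count at which the
    weakest present species (smallest ``biomass * mito_fraction``) expects
    ``target_min_reads`` mappable mitochondrial reads.

    ``target_min_reads = 50`` puts expected coverage of a 16 kb reference at
    ~27% (from ``1 - exp(-n * L_read / L_ref)``), comfortably above the 10%
    detection threshold even after Poisson noise.
    """
    species, p = _weights(meta, truth)
    frac = mappable_fraction(read_length, error_rate)
    pmin = p[: len(species)].min()
    return max(int(floor), int(np.ceil(target_min_reads / (pmin * frac))))


def _species_reads(
    ref: MitoReference, n: int, read_length: int, error_rate: float, rng: np.random.Generator
) -> np.ndarray:
    L = ref.sequence.size
    if read_length > L:
        raise ValueError(f"read_length {read_length} exceeds reference {ref.species_id} ({L} bp)")
    circ = np.concatenate([ref.sequence, ref.sequence[: read_length - 1]])
    starts = rng.integers(0, L, size=n)
    reads = circ[starts[:, None] + np.arange(read_length)[None, :]]
    if error_rate > 0:
        err = rng.random(reads.shape) < error_rate
        n_err = int(err.sum())
        if n_err:
            shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
            reads[err] = (reads[err] + shift) % 4
    rev = rng.random(n) < 0.5
    if rev.any():
        reads[rev] = revcomp(reads[rev])
    return reads


def simulate_bulk_sample_chunks(
    library: ReferenceLibrary,
    meta: pd.DataFrame,
    truth: BulkSampleTruth,
    total_reads: int,
    read_length: int = 100,
    error_rate: float = 0.002,
    seed: int | np.random.Generator = 0,
    chunk_size: int = 250_000,
) -> tuple[Iterator[ReadSet], pd.DataFrame]:
    """Streaming variant of :func:`simulate_bulk_sample`.

    Returns a chunk iterator plus the expected-read table.  Each chunk is a
    deterministic mixture of mitochondrial reads and nuclear background in
    the drawn proportions (reads within a chunk are shuffled).
    """
    rng = np.random.default_rng(seed)
    if error_rate < 0 or error_rate > 0.05:
        raise ValueError("error_rate must lie in [0, 0.05]")
    species, p = _weights(meta, truth)
    missing = [sp for sp in species if sp not in library.species_ids]
    if missing:
        raise KeyError(f"truth species missing from library: {missing}")
    shortest = min(r.sequence.size for r in library)
    if read_length > shortest:
        raise ValueError(f"read_length {read_length} exceeds shortest reference ({shortest} bp)")
    counts = rng.multinomial(total_reads, p)
    expected = pd.DataFrame(
        {
            "expected_reads": total_reads * p[: len(species)],
            "drawn_reads": counts[: len(species)],
        },
        index=pd.Index(species, name="species_id"),
    )
    expected.attrs["nuclear_reads"] = int(counts[-1])

    def gen() -> Iterator[ReadSet]:
        remaining = counts.copy()
        sources = species + ["__nuclear__"]
        chunk_no = 0
        while remaining.sum() > 0:
            take = np.minimum(
                remaining, rng.multinomial(min(chunk_size, remaining.sum()),
                                           remaining / remaining.sum()),
            )
            # multinomial with capped cells can under-fill; top up greedily
            deficit = min(chunk_size, remaining.sum()) - take.sum()
            while deficit > 0:
                room = np.nonzero(remaining - take > 0)[0]
                add = min(deficit, int((remaining - take)[room[0]]))
                take[room[0]] += add
                deficit -= add
            parts = []
            for i, src in enumerate(sources):
                n = int(take[i])
                if n == 0:
                    continue
                if src == "__nuclear__":
                    raw = np.frombuffer(rng.bytes(n * read_length), dtype=np.uint8)
                    parts.append((raw & 3).reshape(n, read_length))
                else:
                    parts.append(
                        _species_reads(library.get(src), n, read_length, error_rate, rng)
                    )
            mat = np.concatenate(parts) if parts else np.zeros((0, read_length), np.uint8)
            mat = mat[rng.permutation(mat.shape[0])]
            yield ReadSet(mat, None, truth.sample_id)
            remaining -= take
            chunk_no += 1

    return gen(), expected


def simulate_bulk_sample(
    library: ReferenceLibrary,
    meta: pd.DataFrame,
    truth: BulkSampleTruth,
    total_reads: int,
    read_length: int = 100,
    error_rate: float = 0.002,
    seed: int | np.random.Generator = 0,
) -> tuple[ReadSet, pd.DataFrame]:
    """Simulate one bulk sample's shotgun reads in memory.

    Mitochondrial reads are ``read_length`` windows drawn uniformly over the
    circular reference on a uniformly chosen strand with iid per-base
    substitution errors; the nuclear background is uniform random DNA.
    Returns the shuffled read set and the expected-read table.
    """
    chunks, expected = simulate_bulk_sample_chunks(
        library, meta, truth, total_reads, read_length, error_rate, seed,
        chunk_size=max(total_reads, 1),
    )
    mats = [c.sequences for c in chunks]
    mat = np.concatenate(mats) if mats else np.zeros((0, read_length), np.uint8)
    return ReadSet(mat, None, truth.sample_id), expected


def simulate_read_counts(
    meta: pd.DataFrame,
    truth: BulkSampleTruth,
    total_reads: int,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Count-level fast path: multinomial mitochondrial read counts per
    present species under the same weight model, without instantiating
    sequences.  Columns: ``reads`` (drawn), ``expected_reads``."""
    rng = np.random.default_rng(seed)
    species, p = _weights(meta, truth)
    counts = rng.multinomial(total_reads, p)
    return pd.DataFrame(
        {"reads": counts[: len(species)], "expected_reads": total_reads * p[: len(species)]},
        index=pd.Index(species, name="species_id"),
    )


def inject_contamination(
    reads: ReadSet,
    library: ReferenceLibrary,
    species_id: str,
    n_reads: int,
    seed: int | np.random.Generator = 0,
) -> ReadSet:
    """Append ``n_reads`` error-free windows of the named (absent) species and
    reshuffle deterministically.

    The default study level, 10 reads per contaminant, covers at most
    1 kb = 6.25% of a 16 kb reference, below the 10% detection threshold and
    matching the observed true-negative coverage range (0-7.7%).
    """
    rng = np.random.default_rng(seed)
    ref = library.get(species_id)  # KeyError if absent from the library
    if n_reads == 0:
        return reads
    L = reads.sequences.shape[1]
    contam = _species_reads(ref, n_reads, L, 0.0, rng)
    mat = np.concatenate([reads.sequences, contam])
    mat = mat[rng.permutation(mat.shape[0])]
    return ReadSet(mat, None, reads.sample_id)


def truth_matrices(
    truths: Sequence[BulkSampleTruth], species_ids: Sequence[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Species x sample count and biomass matrices over the full reference
    grid (absent species appear as zero rows)."""
    samples = [t.sample_id for t in truths]
    counts = pd.DataFrame(0.0, index=list(species_ids), columns=samples)
    biomass = pd.DataFrame(0.0, index=list(species_ids), columns=samples)
    for t in truths:
        for sp, c in t.counts.items():
            counts.loc[sp, t.sample_id] = c
            biomass.loc[sp, t.sample_id] = t.biomass[sp]
    return counts, biomass
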