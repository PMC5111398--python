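"""One-call synthetic study: generate a reference library and bulk samples,
map the reads, profile, and run the downstream analyses.

This is the validation harness the package ships with: every quantity is
computed by the same code paths a real study would use, but against known
ground truth.  Sequencing depth per sample is right-sized by
:func:`mitopool.simulate.required_depth` — the weakest present species gets
an expected ~50 mappable mitochondrial reads, mirroring how a real study
picks its depth so rare species stay detectable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import community as comm
from . import evaluate as ev
from . import quantify as qt
from . import simulate as sim
from .mapper import Index, build_index, map_reads
from .profiling import DetectionConfig, ProfileTable, build_profile, read_frequencies

__all__ = [
    "StudyResult",
    "run_synthetic_study",
    "contaminant_coverages",
    "study_regression",
    "study_community",
]


@dataclass
class StudyResult:
    library: sim.ReferenceLibrary
    meta: pd.DataFrame
    truths: list[sim.BulkSampleTruth]
    profile: ProfileTable
    confusion: ev.ConfusionSummary
    depths_used: dict[str, int]
    index: Index | None = None
    sample_rngs: dict[str, np.random.Generator] = field(default_factory=dict)

    def truth_presence(self) -> pd.DataFrame:
        counts, _ = sim.truth_matrices(self.truths, self.library.species_ids)
        return counts > 0

    def truth_biomass(self) -> pd.DataFrame:
        _, biomass = sim.truth_matrices(self.truths, self.library.species_ids)
        return biomass


def run_synthetic_study(
    seed: int,
    n_species: int = 48,
    n_samples: int = 10,
    read_length: int = 100,
    error_rate: float = 0.002,
    total_reads: int | None = None,
    target_min_reads: int = 50,
    detection: DetectionConfig = DetectionConfig(),
    fixed_library: tuple | None = None,
) -> StudyResult:
    """Simulate and profile a full study at the given seed.

    ``total_reads=None`` applies the per-sample depth design rule (floored at
    5e4 reads).  ``fixed_library`` optionally reuses a pre-built
    ``(library, meta, index)`` so multi-seed experiments share one reference
    set, as a real monitoring programme would.
    """
    root = np.random.SeedSequence(seed)
    s_lib, s_truth, s_reads = root.spawn(3)
    if fixed_library is not None:
        library, meta, index = fixed_library
    else:
        library, meta = sim.simulate_reference_library(
            n_species, seed=np.random.default_rng(s_lib), read_length=read_length
        )
        index = build_index(library, read_length)
    truths = sim.simulate_truth(library, meta, n_samples, seed=np.random.default_rng(s_truth))

    mapping = {}
    depths_used = {}
    sample_rngs = {}
    for truth, child in zip(truths, s_reads.spawn(len(truths))):
        depth = total_reads or sim.required_depth(
            truth, meta, read_length, error_rate, target_min_reads
        )
        depths_used[truth.sample_id] = depth
        rng = np.random.default_rng(child)
        chunks, _ = sim.simulate_bulk_sample_chunks(
            library, meta, truth, depth, read_length, error_rate, seed=rng
        )
        mapping[truth.sample_id] = map_reads(chunks, index, keep_assignments=False)
        sample_rngs[truth.sample_id] = rng

    profile = build_profile(mapping, library, meta, detection)
    counts, _ = sim.truth_matrices(truths, library.species_ids)
    summ = ev.confusion(profile.presence_matrix(), counts > 0)
    return StudyResult(library, meta, truths, profile, summ, depths_used, index, sample_rngs)


def contaminant_coverages(
    result: StudyResult, n_reads: int = 10, seed: int = 0
) -> pd.Series:
    """Coverage fraction each sample's cross-contaminant would reach.

    For every sample, one absent species is chosen and ``n_reads`` error-free
    reads of it are mapped (read mapping is per-read independent, so mapping
    the contaminant reads alone and combining depth equals remapping the
    whole injected sample).  Returns contaminant coverage per sample.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for truth in result.truths:
        absent = sorted(set(result.library.species_ids) - set(truth.counts))
        contaminant = absent[int(rng.integers(len(absent)))]
        ref = result.library.get(contaminant)
        reads = sim._species_reads(ref, n_reads, result.index.read_length, 0.0, rng)
        mr = map_reads(sim.ReadSet(reads), result.index, keep_assignments=False)
        depth = mr.depth[contaminant]
        out[truth.sample_id] = float((depth > 0).mean())
    return pd.Series(out)


def study_regression(
    result: StudyResult, variant: str = "corrected_reads", model: str = "both"
) -> dict[str, qt.RegressionResult]:
    """Biomass-frequency vs read-frequency regression on a study's profile."""
    x, y = qt.regression_points(result.profile.matrix(variant), result.truth_biomass())
    out = {}
    if model in ("ols", "both"):
        out["ols"] = qt.ols_fit(x, y)
    if model in ("gls", "both"):
        out["gls"] = qt.gls_varexp_fit(x, y)
    return out


def study_community(
    result: StudyResult, n_permutations: int = 999, seed: int = 0
) -> dict:
    """Ordination congruence and richness between read- and biomass-based
    community tables (presence/absence and quantitative).

    The two ordinations of each pair run from identical restart
    initialisations (common random numbers), so configuration differences
    reflect the data rather than restart luck.
    """
    rng = np.random.default_rng(seed)
    freqs = read_frequencies(result.profile)
    biomass = result.truth_biomass()
    bfreq = biomass / biomass.sum(axis=0)
    pres_reads = result.profile.presence_matrix()
    pres_truth = result.truth_presence()

    out = {}
    for label, (a, b, binary) in {
        "presence": (pres_reads.astype(float), pres_truth.astype(float), True),
        "quantitative": (freqs, bfreq, False),
    }.items():
        d_a = comm.jaccard(a, binary=binary)
        d_b = comm.jaccard(b, binary=binary)
        ord_seed = int(rng.integers(2**31))
        o_a = comm.nmds(d_a, seed=ord_seed)
        o_b = comm.nmds(d_b, seed=ord_seed)
        out[label] = comm.procrustes_protest(
            o_b.configuration, o_a.configuration, n_permutations=n_permutations, seed=rng
        )
    out["chao2_reads"] = comm.chao2(pres_reads)
    out["chao2_truth"] = comm.chao2(pres_truth)
    out["welch"] = comm.welch_from_estimates(
        out["chao2_truth"].chao2, max(out["chao2_truth"].se, 1e-9), pres_truth.shape[1],
        out["chao2_reads"].chao2, max(out["chao2_reads"].se, 1e-9), pres_reads.shape[1],
    )
    return out
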