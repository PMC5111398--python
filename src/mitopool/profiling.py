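"""Species x sample profiling: raw counts, coverage fractions, normalised and
mitonuclear-corrected read numbers, read frequencies, and presence calls.

Read counts are normalised in two steps:

* length normalisation — mapped reads divided by ``achieved_length / 16000``
  so that species with incomplete reference assemblies are not undercounted;
* mitonuclear correction — the length-normalised count divided by the
  species' mitochondrial read fraction, compensating for species-level
  differences in the mitochondrial share of total DNA.

A species is called present in a sample when the fraction of its reference
positions covered by at least one uniquely mapped read is strictly greater
than the detection threshold (default 10%).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DetectionConfig",
    "ProfileTable",
    "coverage_fraction",
    "normalize_reads",
    "build_profile",
    "profile_from_counts",
    "call_detections",
    "read_frequencies",
]


@dataclass(frozen=True)
class DetectionConfig:
    coverage_threshold: float = 0.10
    canonical_length: int = 16_000

    def __post_init__(self) -> None:
        if not 0 < self.coverage_threshold < 1:
            raise ValueError("coverage_threshold must be in (0, 1)")


def coverage_fraction(depth_vector: np.ndarray) -> float:
    """Fraction of reference positions with depth >= 1."""
    depth_vector = np.asarray(depth_vector)
    if depth_vector.size == 0:
        raise ValueError("empty depth vector")
    return float(np.count_nonzero(depth_vector >= 1) / depth_vector.size)


def normalize_reads(
    raw_reads: float,
    achieved_length: int,
    mito_fraction: float,
    canonical_length: int = 16_000,
) -> tuple[float, float]:
    """Length-normalised and mitonuclear-corrected read numbers.

    ``normalized = raw / (achieved_length / canonical_length)``;
    ``corrected = normalized / mito_fraction``.
    """
    if achieved_length <= 0:
        raise ValueError("achieved_length must be positive")
    if not 0 < mito_fraction <= 1:
        raise ValueError("mito_fraction must be in (0, 1]")
    normalized = raw_reads / (achieved_length / canonical_length)
    return normalized, normalized / mito_fraction


@dataclass
class ProfileTable:
    """Long-form species x sample profile.

    ``data`` columns: species, sample, raw_reads, coverage_fraction,
    normalized_reads, corrected_reads, present.  Every reference species
    appears in every sample (explicit zero rows), so true negatives are
    representable.
    """

    data: pd.DataFrame
    config: DetectionConfig

    def matrix(self, column: str) -> pd.DataFrame:
        return self.data.pivot(index="species", columns="sample", values=column)

    def presence_matrix(self) -> pd.DataFrame:
        return self.matrix("present").astype(bool)

    def coverage_matrix(self) -> pd.DataFrame:
        return self.matrix("coverage_fraction")


def build_profile(
    mapping_results: Mapping[str, "MappingResult"],
    library,
    meta: pd.DataFrame,
    config: DetectionConfig = DetectionConfig(),
) -> ProfileTable:
    """Assemble the profile from per-sample mapping results.

    ``mapping_results`` maps sample id -> MappingResult; ``library`` provides
    achieved lengths; ``meta`` the per-species mito fractions.
    """
    rows = []
    for sample_id, mr in mapping_results.items():
        for ref in library:
            sp = ref.species_id
            depth = mr.depth[sp]
            raw = int(mr.unique_counts.get(sp, 0))
            cov = coverage_fraction(depth)
            norm, corr = normalize_reads(
                raw, ref.achieved_length, float(meta.loc[sp, "mito_fraction"]),
                config.canonical_length,
            )
            rows.append((sp, sample_id, raw, cov, norm, corr))
    df = pd.DataFrame(
        rows,
        columns=["species", "sample", "raw_reads", "coverage_fraction",
                 "normalized_reads", "corrected_reads"],
    )
    df["present"] = df["coverage_fraction"] > config.coverage_threshold
    return ProfileTable(df, config)


def profile_from_counts(
    counts: pd.DataFrame,
    library,
    meta: pd.DataFrame,
    config: DetectionConfig = DetectionConfig(),
    read_length: int = 100,
) -> ProfileTable:
    """Build a profile from a species x sample raw-read-count matrix, with
    coverage approximated by its expectation ``1 - exp(-n L_read / L_ref)``
    (used by the count-level simulation fast path)."""
    lengths = {r.species_id: r.achieved_length for r in library}
    rows = []
    for sample in counts.columns:
        for sp in counts.index:
            raw = float(counts.loc[sp, sample])
            cov = 1.0 - np.exp(-raw * read_length / lengths[sp])
            norm, corr = normalize_reads(
                raw, lengths[sp], float(meta.loc[sp, "mito_fraction"]), config.canonical_length
            )
            rows.append((sp, sample, raw, cov, norm, corr))
    df = pd.DataFrame(
        rows,
        columns=["species", "sample", "raw_reads", "coverage_fraction",
                 "normalized_reads", "corrected_reads"],
    )
    df["present"] = df["coverage_fraction"] > config.coverage_threshold
    return ProfileTable(df, config)


def call_detections(profile: ProfileTable, config: DetectionConfig | None = None) -> ProfileTable:
    """(Re)compute presence flags: present iff coverage_fraction > threshold
    (strict inequality: coverage exactly at the threshold is absent)."""
    config = config or profile.config
    df = profile.data.copy()
    df["present"] = df["coverage_fraction"] > config.coverage_threshold
    return ProfileTable(df, config)


def read_frequencies(profile: ProfileTable, column: str = "corrected_reads") -> pd.DataFrame:
    """Within-sample frequencies of (by default) corrected reads; each sample
    column sums to 1.  A sample with no reads at all is an error."""
    mat = profile.matrix(column)
    totals = mat.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"sample(s) with no reads: {list(zero.index)}")
    return mat / totals
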