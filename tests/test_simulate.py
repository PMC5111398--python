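import numpy as np
import pytest
from scipy import stats

from mitopool import simulate as sim
from mitopool._seq import decode, revcomp


class TestReferenceLibrary:
    def test_seeded_determinism_is_byte_identical(self):
        a, ma = sim.simulate_reference_library(4, (8_000, 9_000), seed=5)
        b, mb = sim.simulate_reference_library(4, (8_000, 9_000), seed=5)
        for ra, rb in zip(a, b):
            assert ra.species_id == rb.species_id
            assert np.array_equal(ra.sequence, rb.sequence)
        assert ma.equals(mb)

    def test_lengths_and_metadata_ranges(self):
        lib, meta = sim.simulate_reference_library(48, (15_000, 16_000), seed=1)
        assert len(lib) == 48
        assert all(15_000 <= r.achieved_length <= 16_000 for r in lib)
        lo, hi = sim.DEFAULT_MITO_FRACTION_RANGE
        assert ((meta.mito_fraction >= lo) & (meta.mito_fraction <= hi)).all()
        assert (meta.biomass_per_individual > 0).all()

    def test_no_window_of_one_species_matches_another_within_budget(self, small_library):
        """Exhaustive cross-window check: after generation, no 100-bp window
        (either strand) of one species aligns to any window of another with
        <= 1 mismatch."""
        lib, _ = small_library
        win = 100
        mats = []
        for r in lib:
            circ = np.concatenate([r.sequence, r.sequence[: win - 1]])
            mats.append(np.lib.stride_tricks.sliding_window_view(circ, win))
        for i in range(len(lib)):
            onehot_i = [(mats[i] == b).astype(np.float32) for b in range(4)]
            for j in range(len(lib)):
                if i == j:
                    continue
                for wj in (mats[j], revcomp(mats[j])):
                    matches = np.zeros((mats[i].shape[0], wj.shape[0]), dtype=np.float32)
                    for b in range(4):
                        matches += onehot_i[b] @ (wj == b).astype(np.float32).T
                    assert (win - matches).min() > 1


class TestTruth:
    def test_composition_ranges(self, small_truths):
        for t in small_truths:
            assert 3 <= len(t.counts) <= 11
            assert 13 <= sum(t.counts.values()) <= 51
            for sp, c in t.counts.items():
                assert t.biomass[sp] > 0 and c >= 1

    def test_biomass_equals_count_times_per_individual(self, small_library, small_truths):
        _, meta = small_library
        for t in small_truths:
            for sp, c in t.counts.items():
                assert t.biomass[sp] == pytest.approx(
                    c * meta.loc[sp, "biomass_per_individual"]
                )


class TestBulkSample:
    def test_single_species_pure_mito_reads_are_exact_windows(self, small_library):
        lib, meta = small_library
        meta = meta.copy()
        meta.loc[lib[0].species_id, "mito_fraction"] = 1.0
        truth = sim.BulkSampleTruth(
            "s", {lib[0].species_id: 3},
            {lib[0].species_id: 3 * meta.loc[lib[0].species_id, "biomass_per_individual"]},
        )
        reads, _ = sim.simulate_bulk_sample(lib, meta, truth, 200, error_rate=0.0, seed=2)
        doubled = decode(np.concatenate([lib[0].sequence, lib[0].sequence]))
        for row in reads.sequences:
            s = decode(row)
            assert s in doubled or decode(revcomp(row)) in doubled

    def test_zero_count_species_contributes_no_reads(self, small_library):
        lib, meta = small_library
        truth = sim.BulkSampleTruth(
            "s",
            {lib[0].species_id: 2, lib[1].species_id: 0},
            {lib[0].species_id: 10.0, lib[1].species_id: 0.0},
        )
        _, expected = sim.simulate_bulk_sample(lib, meta, truth, 10_000, seed=3)
        assert expected.loc[lib[1].species_id, "expected_reads"] == 0
        assert expected.loc[lib[1].species_id, "drawn_reads"] == 0

    def test_read_count_conservation(self, small_library, small_truths):
        lib, meta = small_library
        reads, _ = sim.simulate_bulk_sample(lib, meta, small_truths[0], 12_345, seed=6)
        assert len(reads) == 12_345

    def test_seeded_determinism(self, small_library, small_truths):
        lib, meta = small_library
        a, _ = sim.simulate_bulk_sample(lib, meta, small_truths[0], 5_000, seed=42)
        b, _ = sim.simulate_bulk_sample(lib, meta, small_truths[0], 5_000, seed=42)
        assert np.array_equal(a.sequences, b.sequences)

    def test_biomass_ratio_three_to_one_within_binomial_noise(self, small_library):
        lib, meta = small_library
        meta = meta.copy()
        sp1, sp2 = lib[0].species_id, lib[1].species_id
        meta.loc[[sp1, sp2], "mito_fraction"] = 0.01
        truth = sim.BulkSampleTruth("s", {sp1: 3, sp2: 1}, {sp1: 30.0, sp2: 10.0})
        _, expected = sim.simulate_bulk_sample(lib, meta, truth, 50_000, seed=13)
        n1 = expected.loc[sp1, "drawn_reads"]
        n2 = expected.loc[sp2, "drawn_reads"]
        total = n1 + n2
        # P(species-1 | mito read) = 0.75; binomial 3-sigma band
        sd = np.sqrt(total * 0.75 * 0.25)
        assert abs(n1 - 0.75 * total) <= 3 * sd

    def test_weight_model_chi_square_over_seeds(self, small_library, small_truths):
        """Drawn per-source counts follow the documented weight formula
        (chi-square goodness of fit pooled over 25 seeds, alpha=0.001)."""
        lib, meta = small_library
        truth = small_truths[1]
        species, p = sim._weights(meta, truth)
        total = 200_000
        counts = np.zeros(len(species) + 1)
        n_seeds = 25
        for s in range(n_seeds):
            df = sim.simulate_read_counts(meta, truth, total, seed=1_000 + s)
            counts[: len(species)] += df["reads"].to_numpy()
            counts[-1] += total - df["reads"].sum()
        chi2 = ((counts - n_seeds * total * p) ** 2 / (n_seeds * total * p)).sum()
        assert stats.chi2.sf(chi2, len(p) - 1) > 0.001

    def test_chunked_and_monolithic_generation_agree(self, small_library, small_truths):
        lib, meta = small_library
        chunks, _ = sim.simulate_bulk_sample_chunks(
            lib, meta, small_truths[0], 30_000, seed=77, chunk_size=7_000
        )
        total = sum(c.sequences.shape[0] for c in chunks)
        assert total == 30_000


class TestContamination:
    def test_zero_reads_returns_same_read_set(self, small_library, small_truths):
        lib, meta = small_library
        reads, _ = sim.simulate_bulk_sample(lib, meta, small_truths[0], 1_000, seed=1)
        out = sim.inject_contamination(reads, lib, lib[0].species_id, 0, seed=1)
        assert out is reads

    def test_read_count_grows_exactly(self, small_library, small_truths):
        lib, meta = small_library
        reads, _ = sim.simulate_bulk_sample(lib, meta, small_truths[0], 50_000, seed=1)
        out = sim.inject_contamination(reads, lib, lib[0].species_id, 100, seed=2)
        assert len(out) == 50_100

    def test_unknown_species_raises(self, small_library, small_truths):
        lib, meta = small_library
        reads, _ = sim.simulate_bulk_sample(lib, meta, small_truths[0], 100, seed=1)
        with pytest.raises(KeyError):
            sim.inject_contamination(reads, lib, "nope", 10, seed=1)

    def test_default_level_stays_under_detection_threshold(self, small_library):
        """10 contaminant reads cover at most 1 kb of a >= 2 kb reference;
        the expected coverage 1 - exp(-n L_read / L_ref) stays below 0.10
        for every reference in the default study (16 kb scale)."""
        n, L_read, L_ref = 10, 100, 16_000
        assert 1 - np.exp(-n * L_read / L_ref) < 0.10
        # and deterministically: n reads can never cover more than n*L_read
        assert n * L_read / L_ref < 0.10


def test_required_depth_design_rule(small_library, small_truths):
    lib, meta = small_library
    t = small_truths[0]
    depth = sim.required_depth(t, meta, target_min_reads=50)
    species, p = sim._weights(meta, t)
    frac = sim.mappable_fraction(100, 0.002)
    # weakest species expects at least the target number of mappable reads
    assert depth * p[: len(species)].min() * frac >= 50 - 1e-6
    assert depth >= 50_000
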