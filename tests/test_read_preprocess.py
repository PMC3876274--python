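"""Adapter profiling/trimming, exact mapping, dedup, coverage statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from scellcn import (
    CoverageStats,
    DEFAULT_ADAPTER,
    coverage_stats,
    dedup_alignments,
    map_reads_exact,
    profile_adapter,
    trim_reads,
)


def _mkreads(seqs):
    return [(f"r{i}", s, "I" * len(s)) for i, s in enumerate(seqs)]


class TestProfileAdapter:
    def test_fixed_prefix_detected(self):
        rng = np.random.default_rng(0)
        bases = np.array(list("ACGT"))
        seqs = [
            DEFAULT_ADAPTER + "".join(rng.choice(bases, 40)) for _ in range(300)
        ]
        prof = profile_adapter(_mkreads(seqs))
        assert prof.suggested_trim == 32

    def test_random_reads_zero_trim(self):
        rng = np.random.default_rng(1)
        bases = np.array(list("ACGT"))
        seqs = ["".join(rng.choice(bases, 60)) for _ in range(300)]
        assert profile_adapter(_mkreads(seqs)).suggested_trim == 0

    def test_identical_reads_degenerate(self):
        with pytest.warns(UserWarning, match="max_len"):
            prof = profile_adapter(_mkreads(["ACGT" * 20] * 10), max_len=50)
        assert prof.suggested_trim == 50

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            profile_adapter([])

    def test_frequencies_sum_to_one(self):
        prof = profile_adapter(_mkreads(["ACGTACGTAC"] * 5), max_len=10)
        assert np.allclose(prof.frequencies.sum(axis=1), 1.0)


class TestTrimReads:
    def test_trim_101_to_69(self):
        reads, dropped = trim_reads(_mkreads(["A" * 101]), 32)
        assert dropped == 0
        assert len(reads[0][1]) == 69
        assert len(reads[0][2]) == 69

    def test_zero_trim_identity(self):
        original = _mkreads(["ACGT" * 10])
        reads, dropped = trim_reads(original, 0)
        assert reads == original and dropped == 0

    def test_short_read_dropped_and_counted(self):
        reads, dropped = trim_reads(_mkreads(["A" * 30, "C" * 101]), 32)
        assert dropped == 1
        assert len(reads) == 1


class TestMapReadsExact:
    def test_unique_read_mapped_forward(self, dup_genome):
        genome, _, _ = dup_genome
        seq = genome["chr1"][25_000 : 25_000 + 69]
        aln, counters = map_reads_exact(_mkreads([seq]), genome)
        assert counters == {"mapped": 1, "unmapped": 0, "multimapped": 0}
        assert aln.iloc[0]["start"] == 25_000
        assert aln.iloc[0]["strand"] == "+"

    def test_reverse_complement_mapped(self, dup_genome):
        from scellcn._io import revcomp

        genome, _, _ = dup_genome
        seq = revcomp(genome["chr1"][25_000 : 25_000 + 69])
        aln, counters = map_reads_exact(_mkreads([seq]), genome)
        assert counters["mapped"] == 1
        assert aln.iloc[0]["start"] == 25_000
        assert aln.iloc[0]["strand"] == "-"

    def test_duplicated_region_read_discarded(self, dup_genome):
        genome, _, _ = dup_genome
        seq = genome["chr1"][11_000 : 11_000 + 69]  # inside the planted duplication
        aln, counters = map_reads_exact(_mkreads([seq]), genome)
        assert counters["multimapped"] == 1
        assert aln.empty

    def test_substituted_read_unmapped(self, dup_genome):
        genome, _, _ = dup_genome
        seq = list(genome["chr1"][25_000 : 25_000 + 69])
        seq[10] = "A" if seq[10] != "A" else "C"
        _, counters = map_reads_exact(_mkreads(["".join(seq)]), genome)
        assert counters["unmapped"] == 1

    def test_simulated_reads_recover_true_positions(self, small_cell):
        genome, _, reads, true_aln = small_cell
        trimmed, _ = trim_reads(reads[:2_000], 32)
        aln, counters = map_reads_exact(trimmed, genome)
        merged = aln.set_index("qname").join(
            true_aln.set_index("qname"), rsuffix="_true"
        )
        assert counters["mapped"] == len(aln)
        assert (merged["start"] == merged["start_true"]).all()
        assert (merged["strand"] == merged["strand_true"]).all()


class TestDedup:
    def test_triplicate_collapsed(self):
        aln = pd.DataFrame(
            {"qname": ["a", "b", "c"], "chrom": "chr1", "start": 100, "strand": "+"}
        )
        out = dedup_alignments(aln)
        assert len(out) == 1
        assert out.iloc[0]["qname"] == "a"  # first by name order

    def test_opposite_strands_both_kept(self):
        aln = pd.DataFrame(
            {"qname": ["a", "b"], "chrom": "chr1", "start": 100, "strand": ["+", "-"]}
        )
        assert len(dedup_alignments(aln)) == 2

    def test_idempotent(self, small_cell):
        _, _, _, aln = small_cell
        once = dedup_alignments(aln)
        twice = dedup_alignments(once)
        pd.testing.assert_frame_equal(once, twice)


class TestCoverageStats:
    def test_single_full_length_read(self):
        aln = pd.DataFrame({"qname": ["r"], "chrom": ["chr1"], "start": [0], "strand": ["+"]})
        cov = coverage_stats(aln, genome_length=69, read_length=69)
        assert cov.breadth == 1.0
        assert cov.depth_genome == pytest.approx(1.0)
        assert cov.depth_covered == pytest.approx(1.0)

    def test_identity_holds_exactly(self, small_cell):
        _, _, _, aln = small_cell
        d = dedup_alignments(aln)
        cov = coverage_stats(d, genome_length=2_000_000, read_length=69)
        assert abs(cov.depth_covered * cov.breadth - cov.depth_genome) < 1e-12

    def test_no_alignments_zeros_with_warning(self):
        empty = pd.DataFrame(columns=["qname", "chrom", "start", "strand"])
        with pytest.warns(UserWarning):
            cov = coverage_stats(empty, 1_000, 69)
        assert (cov.breadth, cov.depth_genome, cov.depth_covered) == (0.0, 0.0, 0.0)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    starts=st.lists(st.integers(0, 500), min_size=1, max_size=40),
    read_length=st.integers(1, 80),
)
def test_coverage_identity_property(starts, read_length):
    aln = pd.DataFrame(
        {
            "qname": [f"r{i}" for i in range(len(starts))],
            "chrom": "chr1",
            "start": starts,
            "strand": "+",
        }
    )
    cov = coverage_stats(aln, genome_length=1_000, read_length=read_length)
    assert abs(cov.depth_covered * cov.breadth - cov.depth_genome) < 1e-12
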