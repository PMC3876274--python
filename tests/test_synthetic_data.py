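"""Statistical and bookkeeping properties of the synthetic-data generator."""

import numpy as np
import pandas as pd
import pytest

from scellcn import (
    Clone,
    CnEvent,
    ReadSimSpec,
    SimGenomeSpec,
    SnpDepthSpec,
    TumorTruth,
    clone_cn_tracks,
    dedup_alignments,
    expected_bulk_cn,
    make_snp_panel,
    read_truth_bed,
    simulate_cell_reads,
    simulate_genome,
    simulate_primary_track,
    simulate_snp_counts,
    simulate_tumor_truth,
    write_truth_bed,
)


class TestSimulateGenome:
    def test_gc_follows_landscape(self):
        spec = SimGenomeSpec(n_chroms=1, chrom_length=100_000,
                             gc_landscape=((0, 0.5), (1, 0.5)), seed=0)
        genome, gc_truth = simulate_genome(spec)
        seq = genome["chr1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert 0.45 <= gc <= 0.55
        # windowed GC within +-0.05 of the control value
        assert ((gc_truth["gc"] - 0.5).abs() < 0.05).all()

    def test_seed_determinism(self):
        spec = SimGenomeSpec(n_chroms=2, chrom_length=20_000, seed=7)
        g1, _ = simulate_genome(spec)
        g2, _ = simulate_genome(spec)
        assert g1 == g2

    def test_duplicated_blocks_identical(self, dup_genome):
        genome, _, spec = dup_genome
        sc, s, e, dc, d = spec.planted_duplications[0]
        assert genome[sc][s:e] == genome[dc][d : d + (e - s)]

    def test_overlapping_duplication_rejected(self):
        spec = SimGenomeSpec(
            n_chroms=1, chrom_length=10_000,
            planted_duplications=[("chr1", 1_000, 3_000, "chr1", 2_000)], seed=0,
        )
        with pytest.raises(ValueError, match="overlap"):
            simulate_genome(spec)

    def test_invalid_gc_control_rejected(self):
        with pytest.raises(ValueError):
            SimGenomeSpec(gc_landscape=((0, 1.5),))


class TestTumorTruth:
    lengths = {"chr1": 100_000, "chr2": 100_000}

    def test_clonal_gain_track(self):
        truth = simulate_tumor_truth(
            self.lengths,
            [Clone("c", 1.0, [CnEvent("chr1", 50_000, 100_000, "A", +1, "arm")])],
        )
        tr = clone_cn_tracks(truth, "c")
        inside = tr[(tr.chrom == "chr1") & (tr.start >= 50_000)]
        outside = tr[(tr.chrom == "chr1") & (tr.end <= 50_000)]
        assert ((inside.cn_a + inside.cn_b) == 3).all()
        assert ((outside.cn_a + outside.cn_b) == 2).all()

    def test_cnloh_copy_neutral(self):
        truth = simulate_tumor_truth(
            self.lengths,
            [Clone("c", 1.0, [CnEvent("chr2", 10_000, 60_000, "A", 0, "cnLOH")])],
        )
        tr = clone_cn_tracks(truth, "c")
        inside = tr[(tr.chrom == "chr2") & (tr.start >= 10_000) & (tr.end <= 60_000)]
        assert ((inside.cn_a + inside.cn_b) == 2).all()
        assert (inside.cn_b == 0).all()

    def test_subclonal_mixture_arithmetic(self):
        truth = simulate_tumor_truth(
            self.lengths,
            [
                Clone("major", 0.6, []),
                Clone("minor", 0.4, [CnEvent("chr1", 10_000, 20_000, "B", -1, "focal")]),
            ],
        )
        tot, b = expected_bulk_cn(truth, "chr1", 15_000)
        assert tot == pytest.approx(0.6 * 2 + 0.4 * 1)

    def test_negative_cn_rejected(self):
        with pytest.raises(ValueError, match="below 0"):
            simulate_tumor_truth(
                self.lengths,
                [Clone("c", 1.0, [CnEvent("chr1", 0, 1_000, "A", -2, "focal")])],
            )

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            TumorTruth(clones=[Clone("c", 0.5, [])], chrom_lengths=self.lengths)

    def test_shatter_expansion_oscillates(self):
        truth = simulate_tumor_truth(
            self.lengths,
            [Clone("c", 1.0, [CnEvent("chr2", 0, 80_000, "A", 0, "shatter")])],
            seed=5,
        )
        tr = clone_cn_tracks(truth, "c")
        totals = (tr[tr.chrom == "chr2"].cn_a + tr[tr.chrom == "chr2"].cn_b).to_numpy()
        assert totals.min() < 2 < totals.max()  # oscillating states around diploid

    def test_truth_roundtrip(self, tmp_path):
        truth = simulate_tumor_truth(
            self.lengths,
            [
                Clone("a", 0.7, [CnEvent("chr1", 0, 50_000, "A", 1, "arm")]),
                Clone("b", 0.3, [CnEvent("chr2", 10_000, 20_000, "B", -1, "focal")]),
            ],
        )
        path = str(tmp_path / "truth.tsv")
        write_truth_bed(truth, path)
        back = read_truth_bed(path)
        assert back.chrom_lengths == truth.chrom_lengths
        assert [c.name for c in back.clones] == [c.name for c in truth.clones]
        for c1, c2 in zip(truth.clones, back.clones):
            assert c1.fraction == c2.fraction
            assert c1.events == c2.events


class TestCellReads:
    def test_read_count_conservation(self, small_cell):
        _, _, reads, aln = small_cell
        assert len(reads) == 20_000
        assert len(aln) == len(reads)

    def test_adapter_prefix_and_length(self, small_cell):
        _, _, reads, _ = small_cell
        spec = ReadSimSpec()
        assert spec.read_length == 69  # 101 raw minus 32-base adapter
        for name, seq, qual in reads[:100]:
            assert seq.startswith(spec.adapter_prefix)
            assert len(seq) == spec.read_length_raw
            assert len(qual) == len(seq)

    def test_seed_determinism(self, small_cell):
        genome, truth, reads, aln = small_cell
        reads2, aln2 = simulate_cell_reads(
            genome, truth, "cell", ReadSimSpec(n_reads=20_000, seed=5)
        )
        assert reads2 == reads
        pd.testing.assert_frame_equal(aln2, aln)

    def test_poisson_like_counts_without_bias(self):
        genome, _ = simulate_genome(SimGenomeSpec(n_chroms=1, chrom_length=500_000, seed=8))
        lengths = {"chr1": 500_000}
        truth = simulate_tumor_truth(lengths, [Clone("c", 1.0, [])])
        spec = ReadSimSpec(
            n_reads=50_000, gc_bias_coeff=0.0, amplification_dispersion=0.0,
            duplicate_rate=0.0, seed=6,
        )
        _, aln = simulate_cell_reads(genome, truth, "c", spec)
        counts, _ = np.histogram(aln["start"], bins=np.arange(0, 500_001, 5_000))
        ratio = counts.var() / counts.mean()
        assert 0.8 <= ratio <= 1.3

    def test_dosage_proportionality(self):
        genome, _ = simulate_genome(SimGenomeSpec(n_chroms=1, chrom_length=400_000, seed=8))
        lengths = {"chr1": 400_000}
        truth = simulate_tumor_truth(
            lengths, [Clone("c", 1.0, [CnEvent("chr1", 200_000, 400_000, "both", +1, "arm")])]
        )
        spec = ReadSimSpec(n_reads=100_000, gc_bias_coeff=0.0,
                           amplification_dispersion=0.0, duplicate_rate=0.0, seed=6)
        _, aln = simulate_cell_reads(genome, truth, "c", spec)
        lo = (aln["start"] < 200_000).sum()
        hi = (aln["start"] >= 200_000).sum()
        assert 1.8 <= hi / lo <= 2.2  # CN 4 vs CN 2

    def test_duplicate_rate_recovered_by_dedup(self):
        genome, _ = simulate_genome(SimGenomeSpec(n_chroms=1, chrom_length=1_000_000, seed=8))
        truth = simulate_tumor_truth({"chr1": 1_000_000}, [Clone("c", 1.0, [])])
        spec = ReadSimSpec(n_reads=10_000, duplicate_rate=0.2, seed=10)
        _, aln = simulate_cell_reads(genome, truth, "c", spec)
        kept = len(dedup_alignments(aln)) / len(aln)
        assert 0.77 <= kept <= 0.83

    def test_zero_reads_empty_outputs(self, small_cell):
        genome, truth, _, _ = small_cell
        reads, aln = simulate_cell_reads(genome, truth, "cell", ReadSimSpec(n_reads=0))
        assert reads == [] and aln.empty


class TestSnpCounts:
    def _balanced_setup(self, n_sites=500, seed=1):
        genome, _ = simulate_genome(SimGenomeSpec(n_chroms=1, chrom_length=200_000, seed=2))
        truth = simulate_tumor_truth({"chr1": 200_000}, [Clone("c", 1.0, [])])
        panel = make_snp_panel(genome, n_sites, het_fraction=1.0, seed=seed)
        return genome, truth, panel

    def test_balanced_het_baf_near_half(self):
        _, truth, panel = self._balanced_setup()
        counts = simulate_snp_counts(truth, "c", panel, SnpDepthSpec(mean_depth=20, seed=3))
        depth = counts.ref_count + counts.alt_count
        baf = counts.alt_count[depth > 0] / depth[depth > 0]
        assert 0.45 <= baf.mean() <= 0.55

    def test_cnloh_sites_monoallelic(self):
        genome, _ = simulate_genome(SimGenomeSpec(n_chroms=1, chrom_length=100_000, seed=2))
        truth = simulate_tumor_truth(
            {"chr1": 100_000},
            [Clone("c", 1.0, [CnEvent("chr1", 0, 100_000, "A", 0, "cnLOH")])],
        )
        panel = make_snp_panel(genome, 200, het_fraction=1.0, seed=4)
        counts = simulate_snp_counts(truth, "c", panel, SnpDepthSpec(mean_depth=20, seed=5))
        # allele B (alt carrier) deleted: no alt reads at all
        assert (counts.alt_count == 0).all()
        assert (counts.ref_count > 0).any()

    def test_homozygous_deletion_zero_depth(self):
        genome, _ = simulate_genome(SimGenomeSpec(n_chroms=1, chrom_length=50_000, seed=2))
        truth = simulate_tumor_truth(
            {"chr1": 50_000},
            [Clone("c", 1.0, [CnEvent("chr1", 0, 50_000, "both", -1, "focal")])],
        )
        panel = make_snp_panel(genome, 100, het_fraction=1.0, seed=4)
        counts = simulate_snp_counts(truth, "c", panel, SnpDepthSpec(mean_depth=20, seed=5))
        assert ((counts.ref_count + counts.alt_count) == 0).all()

    def test_empty_panel(self):
        from scellcn import SnpPanel

        _, truth, _ = self._balanced_setup()
        empty = SnpPanel(pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "base_a", "base_b"]))
        counts = simulate_snp_counts(truth, "c", empty, SnpDepthSpec())
        assert counts.empty
        assert list(counts.columns) == ["chrom", "pos", "ref", "alt", "ref_count", "alt_count"]


class TestPrimaryTrack:
    def test_clonal_gain_logr_closed_form(self):
        genome, _ = simulate_genome(SimGenomeSpec(n_chroms=1, chrom_length=100_000, seed=2))
        truth = simulate_tumor_truth(
            {"chr1": 100_000},
            [Clone("c", 1.0, [CnEvent("chr1", 0, 100_000, "A", +1, "arm")])],
        )
        track = simulate_primary_track(genome, truth, probe_spacing=5_000, noise_sd=0.0)
        assert np.allclose(track["logr"], np.log2(1.5))

    def test_half_subclonal_loss_logr(self):
        genome, _ = simulate_genome(SimGenomeSpec(n_chroms=1, chrom_length=100_000, seed=2))
        truth = simulate_tumor_truth(
            {"chr1": 100_000},
            [
                Clone("major", 0.5, []),
                Clone("minor", 0.5, [CnEvent("chr1", 0, 100_000, "B", -1, "focal")]),
            ],
        )
        track = simulate_primary_track(genome, truth, probe_spacing=5_000, noise_sd=0.0)
        assert np.allclose(track["logr"], np.log2(0.75))

    def test_diploid_genome_neutral(self):
        genome, _ = simulate_genome(SimGenomeSpec(n_chroms=1, chrom_length=100_000, seed=2))
        truth = simulate_tumor_truth({"chr1": 100_000}, [Clone("c", 1.0, [])])
        track = simulate_primary_track(genome, truth, probe_spacing=5_000, noise_sd=0.0, seed=9)
        assert np.allclose(track["logr"], 0.0)
        assert set(np.round(track["baf"], 6)) <= {0.0, 0.5, 1.0}
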