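"""logR construction, GC correction, ploidy scaling and aCGH processing."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare, spearmanr

from scellcn import (
    PloidyEstimate,
    SegmentationParams,
    call_integer_cn,
    compute_logr,
    count_reads_in_bins,
    estimate_ploidy,
    gc_correct,
    process_acgh_track,
)


def _bins(n, width=1_000, gc=0.45, chrom="chr1"):
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": np.arange(n) * width,
            "end": (np.arange(n) + 1) * width,
            "unique_count": width,
            "gc": gc if np.ndim(gc) else np.full(n, gc),
        }
    )


def _aln(starts, chrom="chr1"):
    return pd.DataFrame(
        {
            "qname": [f"r{i}" for i in range(len(starts))],
            "chrom": chrom,
            "start": starts,
            "strand": "+",
        }
    )


class TestCountReads:
    def test_reads_land_in_containing_bin(self):
        bins = _bins(6)
        out = count_reads_in_bins(_aln([3_200] * 10), bins)
        assert out["raw_count"].tolist() == [0, 0, 0, 10, 0, 0]

    def test_boundary_read_goes_right(self):
        bins = _bins(3)
        out = count_reads_in_bins(_aln([1_000]), bins)
        assert out["raw_count"].tolist() == [0, 1, 0]  # half-open [1000, 2000)

    def test_reads_outside_bins_counted(self):
        bins = _bins(2)
        out = count_reads_in_bins(_aln([5_000]), bins)
        assert out["raw_count"].sum() == 0
        assert out.attrs["n_outside"] == 1

    def test_uniform_reads_uniform_counts(self):
        rng = np.random.default_rng(0)
        bins = _bins(50)
        out = count_reads_in_bins(_aln(rng.integers(0, 50_000, 20_000)), bins)
        stat = chisquare(out["raw_count"])
        assert stat.pvalue > 0.01


class TestComputeLogr:
    def test_hand_arithmetic(self):
        bins = _bins(3)
        bins["raw_count"] = [1, 1, 7]
        track = compute_logr(bins, pseudocount=1, gc_min=0.28)
        assert np.allclose(track["logr"], [-1.0, -1.0, 1.0])  # counts' 2,2,8; mean 4

    def test_equal_counts_all_zero(self):
        bins = _bins(5)
        bins["raw_count"] = 9
        assert np.allclose(compute_logr(bins)["logr"], 0.0)

    def test_low_gc_bin_filtered_before_mean(self):
        bins = _bins(3, gc=np.array([0.25, 0.5, 0.5]))
        bins["raw_count"] = [100, 1, 7]
        track = compute_logr(bins)
        assert len(track) == 2
        # retained counts' are (2, 8); their mean 5 excludes the filtered bin
        assert np.allclose(track["logr"], [np.log2(2 / 5), np.log2(8 / 5)])

    def test_all_filtered_raises(self):
        bins = _bins(3, gc=0.1)
        bins["raw_count"] = 1
        with pytest.raises(ValueError, match="filtered"):
            compute_logr(bins)

    def test_scaling_counts_leaves_logr_unchanged(self):
        rng = np.random.default_rng(3)
        bins = _bins(40)
        counts = rng.integers(10, 60, 40)
        bins["raw_count"] = counts
        a = compute_logr(bins, pseudocount=0)["logr"]
        bins["raw_count"] = counts * 7
        b = compute_logr(bins, pseudocount=0)["logr"]
        assert np.allclose(a, b)


class TestGcCorrect:
    def _track(self, gc, logr):
        df = _bins(len(gc), gc=np.asarray(gc))
        df["raw_count"] = 0
        df["logr"] = logr
        return df

    def test_unbiased_track_only_centred(self):
        rng = np.random.default_rng(1)
        gc = rng.uniform(0.3, 0.6, 300)
        logr = rng.normal(0.7, 0.05, 300)  # no GC dependence
        out = gc_correct(self._track(gc, logr))
        change = out["logr"] - (logr - np.median(logr))
        assert np.abs(change).max() < 0.05
        assert abs(np.median(out["logr"])) < 1e-9

    def test_injected_gc_slope_removed(self):
        rng = np.random.default_rng(2)
        gc = rng.uniform(0.3, 0.6, 1_000)
        logr = 0.8 * (gc - gc.mean()) + rng.normal(0, 0.1, 1_000)
        out = gc_correct(self._track(gc, logr))
        assert abs(spearmanr(out["logr"], gc).statistic) < 0.1

    def test_constant_logr_all_zero(self):
        rng = np.random.default_rng(3)
        gc = rng.uniform(0.3, 0.6, 100)
        out = gc_correct(self._track(gc, np.full(100, 0.42)))
        assert np.allclose(out["logr"], 0.0, atol=1e-9)

    def test_degenerate_gc_range_warns(self):
        rng = np.random.default_rng(4)
        logr = rng.normal(0, 0.1, 50)
        with pytest.warns(UserWarning, match="degenerate"):
            out = gc_correct(self._track(np.full(50, 0.5), logr))
        assert np.allclose(out["logr"], logr - np.median(logr))

    def test_too_few_bins_raises(self):
        with pytest.raises(ValueError, match="30"):
            gc_correct(self._track([0.4] * 10, [0.0] * 10))


class TestPloidy:
    def _track(self, logr, chrom="chr1"):
        df = _bins(len(logr), chrom=chrom)
        df["logr"] = logr
        return df

    def test_neutral_reference_psi_two(self):
        est = estimate_ploidy(self._track([0.0] * 30), ("chr1", 0, 30_000))
        assert est.psi == pytest.approx(2.0)

    def test_depressed_reference_scales_up(self):
        est = estimate_ploidy(self._track([-0.3] * 30), ("chr1", 0, 30_000))
        assert est.psi == pytest.approx(2 * 2**0.3)

    def test_tetraploid_reference(self):
        est = estimate_ploidy(self._track([1.0] * 30), ("chr1", 0, 30_000), reference_cn=4)
        assert est.psi == pytest.approx(2.0)

    def test_region_without_bins_raises(self):
        with pytest.raises(ValueError, match="no bins"):
            estimate_ploidy(self._track([0.0] * 30), ("chr9", 0, 1_000))

    def test_psi_must_be_positive(self):
        with pytest.raises(ValueError):
            PloidyEstimate(psi=0.0, reference_region=("chr1", 0, 1))


class TestIntegerCn:
    @pytest.mark.parametrize(
        "mean_logr,psi,expected_cont,expected_int",
        [
            (0.0, 2.0, 2.0, 2),
            (1.0, 2.0, 4.0, 4),
            (0.45, 2.0, 2.732, 3),
            (-8.0, 2.0, 0.0078125, 0),
        ],
    )
    def test_formula(self, mean_logr, psi, expected_cont, expected_int):
        seg = pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [10], "n_bins": [1], "mean": [mean_logr]}
        )
        out = call_integer_cn(seg, PloidyEstimate(psi=psi, reference_region=("chr1", 0, 1)))
        assert out["cn_continuous"].iloc[0] == pytest.approx(expected_cont, rel=1e-3)
        assert out["cn_integer"].iloc[0] == expected_int

    def test_half_up_rounding(self):
        seg = pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [10], "n_bins": [1],
             "mean": [np.log2(2.5 / 2)]}
        )
        out = call_integer_cn(seg, PloidyEstimate(psi=2.0, reference_region=("chr1", 0, 1)))
        assert out["cn_integer"].iloc[0] == 3


class TestAcgh:
    def _probes(self, values, chrom="chr1"):
        return pd.DataFrame(
            {"chrom": chrom, "pos": np.arange(len(values)) * 1_000 + 500, "logr": values}
        )

    def test_degenerate_all_low(self):
        probes = self._probes(np.full(100, -5.0))
        processed, segments = process_acgh_track(
            probes, params=SegmentationParams(gamma=60, kmin=25)
        )
        assert np.allclose(processed["logr"], 0.0)  # floored to -2 then recentred
        assert len(segments) == 1

    def test_mean_zero_after_processing(self):
        rng = np.random.default_rng(5)
        probes = self._probes(rng.normal(0.3, 0.5, 400))
        processed, _ = process_acgh_track(probes)
        assert abs(processed["logr"].mean()) < 1e-9

    def test_step_recovered_within_three_probes(self):
        rng = np.random.default_rng(6)
        values = np.concatenate(
            [rng.normal(0, 0.15, 200), rng.normal(1.0, 0.15, 200), rng.normal(-1.0, 0.15, 200)]
        )
        probes = self._probes(values)
        _, segments = process_acgh_track(probes)
        assert len(segments) == 3
        # breakpoints at probe indices 200 and 400 (pos 200500, 400500)
        assert abs(segments["start"].iloc[1] - 200_500) <= 3_000
        assert abs(segments["start"].iloc[2] - 400_500) <= 3_000

    def test_missing_gc_column_warns_and_skips(self):
        probes = self._probes(np.zeros(50))
        with pytest.warns(UserWarning, match="gc column"):
            process_acgh_track(
                probes, params=SegmentationParams(gamma=60, kmin=25), gc_correct_flag=True
            )

    def test_unsorted_probes_rejected(self):
        probes = self._probes(np.zeros(30)).iloc[::-1]
        with pytest.raises(ValueError, match="sorted"):
            process_acgh_track(probes)
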