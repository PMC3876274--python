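"""Single-cell copy-number pipeline: bin counts to integer copy number.

The stages run in this order, mirroring how focal read-depth analysis of a
whole-genome-amplified single cell proceeds:

1. count deduplicated reads per variable bin (a read belongs to the bin
   containing its 5' start);
2. add a pseudocount of 1 to every bin and discard bins with GC < 28%;
3. logR = log2(count' / mean count' over retained bins);
4. loess-correct logR against bin GC (tricube weights, local degree-2
   polynomial by default) and subtract the genome-wide median;
5. segment per chromosome with PCF (penalty gamma = 25 by default);
6. estimate the average ploidy Psi from a reference region of known copy
   number: Psi = reference_cn * 2^(-mean corrected logR over the region);
7. per segment, continuous CN = 2^mean_logR * Psi, integer CN = half-up
   rounding floored at 0.

An aCGH processing mode handles probe-level log2 tracks instead: floor at
-2, optional GC loess, recentre to genome-wide mean 0, then PCF with
gamma = 60 and a 25-probe minimum segment length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pcf import SegmentationParams, segment_track

DEFAULT_PSEUDOCOUNT = 1.0
DEFAULT_GC_MIN = 0.28
DEFAULT_GAMMA_SEQ = 25.0
DEFAULT_GAMMA_ACGH = 60.0
DEFAULT_KMIN_ACGH = 25
DEFAULT_ACGH_FLOOR = -2.0


@dataclass
class PloidyEstimate:
    """Average ploidy Psi and the reference region that anchored it."""

    psi: float
    reference_region: tuple[str, int, int]
    reference_cn: int = 2

    def __post_init__(self) -> None:
        if self.psi <= 0:
            raise ValueError("psi must be > 0")


# ---------------------------------------------------------------- counting

def count_reads_in_bins(alignments: pd.DataFrame, binset: pd.DataFrame) -> pd.DataFrame:
    """Raw read count per variable bin.

    A read is assigned to the unique bin whose half-open interval contains
    its 5' start. Returns the binset with a ``raw_count`` column; reads
    falling outside every bin are counted in ``attrs['n_outside']``.
    """
    out = binset.copy().reset_index(drop=True)
    out["raw_count"] = 0
    n_outside = 0
    for chrom, sub in alignments.groupby("chrom", sort=False):
        bins = out[out["chrom"] == chrom]
        if bins.empty:
            n_outside += len(sub)
            continue
        starts = bins["start"].to_numpy()
        ends = bins["end"].to_numpy()
        pos = np.sort(sub["start"].to_numpy())
        idx = np.searchsorted(starts, pos, side="right") - 1
        inside = (idx >= 0) & (pos < ends[np.clip(idx, 0, len(ends) - 1)])
        n_outside += int((~inside).sum())
        counts = np.bincount(idx[inside], minlength=len(bins))
        out.loc[bins.index, "raw_count"] += counts
    out.attrs["n_outside"] = n_outside
    return out


# ---------------------------------------------------------------- logR

def compute_logr(
    counts: pd.DataFrame,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    gc_min: float = DEFAULT_GC_MIN,
) -> pd.DataFrame:
    """Pseudocounted, GC-filtered log2 ratios versus the genome-wide mean.

    The mean in the denominator is taken over the retained (GC-passing)
    bins. Raises if the filter removes every bin.
    """
    if (counts["raw_count"] < 0).any():
        raise ValueError("raw counts must be >= 0")
    retained = counts[counts["gc"] >= gc_min].copy().reset_index(drop=True)
    if retained.empty:
        raise ValueError(f"all bins filtered at gc_min={gc_min}")
    adjusted = retained["raw_count"].to_numpy(dtype=float) + pseudocount
    retained["logr"] = np.log2(adjusted / adjusted.mean())
    return retained


# ---------------------------------------------------------------- loess

def loess_fit(
    x: np.ndarray,
    y: np.ndarray,
    span: float = 0.3,
    degree: int = 2,
    grid: int = 200,
) -> np.ndarray:
    """Locally weighted polynomial regression of y on x (tricube weights).

    For every evaluation point the nearest ``ceil(span * n)`` neighbors get
    tricube weights on scaled distance and a degree-``degree`` weighted
    polynomial is fitted. For n above the grid size the fit is evaluated on
    a quantile grid and interpolated, keeping the cost independent of n.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    k = max(degree + 2, int(np.ceil(span * n)))
    k = min(k, n)
    order = np.argsort(x)
    xs, ys = x[order], y[order]

    def fit_at(x0: float) -> float:
        lo = np.searchsorted(xs, x0)
        lo = max(0, min(lo - k // 2, n - k))
        xw, yw = xs[lo : lo + k], ys[lo : lo + k]
        d = np.abs(xw - x0)
        dmax = d.max()
        if dmax == 0:
            return float(yw.mean())
        w = (1 - (d / dmax) ** 3) ** 3
        X = np.vander(xw - x0, degree + 1, increasing=True)
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], yw * sw, rcond=None)
        return float(beta[0])

    if n <= grid:
        fitted_sorted = np.array([fit_at(v) for v in xs])
        fitted = np.empty(n)
        fitted[order] = fitted_sorted
        return fitted
    qs = np.quantile(xs, np.linspace(0, 1, grid))
    qs = np.unique(qs)
    fq = np.array([fit_at(v) for v in qs])
    return np.interp(x, qs, fq)


def gc_correct(
    track: pd.DataFrame,
    span: float = 0.3,
    degree: int = 2,
) -> pd.DataFrame:
    """Loess-correct logR against GC, then median-normalize genome-wide.

    corrected = logr - loess(gc) followed by subtraction of the genome-wide
    median, so the corrected track has median 0. A degenerate GC range
    (all bins equal) skips the fit and median-centres only, with a warning.
    """
    if len(track) < 30:
        raise ValueError("GC correction needs at least 30 retained bins")
    out = track.copy()
    gc = out["gc"].to_numpy(dtype=float)
    logr = out["logr"].to_numpy(dtype=float)
    if np.ptp(gc) == 0:
        warnings.warn("degenerate GC range; median-centring only")
        corrected = logr
    else:
        corrected = logr - loess_fit(gc, logr, span=span, degree=degree)
    corrected = corrected - np.median(corrected)
    out["logr"] = corrected
    return out


# ---------------------------------------------------------------- ploidy

def estimate_ploidy(
    track: pd.DataFrame,
    reference_region: tuple[str, int, int],
    reference_cn: int = 2,
) -> PloidyEstimate:
    """Anchor the average ploidy on a region of known copy number.

    Psi = reference_cn * 2^(-mean corrected logR over bins overlapping the
    region). Errors if the region overlaps no retained bin; fewer than 20
    overlapping bins triggers a warning (the anchor should be large).
    """
    chrom, start, end = reference_region
    sel = (
        (track["chrom"] == chrom)
        & (track["end"] > start)
        & (track["start"] < end)
    )
    sub = track[sel]
    if sub.empty:
        raise ValueError(f"reference region {reference_region} overlaps no bins")
    if len(sub) < 20:
        warnings.warn(
            f"reference region overlaps only {len(sub)} bins; ploidy may be noisy"
        )
    mean_logr = float(sub["logr"].mean())
    return PloidyEstimate(
        psi=reference_cn * 2.0 ** (-mean_logr),
        reference_region=reference_region,
        reference_cn=reference_cn,
    )


# ---------------------------------------------------------------- integer CN

def call_integer_cn(segments: pd.DataFrame, ploidy: PloidyEstimate) -> pd.DataFrame:
    """Per-segment continuous and integer copy number.

    cn_continuous = 2^mean_logR * Psi; cn_integer rounds half-up and is
    floored at 0.
    """
    out = segments.copy()
    cont = 2.0 ** out["mean"].to_numpy(dtype=float) * ploidy.psi
    out["cn_continuous"] = cont
    out["cn_integer"] = np.maximum(np.floor(cont + 0.5), 0).astype(int)
    return out


def single_cell_cn_profile(
    alignments: pd.DataFrame,
    binset: pd.DataFrame,
    reference_region: tuple[str, int, int],
    *,
    reference_cn: int = 2,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    gc_min: float = DEFAULT_GC_MIN,
    gamma: float = DEFAULT_GAMMA_SEQ,
    kmin: int = 1,
    span: float = 0.3,
    degree: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame, PloidyEstimate]:
    """Run the whole per-cell pipeline; returns (track, cn_segments, ploidy)."""
    counts = count_reads_in_bins(alignments, binset)
    track = compute_logr(counts, pseudocount=pseudocount, gc_min=gc_min)
    track = gc_correct(track, span=span, degree=degree)
    assert (track["gc"] >= gc_min).all(), "GC-filtered bin reached segmentation"
    segments = segment_track(track, SegmentationParams(gamma=gamma, kmin=kmin))
    ploidy = estimate_ploidy(track, reference_region, reference_cn=reference_cn)
    return track, call_integer_cn(segments, ploidy), ploidy


# ---------------------------------------------------------------- aCGH mode

def process_acgh_track(
    probes: pd.DataFrame,
    floor: float = DEFAULT_ACGH_FLOOR,
    params: SegmentationParams = SegmentationParams(
        gamma=DEFAULT_GAMMA_ACGH, kmin=DEFAULT_KMIN_ACGH
    ),
    gc_correct_flag: bool = False,
    span: float = 0.3,
    degree: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """aCGH-style processing of a probe log2 track.

    Values below ``floor`` are clamped to it; optional loess GC correction
    uses the probe ``gc`` column when present; finally the genome-wide mean
    is subtracted (zero-line recentring), so the processed track has mean
    exactly 0, and PCF segments each chromosome with the aCGH parameters
    (gamma = 60, kmin = 25 by default). Returns (processed probes,
    segments).
    """
    if not probes["pos"].is_monotonic_increasing:
        grouped = probes.groupby("chrom", sort=False)["pos"]
        if not all(s.is_monotonic_increasing for _, s in grouped):
            raise ValueError("probes must be sorted by position within chromosome")
    out = probes.copy().reset_index(drop=True)
    values = out["logr"].to_numpy(dtype=float)
    values = np.maximum(values, floor)
    if gc_correct_flag:
        if "gc" not in out.columns:
            warnings.warn("gc column missing; skipping aCGH GC correction")
        elif np.ptp(out["gc"].to_numpy()) > 0:
            values = values - loess_fit(
                out["gc"].to_numpy(dtype=float), values, span=span, degree=degree
            )
    values = values - values.mean()
    out["logr"] = values
    seg_in = pd.DataFrame(
        {
            "chrom": out["chrom"],
            "start": out["pos"],
            "end": out["pos"] + 1,
            "logr": out["logr"],
        }
    )
    segments = segment_track(seg_in, params)
    return out, segments
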