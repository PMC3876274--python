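"""Piecewise constant fitting (PCF) by exact penalized least squares.

Given an ordered numeric series y, PCF minimizes

    sum over segments of SSE(segment)  +  gamma * (number of breakpoints)

over all segmentations whose segments contain at least ``kmin`` points.
``gamma`` is the per-breakpoint penalty; larger values yield fewer, longer
segments. The minimizer is found by exact dynamic programming over segment
ends (prefix sums of y and y^2 make each candidate segment cost O(1), so the
whole fit is O(n^2)); this is affordable at the few-thousand-bin scale of
single-cell copy-number tracks and, unlike fast heuristics, is directly
checkable against exhaustive enumeration.

Ties are broken deterministically: among segmentations of equal objective,
fewer breakpoints win; among those, the lexicographically smallest
breakpoint sequence (leftmost breakpoints) wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

_TIE_RTOL = 1e-9


@dataclass(frozen=True)
class SegmentationParams:
    """Penalty ``gamma`` (>= 0) and minimum segment length ``kmin`` (>= 1)."""

    gamma: float = 25.0
    kmin: int = 1

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")
        if self.kmin < 1:
            raise ValueError(f"kmin must be >= 1, got {self.kmin}")


@dataclass
class PiecewiseFit:
    """A fitted segmentation of one series.

    ``breakpoints`` are the interior segment-start indices (0 < b < n,
    ascending); segment k covers ``[starts[k], starts[k+1])`` where
    ``starts = [0, *breakpoints]``.
    """

    n: int
    breakpoints: list[int]
    segment_means: np.ndarray
    objective: float
    segment_lengths: list[int] = field(default_factory=list)

    @property
    def starts(self) -> list[int]:
        return [0, *self.breakpoints]

    @property
    def ends(self) -> list[int]:
        return [*self.breakpoints, self.n]

    def fitted(self) -> np.ndarray:
        out = np.empty(self.n)
        for s, e, m in zip(self.starts, self.ends, self.segment_means):
            out[s:e] = m
        return out


def _prefix_sums(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    cs = np.zeros(len(y) + 1)
    cs2 = np.zeros(len(y) + 1)
    np.cumsum(y, out=cs[1:])
    np.cumsum(y * y, out=cs2[1:])
    return cs, cs2


def _segment_sse(cs: np.ndarray, cs2: np.ndarray, i, j) -> np.ndarray:
    n = j - i
    s = cs[j] - cs[i]
    return (cs2[j] - cs2[i]) - s * s / n


def _build_fit(y: np.ndarray, breakpoints: list[int], gamma: float) -> PiecewiseFit:
    starts = [0, *breakpoints]
    ends = [*breakpoints, len(y)]
    means = np.array([y[s:e].mean() for s, e in zip(starts, ends)])
    sse = sum(float(((y[s:e] - m) ** 2).sum()) for s, e, m in zip(starts, ends, means))
    return PiecewiseFit(
        n=len(y),
        breakpoints=list(breakpoints),
        segment_means=means,
        objective=sse + gamma * len(breakpoints),
        segment_lengths=[e - s for s, e in zip(starts, ends)],
    )


def pcf_segment(values, params: SegmentationParams) -> PiecewiseFit:
    """Exact global minimizer of the penalized least-squares segmentation.

    Raises ``ValueError`` on non-finite input or series shorter than ``kmin``.
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if not np.all(np.isfinite(y)):
        raise ValueError("values must be finite")
    n = len(y)
    kmin, gamma = params.kmin, params.gamma
    if n < kmin:
        raise ValueError(f"series length {n} < kmin {kmin}")

    cs, cs2 = _prefix_sums(y)
    inf = np.inf
    obj = np.full(n + 1, inf)
    nbp = np.full(n + 1, 0, dtype=int)
    parent = np.full(n + 1, -1, dtype=int)
    obj[0] = 0.0

    def bkps_of(j: int) -> tuple[int, ...]:
        out = []
        while j > 0:
            i = parent[j]
            if i > 0:
                out.append(i)
            j = i
        return tuple(reversed(out))

    for j in range(kmin, n + 1):
        i_cand = np.arange(0, j - kmin + 1)
        # segments may only start at 0 or at a reachable prefix end
        feasible = np.isfinite(obj[i_cand])
        if not feasible.any():
            continue
        i_cand = i_cand[feasible]
        cost = (
            obj[i_cand]
            + gamma * (i_cand > 0)
            + _segment_sse(cs, cs2, i_cand, j)
        )
        best = cost.min()
        tol = _TIE_RTOL * max(1.0, abs(best))
        tied = i_cand[cost <= best + tol]
        if len(tied) == 1:
            i_star = int(tied[0])
        else:
            cand_nbp = nbp[tied] + (tied > 0)
            tied = tied[cand_nbp == cand_nbp.min()]
            if len(tied) == 1:
                i_star = int(tied[0])
            else:  # rare: resolve by full breakpoint sequence
                seqs = {
                    int(i): bkps_of(int(i)) + ((int(i),) if i > 0 else ())
                    for i in tied
                }
                i_star = min(seqs, key=seqs.get)
        parent[j] = i_star
        obj[j] = obj[i_star] + gamma * (i_star > 0) + float(_segment_sse(cs, cs2, i_star, j))
        nbp[j] = nbp[i_star] + (i_star > 0)

    if not np.isfinite(obj[n]):
        raise ValueError("no admissible segmentation (check kmin)")
    return _build_fit(y, list(bkps_of(n)), gamma)


def segment_oracle(values, params: SegmentationParams) -> PiecewiseFit:
    """Exhaustive-enumeration reference for short series (n <= 15).

    Enumerates every admissible breakpoint subset and applies the same
    tie-breaking rule as :func:`pcf_segment`. Kept deliberately independent
    of the dynamic program so the two can cross-validate each other.
    """
    y = np.asarray(values, dtype=float)
    n = len(y)
    if n > 15:
        raise ValueError("oracle refuses series longer than 15 points")
    if n < params.kmin:
        raise ValueError(f"series length {n} < kmin {params.kmin}")

    def admissible(bkps: tuple[int, ...]) -> bool:
        edges = [0, *bkps, n]
        return all(e - s >= params.kmin for s, e in zip(edges, edges[1:]))

    def objective(bkps: tuple[int, ...]) -> float:
        edges = [0, *bkps, n]
        sse = 0.0
        for s, e in zip(edges, edges[1:]):
            seg = y[s:e]
            sse += float(((seg - seg.mean()) ** 2).sum())
        return sse + params.gamma * len(bkps)

    candidates: list[tuple[float, int, tuple[int, ...]]] = []
    for k in range(0, n):
        for bkps in combinations(range(1, n), k):
            if admissible(bkps):
                candidates.append((objective(bkps), k, bkps))
    best_obj = min(c[0] for c in candidates)
    tol = _TIE_RTOL * max(1.0, abs(best_obj))
    tied = [c for c in candidates if c[0] <= best_obj + tol]
    min_k = min(c[1] for c in tied)
    tied = [c for c in tied if c[1] == min_k]
    _, _, bkps = min(tied, key=lambda c: c[2])
    return _build_fit(y, list(bkps), params.gamma)


def segment_track(
    track: pd.DataFrame,
    params: SegmentationParams,
    value_column: str = "logr",
) -> pd.DataFrame:
    """Segment an ordered per-bin track independently per chromosome.

    ``track`` needs columns ``chrom, start, end`` plus ``value_column`` and
    must be sorted by (chrom, position). Returns one row per segment with
    genomic extent (first bin start to last bin end), point count and mean.
    Chromosomes with fewer than ``kmin`` bins are emitted as a single
    unsegmented segment with a warning.
    """
    rows = []
    for chrom in track["chrom"].unique():
        sub = track.loc[track["chrom"] == chrom]
        y = sub[value_column].to_numpy(dtype=float)
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if len(y) < params.kmin:
            warnings.warn(
                f"{chrom}: {len(y)} bins < kmin {params.kmin}; left unsegmented"
            )
            rows.append((chrom, int(starts[0]), int(ends[-1]), len(y), float(y.mean())))
            continue
        fit = pcf_segment(y, params)
        for s, e, m in zip(fit.starts, fit.ends, fit.segment_means):
            rows.append((chrom, int(starts[s]), int(ends[e - 1]), e - s, float(m)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_bins", "mean"])
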