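"""Digital SNP B-allele fractions and per-segment allelic state.

BAF at a known SNP is the fraction of reads carrying the alternate allele
(alt-allele convention). Single-cell WGA suffers allele dropout, so a site
is *informative* only when covered by at least eight reads, and allelic
state is called per copy-number segment from the fraction of informative
sites at extreme BAF rather than from individual sites:

* **LOH** — at least 90% of >= 10 informative sites have BAF <= 0.15 or
  >= 0.85 (only one allele observed);
* **cnLOH** — the LOH criterion holds and the segment's integer copy
  number is 2 (dosage-invisible loss of heterozygosity);
* **imbalanced** — mean mirrored BAF max(b, 1-b) above 0.65 without LOH;
* **balanced** — otherwise; segments with < 10 informative sites are
  ``uncalled``.

All thresholds are package choices exposed in :class:`AllelicStateThresholds`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_MIN_DEPTH = 8


@dataclass(frozen=True)
class AllelicStateThresholds:
    low: float = 0.15
    high: float = 0.85
    loh_site_fraction: float = 0.9
    min_sites: int = 10
    imbalance_mirrored_baf: float = 0.65


def compute_baf(allele_counts: pd.DataFrame, min_depth: int = DEFAULT_MIN_DEPTH) -> pd.DataFrame:
    """Per-site BAF = alt / (ref + alt), only at sites with depth >= min_depth.

    Input columns: chrom, pos (1-based), ref_count, alt_count. Adds
    ``depth``, ``informative`` and ``baf`` (NaN where uninformative).
    """
    if (allele_counts[["ref_count", "alt_count"]] < 0).any().any():
        raise ValueError("allele counts must be >= 0")
    out = allele_counts.copy()
    depth = out["ref_count"] + out["alt_count"]
    out["depth"] = depth
    out["informative"] = depth >= min_depth
    with np.errstate(invalid="ignore"):
        baf = out["alt_count"] / depth
    out["baf"] = baf.where(out["informative"], np.nan)
    return out


def classify_allelic_state(
    baf_track: pd.DataFrame,
    cn_segments: pd.DataFrame,
    thresholds: AllelicStateThresholds = AllelicStateThresholds(),
) -> pd.DataFrame:
    """Per-segment allelic state from informative-site BAF fractions.

    ``cn_segments`` needs chrom, start, end (0-based half-open) and
    ``cn_integer``; sites are matched by 0-based position (pos - 1).
    Returns one row per segment with n_informative, loh_fraction,
    mean_mirrored_baf and state.
    """
    t = thresholds
    rows = []
    for seg in cn_segments.itertuples(index=False):
        sel = (
            (baf_track["chrom"] == seg.chrom)
            & (baf_track["pos"] - 1 >= seg.start)
            & (baf_track["pos"] - 1 < seg.end)
            & baf_track["informative"]
        )
        baf = baf_track.loc[sel, "baf"].to_numpy(dtype=float)
        n = len(baf)
        if n == 0:
            loh_fraction = np.nan
            mirrored = np.nan
        else:
            extreme = (baf <= t.low) | (baf >= t.high)
            loh_fraction = float(extreme.mean())
            mirrored = float(np.maximum(baf, 1 - baf).mean())
        if n < t.min_sites:
            state = "uncalled"
        elif loh_fraction >= t.loh_site_fraction:
            state = "cnLOH" if int(seg.cn_integer) == 2 else "LOH"
        elif mirrored > t.imbalance_mirrored_baf:
            state = "imbalanced"
        else:
            state = "balanced"
        rows.append(
            (seg.chrom, seg.start, seg.end, int(seg.cn_integer), n, loh_fraction, mirrored, state)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "cn_integer",
            "n_informative", "loh_fraction", "mean_mirrored_baf", "state",
        ],
    )
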