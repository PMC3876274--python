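"""Single-cell versus primary-tumor copy-number concordance.

Profiles are reduced to a gain / neutral / loss *status track* relative to
a baseline copy number (2 for near-diploid tumors), and concordance is the
base-pair-weighted fraction of the jointly covered genome on which the two
tracks agree in status. Non-neutral events are further matched between the
cell and the primary tumor's clone structure to label each one
clonal-shared, subclonal-shared or private to either side — the comparison
that distinguishes a cell descending from the dominant clone from one
descending from a minor subclone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic_data import TumorTruth, clone_cn_tracks


@dataclass
class ConcordanceReport:
    concordant_bp: int
    compared_bp: int
    per_chromosome: pd.DataFrame = field(repr=False, default=None)

    @property
    def concordance(self) -> float:
        return self.concordant_bp / self.compared_bp if self.compared_bp else float("nan")


def status_track(cn_profile: pd.DataFrame, baseline: int = 2) -> pd.DataFrame:
    """Gain/neutral/loss status per window by integer comparison to baseline."""
    out = cn_profile[["chrom", "start", "end"]].copy()
    cn = cn_profile["cn_integer"].to_numpy()
    out["status"] = np.where(cn > baseline, "gain", np.where(cn < baseline, "loss", "neutral"))
    return out


def _atomic_overlap(a: pd.DataFrame, b: pd.DataFrame, chrom: str):
    sa = a[a["chrom"] == chrom]
    sb = b[b["chrom"] == chrom]
    if sa.empty or sb.empty:
        return None
    edges = np.unique(
        np.concatenate(
            [sa["start"], sa["end"], sb["start"], sb["end"]]
        )
    )
    lo = max(sa["start"].min(), sb["start"].min())
    hi = min(sa["end"].max(), sb["end"].max())
    edges = edges[(edges >= lo) & (edges <= hi)]
    if len(edges) < 2:
        return None
    starts, ends = edges[:-1], edges[1:]

    def lookup(sub: pd.DataFrame) -> np.ndarray:
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        st = sub["status"].to_numpy()
        idx = np.searchsorted(s, starts, side="right") - 1
        ok = (idx >= 0) & (starts < e[np.clip(idx, 0, len(e) - 1)])
        res = np.full(len(starts), None, dtype=object)
        res[ok] = st[idx[ok]]
        return res

    return starts, ends, lookup(sa), lookup(sb)


def concordance(a: pd.DataFrame, b: pd.DataFrame) -> ConcordanceReport:
    """Base-pair-weighted status agreement over the jointly covered genome.

    Windows are intersected per chromosome; only base pairs where both
    tracks define a status are compared. Errors if the tracks share no
    coordinates at all.
    """
    shared = sorted(set(a["chrom"]) & set(b["chrom"]))
    rows = []
    concordant = compared = 0
    for chrom in shared:
        res = _atomic_overlap(a, b, chrom)
        if res is None:
            continue
        starts, ends, st_a, st_b = res
        width = ends - starts
        both = (st_a != None) & (st_b != None)  # noqa: E711
        agree = both & (st_a == st_b)
        c_bp = int(width[agree].sum())
        t_bp = int(width[both].sum())
        concordant += c_bp
        compared += t_bp
        rows.append((chrom, c_bp, t_bp, c_bp / t_bp if t_bp else np.nan))
    if compared == 0:
        raise ValueError("tracks share no comparable coordinates")
    per_chrom = pd.DataFrame(
        rows, columns=["chrom", "concordant_bp", "compared_bp", "concordance"]
    )
    return ConcordanceReport(
        concordant_bp=concordant, compared_bp=compared, per_chromosome=per_chrom
    )


# ---------------------------------------------------------------- events

def _merge_status_events(track: pd.DataFrame) -> pd.DataFrame:
    """Merge adjacent same-status windows into events; drop neutral runs."""
    rows = []
    for chrom in track["chrom"].unique():
        sub = track[track["chrom"] == chrom].sort_values("start")
        cur = None
        for w in sub.itertuples(index=False):
            if cur is not None and w.status == cur[3] and w.start == cur[2]:
                cur[2] = w.end
                continue
            if cur is not None and cur[3] != "neutral":
                rows.append(tuple(cur))
            cur = [chrom, w.start, w.end, w.status]
        if cur is not None and cur[3] != "neutral":
            rows.append(tuple(cur))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "status"])


def primary_events_from_truth(truth: TumorTruth) -> pd.DataFrame:
    """Dosage events of the primary tumor with their aggregate clone fraction.

    Per clone, the total-CN track is reduced to gain/loss runs versus
    diploid; identical (chrom, interval, direction) events across clones
    are pooled and their clone fractions summed. Fractions are expressed
    relative to the tumor cell content (normal cells excluded). Copy-neutral
    events (cnLOH) carry no dosage signal and do not appear.
    """
    tumor_total = sum(c.fraction for c in truth.clones)
    pooled: dict[tuple, float] = {}
    for clone in truth.clones:
        tr = clone_cn_tracks(truth, clone.name)
        tr = tr.assign(cn_integer=tr["cn_a"] + tr["cn_b"])
        ev = _merge_status_events(status_track(tr, baseline=2))
        for e in ev.itertuples(index=False):
            key = (e.chrom, e.start, e.end, e.status)
            pooled[key] = pooled.get(key, 0.0) + clone.fraction / tumor_total
    rows = [(c, s, e, st, f) for (c, s, e, st), f in pooled.items()]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "status", "clone_fraction"])


def _jaccard(s1, e1, s2, e2) -> float:
    inter = max(0, min(e1, e2) - max(s1, s2))
    union = (e1 - s1) + (e2 - s2) - inter
    return inter / union if union else 0.0


def classify_events(
    dtc_profile: pd.DataFrame,
    primary: TumorTruth | pd.DataFrame,
    min_jaccard: float = 0.5,
    subclonal_max_fraction: float = 0.8,
    baseline: int = 2,
) -> pd.DataFrame:
    """Label each non-neutral event clonal-shared / subclonal-shared / private.

    ``dtc_profile`` is an integer-CN profile (chrom, start, end,
    cn_integer); ``primary`` is either a :class:`TumorTruth` or an event
    table with columns chrom, start, end, status, clone_fraction. A cell
    event matches a same-direction primary event when their interval
    Jaccard index reaches ``min_jaccard``; matched events are
    clonal-shared when the primary clone fraction is at least
    ``subclonal_max_fraction``, otherwise subclonal-shared. Unmatched cell
    events are dtc-private; primary events never matched are
    primary-private.
    """
    if isinstance(primary, TumorTruth):
        primary_events = primary_events_from_truth(primary)
    else:
        primary_events = primary
    dtc_events = _merge_status_events(status_track(dtc_profile, baseline=baseline))
    matched_primary = np.zeros(len(primary_events), dtype=bool)
    rows = []
    for ev in dtc_events.itertuples(index=False):
        best_j, best_i = 0.0, -1
        for i, pe in enumerate(primary_events.itertuples(index=False)):
            if pe.chrom != ev.chrom or pe.status != ev.status:
                continue
            j = _jaccard(ev.start, ev.end, pe.start, pe.end)
            if j > best_j:
                best_j, best_i = j, i
        if best_i >= 0 and best_j >= min_jaccard:
            matched_primary[best_i] = True
            frac = float(primary_events.iloc[best_i]["clone_fraction"])
            label = "clonal-shared" if frac >= subclonal_max_fraction else "subclonal-shared"
            rows.append((ev.chrom, ev.start, ev.end, ev.status, label, best_j, frac))
        else:
            rows.append((ev.chrom, ev.start, ev.end, ev.status, "dtc-private", best_j, np.nan))
    for i, pe in enumerate(primary_events.itertuples(index=False)):
        if not matched_primary[i]:
            rows.append(
                (pe.chrom, pe.start, pe.end, pe.status, "primary-private", np.nan,
                 float(pe.clone_fraction))
            )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "status", "label", "jaccard", "clone_fraction"],
    )
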