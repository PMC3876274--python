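"""Synthetic tumor genomes, single-cell WGA reads, SNP counts and bulk tracks.

This module generates every input the copy-number pipeline consumes, with
the statistical structure the analysis assumes:

* a small multi-chromosome genome with a smoothly varying GC landscape and
  optional planted exact duplications (which create unmappable regions);
* a clonal/subclonal tumor truth: per-clone allele-specific copy-number
  events (whole-arm, focal, copy-neutral LOH, chromothripsis-like shatter);
* single-cell reads from one clone, emulating PCR-based whole-genome
  amplification: each chromosomal copy is partitioned into amplicons whose
  sampling weight carries a gamma-distributed (or lognormal) multiplier,
  a log-linear GC bias acts on coverage, a fraction of alignments are exact
  PCR duplicates, and every raw read begins with a fixed 32-base WGA
  adapter so that reads are 69 bases after trimming;
* per-SNP ref/alt read counts (digital BAF input) honoring allele-specific
  copy number, with optional WGA overdispersion and sequencing error;
* a bulk "primary tumor" probe track mixing clones by fraction (logR and
  BAF with Gaussian noise), standing in for SNP-CGH of the primary.

All randomness flows from explicit integer seeds; identical spec + seed
gives byte-identical outputs. A single cell is a pure clone: clone
fractions matter only for the bulk primary track.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._io import revcomp

#: Fixed WGA adapter contaminating the 5' end of every raw read (32 bases).
DEFAULT_ADAPTER = "TGTGTTGGGTGTGTTTGGCAGCGGTAACGATC"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# =====================================================================
# Genome simulation
# =====================================================================

@dataclass
class SimGenomeSpec:
    """Reference-genome recipe: sizes, GC landscape, planted duplications.

    ``gc_landscape`` lists (position, gc) control points shared by all
    chromosomes; realized GC follows the linear interpolation of these
    points. Positions <= 1 are read as fractions of the chromosome length,
    larger values as base-pair coordinates. ``planted_duplications`` are exact
    copies: (src_chrom, src_start, src_end, dst_chrom, dst_start), the
    destination block being overwritten (0-based half-open).
    """

    n_chroms: int = 2
    chrom_length: int = 1_000_000
    # isochore-like oscillation: GC varies on a much finer scale than the
    # copy-number events planted on top, as in real genomes, so loess
    # GC correction cannot absorb broad dosage signal
    gc_landscape: Sequence[tuple[float, float]] = (
        (0.0, 0.42), (0.1, 0.55), (0.2, 0.38), (0.3, 0.52), (0.4, 0.44),
        (0.5, 0.56), (0.6, 0.40), (0.7, 0.53), (0.8, 0.38), (0.9, 0.50),
        (1.0, 0.45),
    )
    planted_duplications: Sequence[tuple[str, int, int, str, int]] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chrom_length <= 0:
            raise ValueError("chrom_length must be > 0")
        for _, g in self.gc_landscape:
            if not 0.0 <= g <= 1.0:
                raise ValueError(f"gc control value {g} outside [0,1]")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]


def _gc_target(spec: SimGenomeSpec, n: int) -> np.ndarray:
    pts = sorted(spec.gc_landscape)
    xs = np.array([min(p, n - 1) if p > 1 else p * (n - 1) for p, _ in pts], dtype=float)
    # control positions <= 1 are interpreted as fractions of the chromosome
    ys = np.array([g for _, g in pts], dtype=float)
    return np.interp(np.arange(n), xs, ys)


def simulate_genome(spec: SimGenomeSpec) -> tuple[dict[str, str], pd.DataFrame]:
    """Generate sequences plus a 10 kb-window GC truth track.

    Bases are drawn per position: G/C with the local target probability,
    A/T otherwise, so realized windowed GC tracks the control landscape.
    Planted duplications are applied afterwards as exact block copies;
    overlapping source/target blocks are rejected.
    """
    lengths = {c: spec.chrom_length for c in spec.chrom_names}
    for sc, s, e, dc, d in spec.planted_duplications:
        if not (0 <= s < e <= lengths[sc]) or not (0 <= d <= lengths[dc] - (e - s)):
            raise ValueError("duplication interval outside chromosome")
        if sc == dc and not (d + (e - s) <= s or e <= d):
            raise ValueError("duplication source and target overlap")
    rng = np.random.default_rng(spec.seed)
    genome: dict[str, str] = {}
    arrays: dict[str, np.ndarray] = {}
    for chrom in spec.chrom_names:
        n = spec.chrom_length
        target = _gc_target(spec, n)
        is_gc = rng.random(n) < target
        pick = rng.integers(0, 2, size=n)
        codes = np.where(is_gc, 1 + pick, np.where(pick == 0, 0, 3)).astype(np.uint8)
        arrays[chrom] = _BASES[codes]
    for sc, s, e, dc, d in spec.planted_duplications:
        arrays[dc][d : d + (e - s)] = arrays[sc][s:e]
    gc_rows = []
    win = 10_000
    for chrom in spec.chrom_names:
        arr = arrays[chrom]
        genome[chrom] = arr.tobytes().decode("ascii")
        gc = np.isin(arr, _BASES[1:3])
        for w0 in range(0, len(arr) - win + 1, win):
            gc_rows.append((chrom, w0, w0 + win, float(gc[w0 : w0 + win].mean())))
    gc_truth = pd.DataFrame(gc_rows, columns=["chrom", "start", "end", "gc"])
    return genome, gc_truth


# =====================================================================
# Tumor truth
# =====================================================================

@dataclass(frozen=True)
class CnEvent:
    """One allele-specific copy-number event (0-based half-open interval).

    ``allele`` is 'A', 'B' or 'both'; ``delta`` the signed copy change per
    targeted allele. For ``kind='cnLOH'`` the copies of the lost allele are
    transferred to the retained one (``allele`` names the retained allele,
    ``delta`` is ignored), so total copy number is unchanged.
    """

    chrom: str
    start: int
    end: int
    allele: str = "both"
    delta: int = 0
    kind: str = "focal"


@dataclass
class Clone:
    name: str
    fraction: float
    events: list[CnEvent] = field(default_factory=list)


@dataclass
class TumorTruth:
    """Clone mixture with allele-specific CN events; the simulation's and
    the comparator's ground truth."""

    clones: list[Clone]
    chrom_lengths: dict[str, int]
    normal_fraction: float = 0.0

    def __post_init__(self) -> None:
        total = sum(c.fraction for c in self.clones) + self.normal_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"clone + normal fractions sum to {total}, not 1")
        for c in self.clones:
            if not 0.0 <= c.fraction <= 1.0:
                raise ValueError(f"clone fraction {c.fraction} outside [0,1]")

    def clone(self, name: str) -> Clone:
        for c in self.clones:
            if c.name == name:
                return c
        raise KeyError(f"no clone named {name!r}")


def clone_cn_tracks(truth: TumorTruth, clone_name: str) -> pd.DataFrame:
    """Piecewise-constant allele-specific CN of one clone.

    Returns columns ``chrom, start, end, cn_a, cn_b`` tiling each
    chromosome. Raises if any event drives an allele below zero copies.
    """
    clone = truth.clone(clone_name)
    rows = []
    for chrom, length in truth.chrom_lengths.items():
        cuts = {0, length}
        for ev in clone.events:
            if ev.chrom == chrom:
                if not (0 <= ev.start < ev.end <= length):
                    raise ValueError(f"event interval invalid on {chrom}: {ev}")
                cuts.update((ev.start, ev.end))
        edges = sorted(cuts)
        cn_a = np.ones(len(edges) - 1, dtype=int)
        cn_b = np.ones(len(edges) - 1, dtype=int)
        starts = np.array(edges[:-1])
        for ev in clone.events:
            if ev.chrom != chrom:
                continue
            sel = (starts >= ev.start) & (starts < ev.end)
            if ev.kind == "cnLOH":
                retained, lost = (cn_a, cn_b) if ev.allele == "A" else (cn_b, cn_a)
                retained[sel] += lost[sel]
                lost[sel] = 0
            elif ev.allele == "A":
                cn_a[sel] += ev.delta
            elif ev.allele == "B":
                cn_b[sel] += ev.delta
            else:
                cn_a[sel] += ev.delta
                cn_b[sel] += ev.delta
        if (cn_a < 0).any() or (cn_b < 0).any():
            raise ValueError(f"events drive an allele below 0 copies on {chrom}")
        for s, e, a, b in zip(edges[:-1], edges[1:], cn_a, cn_b):
            rows.append((chrom, s, e, int(a), int(b)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "cn_a", "cn_b"])


def expected_bulk_cn(truth: TumorTruth, chrom: str, pos: int) -> tuple[float, float]:
    """Clone-fraction-weighted (total CN, allele-B CN) at one position."""
    tot = 2.0 * truth.normal_fraction
    b = 1.0 * truth.normal_fraction
    for clone in truth.clones:
        tracks = clone_cn_tracks(truth, clone.name)
        sub = tracks[(tracks["chrom"] == chrom) & (tracks["start"] <= pos) & (tracks["end"] > pos)]
        row = sub.iloc[0]
        tot += clone.fraction * (row.cn_a + row.cn_b)
        b += clone.fraction * row.cn_b
    return tot, b


def simulate_tumor_truth(
    chrom_lengths: Mapping[str, int],
    event_plan: Sequence[Clone],
    seed: int = 0,
    shatter_pieces: tuple[int, int] = (8, 16),
) -> TumorTruth:
    """Materialize a clone plan into a validated :class:`TumorTruth`.

    Events of kind ``'shatter'`` are expanded into an oscillating run of
    focal one-copy gains/losses on alternating pieces of the interval
    (a chromothripsis-like pattern); all other events pass through. The
    result is validated by deriving every clone's CN track.
    """
    rng = np.random.default_rng(seed)
    clones = []
    for clone in event_plan:
        events: list[CnEvent] = []
        for ev in clone.events:
            if ev.kind != "shatter":
                events.append(ev)
                continue
            n_pieces = int(rng.integers(shatter_pieces[0], shatter_pieces[1] + 1))
            edges = np.sort(
                rng.choice(
                    np.arange(ev.start + 1, ev.end), size=n_pieces - 1, replace=False
                )
            )
            edges = np.concatenate([[ev.start], edges, [ev.end]])
            for i in range(n_pieces):
                if i % 2 == 0:
                    continue  # alternate: even pieces stay at baseline
                delta = 1 if (i // 2) % 2 == 0 else -1
                events.append(
                    CnEvent(ev.chrom, int(edges[i]), int(edges[i + 1]), "A", delta, "shatter")
                )
        clones.append(Clone(clone.name, clone.fraction, events))
    truth = TumorTruth(clones=clones, chrom_lengths=dict(chrom_lengths))
    for c in truth.clones:
        clone_cn_tracks(truth, c.name)  # validates non-negative CN
    return truth


# ------------------------------------------------ truth (de)serialization

def truth_to_table(truth: TumorTruth) -> pd.DataFrame:
    rows = []
    for clone in truth.clones:
        for ev in clone.events:
            rows.append(
                (ev.chrom, ev.start, ev.end, clone.name, clone.fraction,
                 ev.allele, ev.delta, ev.kind)
            )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "clone", "fraction", "allele", "delta", "kind"],
    )


def write_truth_bed(truth: TumorTruth, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"#normal_fraction={truth.normal_fraction!r}\n")
        for chrom, length in truth.chrom_lengths.items():
            fh.write(f"#chrom={chrom},length={length}\n")
        fh.write("#chrom\tstart\tend\tclone\tfraction\tallele\tdelta\tkind\n")
        for row in truth_to_table(truth).itertuples(index=False):
            fh.write("\t".join(str(v) for v in row) + "\n")


def read_truth_bed(path: str) -> TumorTruth:
    normal_fraction = 0.0
    chrom_lengths: dict[str, int] = {}
    clones: dict[str, Clone] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#normal_fraction="):
                normal_fraction = float(line.split("=", 1)[1])
                continue
            if line.startswith("#chrom="):
                body = line[1:]
                parts = dict(p.split("=") for p in body.split(","))
                chrom_lengths[parts["chrom"]] = int(parts["length"])
                continue
            if line.startswith("#") or not line:
                continue
            chrom, s, e, name, frac, allele, delta, kind = line.split("\t")
            clone = clones.setdefault(name, Clone(name, float(frac)))
            clone.events.append(CnEvent(chrom, int(s), int(e), allele, int(delta), kind))
    return TumorTruth(
        clones=list(clones.values()),
        chrom_lengths=chrom_lengths,
        normal_fraction=normal_fraction,
    )


# =====================================================================
# Single-cell WGA read simulation
# =====================================================================

@dataclass
class ReadSimSpec:
    """WGA sequencing model for one cell.

    Per-amplicon multipliers are Gamma(1/d, d) with d =
    ``amplification_dispersion`` (mean 1, variance d); ``noise_model``
    'lognormal' swaps in a lognormal of matching mean/variance. GC bias
    multiplies sampling weight by exp(gc_bias_coeff * (gc - genome mean
    gc)). ``duplicate_rate`` of the emitted alignments are exact copies of
    earlier ones (PCR duplicates).
    """

    n_reads: int = 100_000
    read_length_raw: int = 101
    adapter_prefix: str = DEFAULT_ADAPTER
    amplicon_length_mean: float = 2_000.0
    amplicon_length_sd: float = 500.0
    amplification_dispersion: float = 0.15
    gc_bias_coeff: float = 0.4
    duplicate_rate: float = 0.05
    sequencing_error_rate: float = 0.0
    noise_model: str = "gamma"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("duplicate_rate", "sequencing_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        if self.read_length_raw <= len(self.adapter_prefix):
            raise ValueError("read_length_raw must exceed the adapter length")

    @property
    def read_length(self) -> int:
        """Aligned read length after adapter trimming (69 by default)."""
        return self.read_length_raw - len(self.adapter_prefix)


def _amplicon_multipliers(rng, n: int, spec: ReadSimSpec) -> np.ndarray:
    d = spec.amplification_dispersion
    if d <= 0:
        return np.ones(n)
    if spec.noise_model == "lognormal":
        sigma2 = np.log1p(d)
        return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=n)
    return rng.gamma(shape=1.0 / d, scale=d, size=n)


def simulate_cell_reads(
    genome: Mapping[str, str],
    truth: TumorTruth,
    clone_id: str,
    spec: ReadSimSpec,
) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Raw FASTQ reads plus true alignments for one single cell (pure clone).

    Every chromosomal copy (level l of the total-CN track) is partitioned
    into amplicons; reads start uniformly within an amplicon, with amplicon
    weight = eligible length x amplification multiplier x GC factor, so the
    expected bin count is proportional to local total CN times the GC-bias
    factor. Returns ``(reads, alignments)`` where reads are (name, seq,
    qual) with the adapter prefix attached and alignments carry the true
    (0-based leftmost) position and strand of the trimmed read.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.read_length
    tracks = clone_cn_tracks(truth, clone_id)

    gc_prefix: dict[str, np.ndarray] = {}
    gc_total, base_total = 0, 0
    for chrom, seq in genome.items():
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        gcmask = (arr == ord("G")) | (arr == ord("C"))
        p = np.zeros(len(arr) + 1, dtype=np.int64)
        np.cumsum(gcmask, out=p[1:])
        gc_prefix[chrom] = p
        gc_total += int(p[-1])
        base_total += len(arr)
    mean_gc = gc_total / max(base_total, 1)

    amp_chrom: list[str] = []
    amp_start: list[int] = []
    amp_end: list[int] = []
    for chrom in truth.chrom_lengths:
        sub = tracks[tracks["chrom"] == chrom]
        total_cn = (sub["cn_a"] + sub["cn_b"]).to_numpy()
        max_cn = int(total_cn.max(initial=0))
        for level in range(1, max_cn + 1):
            present = sub[total_cn >= level]
            for row in present.itertuples(index=False):
                pos = row.start
                while pos < row.end:
                    ln = max(
                        L + 1,
                        int(rng.normal(spec.amplicon_length_mean, spec.amplicon_length_sd)),
                    )
                    end = min(pos + ln, row.end)
                    amp_chrom.append(chrom)
                    amp_start.append(pos)
                    amp_end.append(end)
                    pos = end
    amp_start_a = np.array(amp_start, dtype=np.int64)
    amp_end_a = np.array(amp_end, dtype=np.int64)
    eligible = np.maximum(amp_end_a - amp_start_a - L + 1, 0)

    mult = _amplicon_multipliers(rng, len(amp_start_a), spec)
    gc_amp = np.array(
        [
            (gc_prefix[c][e] - gc_prefix[c][s]) / max(e - s, 1)
            for c, s, e in zip(amp_chrom, amp_start_a, amp_end_a)
        ]
    )
    weight = eligible * mult * np.exp(spec.gc_bias_coeff * (gc_amp - mean_gc))

    if spec.n_reads == 0 or weight.sum() == 0:
        empty = pd.DataFrame(columns=["qname", "chrom", "start", "strand"])
        return [], empty

    n_dup = int(round(spec.n_reads * spec.duplicate_rate))
    n_unique = spec.n_reads - n_dup
    picks = rng.choice(len(weight), size=n_unique, p=weight / weight.sum())
    offsets = (rng.random(n_unique) * eligible[picks]).astype(np.int64)
    starts = amp_start_a[picks] + offsets
    strands = np.where(rng.random(n_unique) < 0.5, "+", "-")
    chroms = np.array(amp_chrom, dtype=object)[picks]

    if n_dup > 0:
        dup_of = rng.integers(0, n_unique, size=n_dup)
        starts = np.concatenate([starts, starts[dup_of]])
        strands = np.concatenate([strands, strands[dup_of]])
        chroms = np.concatenate([chroms, chroms[dup_of]])
    order = rng.permutation(len(starts))
    starts, strands, chroms = starts[order], strands[order], chroms[order]

    reads: list[tuple[str, str, str]] = []
    qual = "I" * spec.read_length_raw
    err = spec.sequencing_error_rate
    rows = []
    for i, (c, s, st) in enumerate(zip(chroms, starts, strands)):
        name = f"{clone_id}_read{i:07d}"
        frag = genome[c][s : s + L]
        if st == "-":
            frag = revcomp(frag)
        if err > 0:
            frag = _add_errors(rng, frag, err)
        reads.append((name, spec.adapter_prefix + frag, qual))
        rows.append((name, c, int(s), st))
    alignments = pd.DataFrame(rows, columns=["qname", "chrom", "start", "strand"])
    return reads, alignments


def _add_errors(rng, seq: str, rate: float) -> str:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        choices = [b for b in b"ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode("ascii")


# =====================================================================
# SNP panel and allele counts
# =====================================================================

@dataclass
class SnpPanel:
    """Known heterozygous-capable SNP sites with phased germline bases.

    ``sites`` columns: chrom, pos (1-based, VCF convention), ref, alt,
    base_a, base_b (the germline base carried by haplotype A / B).
    """

    sites: pd.DataFrame

    def __post_init__(self) -> None:
        dup = self.sites.duplicated(subset=["chrom", "pos"])
        if dup.any():
            raise ValueError("SNP positions must be unique per chromosome")


@dataclass
class SnpDepthSpec:
    mean_depth: float = 15.0
    wga_dispersion: float = 0.0  # beta-binomial overdispersion rho in [0,1)
    error_rate: float = 0.0
    seed: int = 0


def make_snp_panel(
    genome: Mapping[str, str],
    n_sites: int,
    het_fraction: float = 0.6,
    seed: int = 0,
) -> SnpPanel:
    """Draw a random panel; het sites carry the alt base on haplotype B."""
    rng = np.random.default_rng(seed)
    rows = []
    chroms = list(genome.keys())
    lengths = np.array([len(genome[c]) for c in chroms], dtype=float)
    per = rng.multinomial(n_sites, lengths / lengths.sum())
    for chrom, k in zip(chroms, per):
        pos = np.sort(rng.choice(len(genome[chrom]), size=min(k, len(genome[chrom])), replace=False))
        for p in pos:
            ref = genome[chrom][p]
            if ref not in "ACGT":
                continue
            alt = rng.choice([b for b in "ACGT" if b != ref])
            u = rng.random()
            if u < het_fraction:
                base_a, base_b = ref, alt
            elif u < het_fraction + (1 - het_fraction) / 2:
                base_a = base_b = ref
            else:
                base_a = base_b = alt
            rows.append((chrom, int(p) + 1, ref, alt, base_a, base_b))
    return SnpPanel(
        pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "base_a", "base_b"])
    )


def simulate_snp_counts(
    truth: TumorTruth,
    clone_id: str,
    panel: SnpPanel,
    depth_spec: SnpDepthSpec,
) -> pd.DataFrame:
    """Per-site ref/alt read counts for one cell.

    Site depth ~ Poisson(mean_depth * totalCN / 2); alt reads ~
    Binomial(depth, alt-carrying CN / total CN), beta-binomial when
    ``wga_dispersion`` > 0. Sites in CN-0 regions record depth 0; a deleted
    allele contributes no reads.
    """
    rng = np.random.default_rng(depth_spec.seed)
    tracks = clone_cn_tracks(truth, clone_id)
    out = []
    for chrom in panel.sites["chrom"].unique():
        sub = panel.sites[panel.sites["chrom"] == chrom]
        tr = tracks[tracks["chrom"] == chrom]
        starts = tr["start"].to_numpy()
        idx = np.searchsorted(starts, sub["pos"].to_numpy() - 1, side="right") - 1
        cn_a = tr["cn_a"].to_numpy()[idx]
        cn_b = tr["cn_b"].to_numpy()[idx]
        total = cn_a + cn_b
        for (row, a, b, tot) in zip(sub.itertuples(index=False), cn_a, cn_b, total):
            if tot == 0:
                out.append((row.chrom, row.pos, row.ref, row.alt, 0, 0))
                continue
            depth = int(rng.poisson(depth_spec.mean_depth * tot / 2.0))
            p_alt = (a * (row.base_a == row.alt) + b * (row.base_b == row.alt)) / tot
            e = depth_spec.error_rate
            p_alt = p_alt * (1 - e) + (1 - p_alt) * e
            rho = depth_spec.wga_dispersion
            if rho > 0 and 0 < p_alt < 1:
                conc = (1 - rho) / rho
                p_alt = rng.beta(p_alt * conc, (1 - p_alt) * conc)
            alt = int(rng.binomial(depth, p_alt)) if depth > 0 else 0
            out.append((row.chrom, row.pos, row.ref, row.alt, depth - alt, alt))
    return pd.DataFrame(
        out, columns=["chrom", "pos", "ref", "alt", "ref_count", "alt_count"]
    )


# =====================================================================
# Bulk primary probe track
# =====================================================================

def simulate_primary_track(
    genome: Mapping[str, str],
    truth: TumorTruth,
    probe_spacing: int = 10_000,
    noise_sd: float = 0.05,
    seed: int = 0,
    het_fraction: float = 0.6,
    mirror_baf: bool = False,
) -> pd.DataFrame:
    """Bulk probe table (chrom, pos, logr, baf, gc) mixing clones by fraction.

    Probe logR = log2(fraction-weighted total CN / 2) + Gaussian noise;
    probe BAF reflects the weighted allele-B fraction for het probes and
    the fixed genotype (0 or 1) for homozygous probes. ``mirror_baf`` folds
    BAF around 0.5 as mirrored-BAF arrays report it.
    """
    if probe_spacing <= 0:
        raise ValueError("probe_spacing must be > 0")
    rng = np.random.default_rng(seed)
    clone_tracks = {c.name: clone_cn_tracks(truth, c.name) for c in truth.clones}
    rows = []
    for chrom, length in truth.chrom_lengths.items():
        positions = np.arange(probe_spacing // 2, length, probe_spacing)
        tot = np.full(len(positions), 2.0 * truth.normal_fraction)
        bcn = np.full(len(positions), 1.0 * truth.normal_fraction)
        for clone in truth.clones:
            tr = clone_tracks[clone.name]
            sub = tr[tr["chrom"] == chrom]
            idx = np.searchsorted(sub["start"].to_numpy(), positions, side="right") - 1
            tot += clone.fraction * (sub["cn_a"].to_numpy() + sub["cn_b"].to_numpy())[idx]
            bcn += clone.fraction * sub["cn_b"].to_numpy()[idx]
        logr = np.log2(np.maximum(tot, 1e-6) / 2.0) + rng.normal(0, noise_sd, len(positions))
        gt = rng.random(len(positions))
        is_het = gt < het_fraction
        hom_alt = gt >= het_fraction + (1 - het_fraction) / 2
        with np.errstate(invalid="ignore", divide="ignore"):
            baf_het = np.where(tot > 0, bcn / np.maximum(tot, 1e-6), 0.5)
        baf = np.where(is_het, baf_het, np.where(hom_alt, 1.0, 0.0))
        baf = np.clip(baf + rng.normal(0, noise_sd, len(positions)) * is_het, 0, 1)
        if mirror_baf:
            baf = np.maximum(baf, 1 - baf)
        seq = genome[chrom]
        for p, lr, bf in zip(positions, logr, baf):
            w0, w1 = max(0, p - 500), min(length, p + 500)
            window = seq[w0:w1]
            gc = (window.count("G") + window.count("C")) / len(window)
            rows.append((chrom, int(p), float(lr), float(bf), float(gc)))
    return pd.DataFrame(rows, columns=["chrom", "pos", "logr", "baf", "gc"])
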