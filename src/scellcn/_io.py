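"""File-format helpers shared across the pipeline.

Coordinate conventions, stated once and enforced here:

* internal tables and BED files are 0-based, half-open;
* SAM and VCF records are 1-based (converted at the boundary).

Alignments travel as a :class:`pandas.DataFrame` with columns
``qname, chrom, start, strand`` where ``start`` is the leftmost (0-based)
reference coordinate of the aligned read.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from pyfaidx import Fasta

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")

ALIGNMENT_COLUMNS = ["qname", "chrom", "start", "strand"]


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------- FASTA

def write_fasta(sequences: Mapping[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str) -> dict[str, str]:
    fa = Fasta(path, as_raw=True, sequence_always_upper=True)
    out = {name: str(fa[name][:]) for name in fa.keys()}
    fa.close()
    return out


# ---------------------------------------------------------------- FASTQ

def write_fastq(reads: Iterable[tuple[str, str, str]], path: str) -> None:
    """Write ``(name, sequence, quality)`` triples as FASTQ."""
    with open(path, "w") as fh:
        for name, seq, qual in reads:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def read_fastq(path: str) -> list[tuple[str, str, str]]:
    out = []
    with pysam.FastxFile(path) as fh:
        for rec in fh:
            out.append((rec.name, rec.sequence, rec.quality or ""))
    return out


# ---------------------------------------------------------------- SAM

def write_sam(
    alignments: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    path: str,
    *,
    read_length: int,
    sequences: Sequence[str] | None = None,
) -> None:
    """Write single-end alignments as a minimal text SAM.

    POS is 1-based; reverse-strand reads carry flag 16 and their SEQ is the
    reverse complement of the reference-forward sequence, as aligners emit.
    """
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unknown"},
            "SQ": [{"SN": c, "LN": int(l)} for c, l in chrom_lengths.items()],
        }
    )
    cigar = f"{read_length}M"
    with pysam.AlignmentFile(path, "w", header=header) as fh:
        for i, row in enumerate(alignments.itertuples(index=False)):
            a = pysam.AlignedSegment(header)
            a.query_name = row.qname
            a.flag = 16 if row.strand == "-" else 0
            a.reference_name = row.chrom
            a.reference_start = int(row.start)  # pysam is 0-based; writes POS+1
            a.mapping_quality = 60
            a.cigarstring = cigar
            if sequences is not None:
                seq = sequences[i]
                a.query_sequence = revcomp(seq) if row.strand == "-" else seq
                a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            fh.write(a)


def read_sam(path: str) -> pd.DataFrame:
    rows = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped:
                continue
            rows.append(
                (
                    a.query_name,
                    a.reference_name,
                    a.reference_start,
                    "-" if a.is_reverse else "+",
                )
            )
    return pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS)


# ---------------------------------------------------------------- BED

def write_alignment_bed(alignments: pd.DataFrame, path: str, *, read_length: int) -> None:
    df = pd.DataFrame(
        {
            "chrom": alignments["chrom"],
            "start": alignments["start"].astype(int),
            "end": alignments["start"].astype(int) + read_length,
            "name": alignments["qname"],
            "score": 0,
            "strand": alignments["strand"],
        }
    )
    df.to_csv(path, sep="\t", header=False, index=False)


def read_alignment_bed(path: str) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str},
    )
    return pd.DataFrame(
        {
            "qname": df["name"],
            "chrom": df["chrom"],
            "start": df["start"].astype(int),
            "strand": df["strand"],
        }
    )


def write_table(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


# ---------------------------------------------------------------- VCF

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##INFO=<ID=GT2,Number=2,Type=String,Description="Phased bases on haplotypes A and B">\n'
)


def write_vcf(sites: pd.DataFrame, chrom_lengths: Mapping[str, int], path: str) -> None:
    """Write a SNP panel (columns chrom, pos (1-based), ref, alt, base_a, base_b)."""
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        for c, l in chrom_lengths.items():
            fh.write(f"##contig=<ID={c},length={int(l)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in sites.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{int(row.pos)}\t.\t{row.ref}\t{row.alt}\t.\t.\t"
                f"GT2={row.base_a},{row.base_b}\n"
            )


def read_vcf(path: str) -> pd.DataFrame:
    rows = []
    with pysam.VariantFile(path) as fh:
        for rec in fh:
            gt2 = rec.info.get("GT2", (".", "."))
            rows.append((rec.chrom, rec.pos, rec.ref, rec.alts[0], gt2[0], gt2[1]))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "base_a", "base_b"])


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path


def chrom_sort_key(chroms: Iterable[str]) -> list[str]:
    """Stable natural order for chromosome names like chr1..chr22."""

    def key(c: str):
        tail = c[3:] if c.startswith("chr") else c
        return (0, int(tail)) if tail.isdigit() else (1, tail)

    return sorted(set(chroms), key=key)


def encode_sequence(seq: str) -> np.ndarray:
    """Encode A/C/G/T as 0..3 (uint8); anything else as 4."""
    table = np.full(256, 4, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
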