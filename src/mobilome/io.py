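"""Readers and writers for the standard formats the pipeline touches.

FASTA/FASTQ go through Biopython; BED and TSV matrices through pandas.
SAM is consumed as plain text (header optional, 11 mandatory columns) and
GFF3 gene models are assembled with intron synthesis — both convert the
formats' 1-based coordinates to the internal 0-based half-open convention
at this boundary and back on write.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    AlignmentRecord,
    GeneModel,
    Genome,
    GenomicInterval,
    SUPPORTED_OPS,
)

logger = logging.getLogger(__name__)

_NON_ACGTN = re.compile("[^ACGTN]")


def read_fasta(path: str | Path) -> Genome:
    """Read a FASTA file into a :class:`Genome`.

    Sequences are upper-cased; characters outside {A,C,G,T,N} map to N.
    """
    chroms: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = _NON_ACGTN.sub("N", str(rec.seq).upper())
        if rec.id in chroms:
            raise ValueError(f"{path}: duplicate sequence name {rec.id!r}")
        if not seq:
            raise ValueError(f"{path}: empty sequence for {rec.id!r}")
        chroms[rec.id] = seq
    if not chroms:
        raise ValueError(f"{path}: no FASTA records found")
    return Genome(chroms)


def write_fasta(genome: Genome, path: str | Path, width: int = 80) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def write_fastq_pair(
    pairs: Iterable[tuple[str, str, str]], path1: str | Path, path2: str | Path
) -> None:
    """Write (read_id, mate1_seq, mate2_seq) triples as a FASTQ pair."""
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for read_id, m1, m2 in pairs:
            q1 = "I" * len(m1)
            q2 = "I" * len(m2)
            f1.write(f"@{read_id}/1\n{m1}\n+\n{q1}\n")
            f2.write(f"@{read_id}/2\n{m2}\n+\n{q2}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


# --- SAM text dialect ----------------------------------------------------

_CIGAR_RE = re.compile(r"(\d+)([A-Z=])")

FLAG_UNMAPPED = 0x4
FLAG_REVERSE = 0x10
FLAG_READ2 = 0x80
FLAG_DUPLICATE = 0x400


def parse_cigar(cigar: str) -> list[tuple[str, int]]:
    if cigar == "*":
        return []
    ops = [(op, int(n)) for n, op in _CIGAR_RE.findall(cigar)]
    if "".join(f"{n}{op}" for op, n in ops) != cigar:
        raise ValueError(f"malformed CIGAR {cigar!r}")
    return ops


def cigar_to_str(cigar: Sequence[tuple[str, int]]) -> str:
    return "".join(f"{n}{op}" for op, n in cigar) if cigar else "*"


def read_sam(path: str | Path) -> tuple[list[AlignmentRecord], int]:
    """Parse SAM text into alignment records.

    Returns ``(records, n_rejected)``. Records whose CIGAR contains ops
    outside {M,I,D,S} are rejected with a warning and counted, never
    silently corrected. 1-based POS becomes 0-based.
    """
    records: list[AlignmentRecord] = []
    n_rejected = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("@") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 11:
                raise ValueError(f"{path}:{lineno}: fewer than 11 SAM columns")
            qname, flag_s, rname, pos_s, _mapq, cigar_s = fields[:6]
            seq = fields[9].upper()
            flag = int(flag_s)
            mapped = not (flag & FLAG_UNMAPPED)
            try:
                cigar = parse_cigar(cigar_s) if mapped else []
            except ValueError:
                n_rejected += 1
                continue
            if any(op not in SUPPORTED_OPS for op, _ in cigar):
                n_rejected += 1
                continue
            try:
                rec = AlignmentRecord(
                    read_id=qname,
                    query_seq="" if seq == "*" else seq,
                    mapped=mapped,
                    ref_name=rname if mapped else "*",
                    pos=int(pos_s) - 1 if mapped else -1,
                    cigar=cigar,
                    strand="-" if flag & FLAG_REVERSE else "+",
                    is_read1=not (flag & FLAG_READ2),
                    is_duplicate=bool(flag & FLAG_DUPLICATE),
                )
            except ValueError:
                n_rejected += 1
                continue
            records.append(rec)
    if n_rejected:
        logger.warning("%s: rejected %d SAM records", path, n_rejected)
    return records, n_rejected


def write_sam(
    records: Iterable[AlignmentRecord],
    path: str | Path,
    genome: Genome | None = None,
) -> None:
    """Write records as SAM text (0-based pos -> 1-based POS)."""
    with open(path, "w") as fh:
        if genome is not None:
            for name, seq in genome.items():
                fh.write(f"@SQ\tSN:{name}\tLN:{len(seq)}\n")
        for rec in records:
            flag = 0
            if not rec.mapped:
                flag |= FLAG_UNMAPPED
            if rec.strand == "-":
                flag |= FLAG_REVERSE
            if not rec.is_read1:
                flag |= FLAG_READ2 | 0x1
            if rec.is_duplicate:
                flag |= FLAG_DUPLICATE
            fh.write(
                "\t".join(
                    [
                        rec.read_id,
                        str(flag),
                        rec.ref_name if rec.mapped else "*",
                        str(rec.pos + 1) if rec.mapped else "0",
                        "60" if rec.mapped else "0",
                        cigar_to_str(rec.cigar),
                        "*",
                        "0",
                        "0",
                        rec.query_seq or "*",
                        "*",
                    ]
                )
                + "\n"
            )


# --- BED -----------------------------------------------------------------


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read 3- or 6-column BED (native 0-based half-open)."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start")
            intervals.append(GenomicInterval(chrom, start, end, strand))
    return intervals


def write_bed(
    intervals: Iterable[GenomicInterval],
    path: str | Path,
    names: Sequence[str] | None = None,
    scores: Sequence[float] | None = None,
) -> None:
    intervals = list(intervals)
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if names is not None or scores is not None or iv.strand != ".":
                cols.append(names[i] if names is not None else ".")
                cols.append(str(scores[i]) if scores is not None else "0")
                cols.append(iv.strand if iv.strand != "." else ".")
            fh.write("\t".join(cols) + "\n")


# --- GFF3 ----------------------------------------------------------------

_GENE_TYPES = {"gene"}
_FEATURE_MAP = {
    "five_prime_UTR": "five_prime_UTR",
    "three_prime_UTR": "three_prime_UTR",
    "exon": "exon",
    "intron": "intron",
}


def _gff_attr(attrs: str, key: str) -> str | None:
    for part in attrs.split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            if k.strip() == key:
                return v.strip()
    return None


def read_gff3_genes(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3 (1-based closed -> 0-based half-open).

    Intron features are synthesized from the gaps between consecutive
    exons when the file does not annotate them.
    """
    genes: dict[str, GeneModel] = {}
    parent_of: dict[str, str] = {}  # transcript id -> gene id
    feature_rows: list[tuple[str, str, GenomicInterval]] = []
    exons_by_tx: dict[str, list[GenomicInterval]] = {}
    has_introns: set[str] = set()

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _src, ftype, start_s, end_s, _score, strand, _phase, attrs = fields
            start, end = int(start_s) - 1, int(end_s)
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end < start after conversion")
            if ftype in _GENE_TYPES:
                gid = _gff_attr(attrs, "ID") or f"gene_{lineno}"
                genes[gid] = GeneModel(
                    gene_id=gid,
                    interval=GenomicInterval(chrom, start, end, strand),
                )
            elif ftype in ("mRNA", "transcript"):
                tid = _gff_attr(attrs, "ID")
                parent = _gff_attr(attrs, "Parent")
                if tid and parent:
                    parent_of[tid] = parent
            elif ftype in _FEATURE_MAP:
                parent = _gff_attr(attrs, "Parent") or ""
                iv = GenomicInterval(chrom, start, end, strand if strand in "+-" else ".")
                feature_rows.append((parent, _FEATURE_MAP[ftype], iv))
                if ftype == "exon":
                    exons_by_tx.setdefault(parent, []).append(iv)
                elif ftype == "intron":
                    has_introns.add(parent)

    def owner(parent: str) -> str | None:
        if parent in genes:
            return parent
        return parent_of.get(parent)

    for parent, kind, iv in feature_rows:
        gid = owner(parent)
        if gid in genes:
            genes[gid].features.append(
                (kind, GenomicInterval(iv.chrom, iv.start, iv.end))
            )
    # synthesize introns from exon gaps per transcript
    for tx, exons in exons_by_tx.items():
        if tx in has_introns:
            continue
        gid = owner(tx)
        if gid not in genes:
            continue
        exons = sorted(exons, key=lambda e: e.start)
        for left, right in zip(exons, exons[1:]):
            if right.start > left.end:
                genes[gid].features.append(
                    ("intron", GenomicInterval(left.chrom, left.end, right.start))
                )
    return list(genes.values())


# --- TSV matrices --------------------------------------------------------


def read_tsv_matrix(path: str | Path) -> pd.DataFrame:
    """TSV with a header row and row identifiers in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_tsv_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")
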