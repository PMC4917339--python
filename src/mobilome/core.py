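"""Shared domain types, coordinate conventions and run configuration.

All genomic coordinates inside the package are 0-based, half-open
(``[start, end)``); conversion to/from the 1-based conventions of SAM and
GFF3 happens only at the format boundary (see :mod:`mobilome.io`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case nucleotide string."""
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval on a named chromosome.

    ``strand`` is "+", "-" or "." (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def contains_pos(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end


class Genome:
    """An ordered mapping of chromosome name -> upper-case sequence."""

    def __init__(self, chromosomes: Mapping[str, str]):
        if not chromosomes:
            raise ValueError("genome has no chromosomes")
        self.chromosomes: dict[str, str] = {}
        for name, seq in chromosomes.items():
            if not name:
                raise ValueError("empty chromosome name")
            if len(seq) < 1:
                raise ValueError(f"chromosome {name!r} is empty")
            self.chromosomes[name] = seq.upper()

    def __getitem__(self, name: str) -> str:
        return self.chromosomes[name]

    def __contains__(self, name: str) -> bool:
        return name in self.chromosomes

    def __iter__(self):
        return iter(self.chromosomes)

    def __len__(self) -> int:
        return len(self.chromosomes)

    def items(self):
        return self.chromosomes.items()

    def length(self, name: str) -> int:
        return len(self.chromosomes[name])

    def total_length(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())

    def fetch(self, interval: GenomicInterval) -> str:
        seq = self.chromosomes[interval.chrom][interval.start : interval.end]
        return revcomp(seq) if interval.strand == "-" else seq


@dataclass
class TEFamily:
    """A transposable-element family: the unit of discovery.

    ``tsd_len`` is the fixed target-site-duplication size created on
    insertion (3-15 bp depending on family), or None for families that do
    not create TSDs (e.g. Helitrons) — those are excluded from split-read
    calling. ``extremity_5``/``extremity_3`` are the terminal sequences
    (up to 300 bp) used as forced-mapping targets.
    """

    name: str
    te_class: str  # "I" (retrotransposon) or "II" (DNA transposon)
    superfamily: str
    tsd_len: int | None
    extremity_5: str
    extremity_3: str

    def __post_init__(self) -> None:
        if self.te_class not in ("I", "II"):
            raise ValueError(f"te_class must be 'I' or 'II', got {self.te_class!r}")
        if self.tsd_len is not None and not (3 <= self.tsd_len <= 15):
            raise ValueError(f"tsd_len must be in [3, 15], got {self.tsd_len}")
        if not self.extremity_5 or not self.extremity_3:
            raise ValueError(f"family {self.name}: extremities must be non-empty")


@dataclass(frozen=True)
class TEAnnotation:
    """An annotated TE copy in the reference genome."""

    interval: GenomicInterval
    family: str

    @property
    def copy_length(self) -> int:
        return len(self.interval)


@dataclass
class GeneModel:
    """A protein-coding gene with its genic features.

    ``features`` holds (kind, interval) pairs with kind one of
    five_prime_UTR / three_prime_UTR / exon / intron; intron features are
    synthesized from exon gaps when absent from the annotation.
    """

    gene_id: str
    interval: GenomicInterval
    features: list[tuple[str, GenomicInterval]] = field(default_factory=list)

    FEATURE_KINDS = ("five_prime_UTR", "three_prime_UTR", "exon", "intron")

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: gene interval must be stranded")
        for kind, iv in self.features:
            if kind not in self.FEATURE_KINDS:
                raise ValueError(f"gene {self.gene_id}: unknown feature kind {kind!r}")
            if not self.interval.contains(iv):
                raise ValueError(
                    f"gene {self.gene_id}: feature {kind} {iv} outside gene interval"
                )


# CIGAR ops: M/I/S consume the query, M/D consume the reference.
QUERY_OPS = frozenset("MIS")
REF_OPS = frozenset("MD")
SUPPORTED_OPS = frozenset("MIDS")


@dataclass
class AlignmentRecord:
    """One read placement, the input currency of the caller.

    ``pos`` is 0-based; ``cigar`` is a list of (op, length) pairs over the
    supported ops M, I, D, S. Unmapped records carry an empty CIGAR.
    """

    read_id: str
    query_seq: str
    mapped: bool
    ref_name: str = "*"
    pos: int = -1
    cigar: list[tuple[str, int]] = field(default_factory=list)
    strand: str = "+"
    is_read1: bool = True
    is_duplicate: bool = False

    def __post_init__(self) -> None:
        if self.mapped:
            qlen = sum(n for op, n in self.cigar if op in QUERY_OPS)
            if self.query_seq and qlen != len(self.query_seq):
                raise ValueError(
                    f"{self.read_id}: CIGAR query length {qlen} != "
                    f"sequence length {len(self.query_seq)}"
                )
        elif self.cigar:
            raise ValueError(f"{self.read_id}: unmapped record must have empty CIGAR")

    @property
    def ref_span(self) -> int:
        return sum(n for op, n in self.cigar if op in REF_OPS)

    def ref_blocks(self) -> list[tuple[int, int]]:
        """Reference intervals consumed by M/D ops (merged runs)."""
        blocks: list[tuple[int, int]] = []
        p = self.pos
        for op, n in self.cigar:
            if op in REF_OPS:
                if blocks and blocks[-1][1] == p:
                    blocks[-1] = (blocks[-1][0], p + n)
                else:
                    blocks.append((p, p + n))
                p += n
        return blocks


_CONFIG_TYPES = {
    "window_bp": int,
    "extremity_len": int,
    "min_clip": int,
    "min_reads_discovery": int,
    "min_reads_genotype": int,
    "tsd_overlap_factor": float,
    "mad_k": float,
    "cohort_freq_filter": float,
    "cnv_fdr_threshold": float,
    "enrich_tail": float,
    "spread_short_bp": int,
    "spread_long_bp": int,
    "meth_window_bp": int,
    "meth_diff_threshold": float,
    "min_te_len_cnv": int,
    "min_te_len_family_exclude": int,
    "n_perm": int,
    "rng_seed": int,
    "genotype_tolerance_bp": int,
    "enrich_window_bp": int,
}


@dataclass
class PipelineConfig:
    """Every tunable constant of the pipeline, overridable from a flat
    ``key=value`` config file. Defaults are the published operating point."""

    window_bp: int = 100              # coverage bin width
    extremity_len: int = 300          # TE extremity target length
    min_clip: int = 20                # minimum soft-clip / anchor length (nt)
    min_reads_discovery: int = 5      # reads per cluster at discovery
    min_reads_genotype: int = 2       # reads to call presence in other accessions
    tsd_overlap_factor: float = 2.0   # max TSD overlap = factor * tsd_len
    mad_k: float = 3.0                # MAD multiplier for outlier masks
    cohort_freq_filter: float = 0.5   # drop calls carried by >= this fraction
    cnv_fdr_threshold: float = 1e-5   # empirical FDR cut for significant CNV
    enrich_tail: float = 5e-5         # upper tail for 10-kb window enrichment
    spread_short_bp: int = 300        # short-distance methylation spreading
    spread_long_bp: int = 1000        # long-distance methylation spreading
    meth_window_bp: int = 50          # methylation window width
    meth_diff_threshold: float = 0.2  # carrier-vs-non-carrier difference cut
    min_te_len_cnv: int = 300         # min annotated copy length for CNV
    min_te_len_family_exclude: int = 350  # family excluded if all copies shorter
    n_perm: int = 1000                # permutations per statistic
    rng_seed: int = 0
    genotype_tolerance_bp: int = 2    # junction tolerance when genotyping
    enrich_window_bp: int = 10_000

    def __post_init__(self) -> None:
        for name in (
            "window_bp", "extremity_len", "min_clip", "min_reads_discovery",
            "min_reads_genotype", "tsd_overlap_factor", "mad_k",
            "cnv_fdr_threshold", "spread_short_bp", "spread_long_bp",
            "meth_window_bp", "min_te_len_cnv", "n_perm", "enrich_window_bp",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"config: {name} must be strictly positive")
        if not (0 < self.cohort_freq_filter <= 1):
            raise ValueError("config: cohort_freq_filter must be in (0, 1]")
        for name in ("cnv_fdr_threshold", "enrich_tail"):
            if not (0 < getattr(self, name) < 1):
                raise ValueError(f"config: {name} must be in (0, 1)")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load overrides from a flat ``key=value`` file (# comments allowed)."""
        overrides: dict[str, object] = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value, got {raw!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in _CONFIG_TYPES:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            overrides[key] = _CONFIG_TYPES[key](value)
        return cls(**overrides)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping/adjacent intervals per chromosome (strand dropped)."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda x: (x.start, x.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_s, cur_e))
    return merged
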