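"""Built-in exact-match alignment.

The split-read algorithm only needs three alignment behaviours: (a) a
whole-genome mapped/unmapped classification of reads, (b) unique exact
end-to-end placement of short fragments, and (c) local alignment of a read
against a short TE-extremity target with one terminal soft clip. All three
are provided here by an exact k-mer seed-and-verify index plus a
longest-terminal-block scanner. Ambiguous placements (two or more equally
good locations) are reported as unmapped rather than resolved at random,
so every downstream result is deterministic. Production runs may instead
feed alignments from any external aligner as SAM text.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import Genome, revcomp

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def _encode(seq_bytes: bytes) -> np.ndarray:
    return _CODE[np.frombuffer(seq_bytes, dtype=np.uint8)]


def _kmer_hash(codes: np.ndarray, k: int) -> int | None:
    """Exact base-4 value of the first k codes; None if any N."""
    window = codes[:k]
    if (window == 4).any():
        return None
    h = 0
    for c in window:
        h = h * 4 + int(c)
    return h


class ExactIndex:
    """Exact-occurrence index over a genome (both strands on query side).

    Indexes every k-mer start position (k defaults to the 20-nt minimum
    anchor of the pipeline); queries of length >= k are located by seeding
    on their first k-mer and verifying the full sequence.
    """

    def __init__(self, genome: Genome, k: int = 20):
        self.k = k
        self.names: list[str] = []
        offsets = []
        parts = []
        off = 0
        for name, seq in genome.items():
            self.names.append(name)
            offsets.append(off)
            parts.append(seq)
            off += len(seq)
        self.concat = "".join(parts)
        self.concat_b = self.concat.encode()
        self.offsets = np.asarray(offsets, dtype=np.int64)
        self.ends = self.offsets + np.asarray(
            [len(p) for p in parts], dtype=np.int64
        )
        self.total = off

        codes = _encode(self.concat_b).astype(np.uint64)
        n = len(codes)
        if n < k:
            self.sorted_h = np.empty(0, dtype=np.uint64)
            self.sorted_pos = np.empty(0, dtype=np.int64)
            return
        n_win = n - k + 1
        h = np.zeros(n_win, dtype=np.uint64)
        for j in range(k):
            h = h * np.uint64(4) + codes[j : j + n_win]
        # valid starts: no N inside the k-mer and k-mer within one chromosome
        is_n = (codes == 4).astype(np.int64)
        cs = np.concatenate([[0], np.cumsum(is_n)])
        valid = (cs[k:] - cs[:-k]) == 0
        start_chrom = np.searchsorted(self.offsets, np.arange(n_win), side="right")
        end_chrom = np.searchsorted(
            self.offsets, np.arange(k - 1, n), side="right"
        )
        valid &= start_chrom == end_chrom
        pos = np.nonzero(valid)[0].astype(np.int64)
        hashes = h[pos]
        order = np.argsort(hashes, kind="stable")
        self.sorted_h = hashes[order]
        self.sorted_pos = pos[order]

    # -- coordinate helpers ------------------------------------------------

    def chrom_of(self, gpos: int) -> int:
        return int(np.searchsorted(self.offsets, gpos, side="right")) - 1

    def to_local(self, gpos: int) -> tuple[str, int]:
        ci = self.chrom_of(gpos)
        return self.names[ci], int(gpos - self.offsets[ci])

    # -- queries -----------------------------------------------------------

    def find_forward(self, seq: str, max_hits: int = 2) -> list[int]:
        """Global start positions where ``seq`` occurs on the forward strand."""
        if len(seq) < self.k:
            raise ValueError(f"query shorter than index k={self.k}")
        codes = _encode(seq.encode())
        h = _kmer_hash(codes, self.k)
        if h is None:
            return []
        h = np.uint64(h)
        lo = int(np.searchsorted(self.sorted_h, h, side="left"))
        hi = int(np.searchsorted(self.sorted_h, h, side="right"))
        seq_b = seq.encode()
        L = len(seq_b)
        hits: list[int] = []
        for p in self.sorted_pos[lo:hi]:
            p = int(p)
            ci = self.chrom_of(p)
            if p + L > self.ends[ci]:
                continue
            if self.concat_b[p : p + L] == seq_b:
                hits.append(p)
                if len(hits) >= max_hits:
                    break
        return hits

    def find_occurrences(
        self, seq: str, max_hits: int = 2
    ) -> list[tuple[str, int, str]]:
        """All exact occurrences of ``seq`` on either strand, as
        (chrom, 0-based start, strand), capped at ``max_hits``."""
        out: list[tuple[str, int, str]] = []
        for p in self.find_forward(seq, max_hits=max_hits):
            out.append((*self.to_local(p), "+"))
        if len(out) < max_hits:
            for p in self.find_forward(revcomp(seq), max_hits=max_hits - len(out)):
                out.append((*self.to_local(p), "-"))
        return out

    def classify_mapped(self, seqs: Sequence[str]) -> np.ndarray:
        """Boolean array: does each read occur exactly (either strand)?

        Vectorized for uniform-length reads; this is the whole-genome
        alignment step that feeds unmapped-read extraction.
        """
        n = len(seqs)
        if n == 0:
            return np.zeros(0, dtype=bool)
        lens = {len(s) for s in seqs}
        if len(lens) != 1 or min(lens) < self.k:
            return np.array(
                [len(self.find_occurrences(s, max_hits=1)) > 0 for s in seqs]
            )
        L = lens.pop()
        buf = "".join(seqs).encode()
        codes = _encode(buf).reshape(n, L).astype(np.uint64)
        k = self.k
        fwd = np.zeros(n, dtype=np.uint64)
        rev = np.zeros(n, dtype=np.uint64)
        for j in range(k):
            fwd = fwd * np.uint64(4) + codes[:, j]
            # first k-mer of the reverse complement = complement of the
            # last k bases, reversed
            rev = rev * np.uint64(4) + (np.uint64(3) - codes[:, L - 1 - j])
        has_n = (codes == 4).any(axis=1)
        mapped = np.zeros(n, dtype=bool)
        arr = np.frombuffer(buf, dtype=np.uint8).reshape(n, L)
        for hashes, is_fwd in ((fwd, True), (rev, False)):
            lo = np.searchsorted(self.sorted_h, hashes, side="left")
            hi = np.searchsorted(self.sorted_h, hashes, side="right")
            todo = np.nonzero((hi > lo) & ~mapped & ~has_n)[0]
            for i in todo:
                s = arr[i].tobytes() if is_fwd else revcomp(seqs[i]).encode()
                for p in self.sorted_pos[lo[i] : hi[i]]:
                    p = int(p)
                    ci = self.chrom_of(p)
                    if p + L <= self.ends[ci] and self.concat_b[p : p + L] == s:
                        mapped[i] = True
                        break
        return mapped


# --- naive aligner contracts ---------------------------------------------


@dataclass
class LocalHit:
    """Result of :func:`naive_local_align`.

    ``strand`` is the orientation of the read against the target;
    ``cigar`` refers to the read oriented to that strand ("M,S" or "S,M").
    """

    target_pos: int      # start of the matched block within the target
    match_len: int
    clip_len: int
    strand: str          # "+": read as given; "-": reverse complement
    cigar: tuple[tuple[str, int], tuple[str, int]]

    @property
    def clipped_first(self) -> bool:
        return self.cigar[0][0] == "S"


def _longest_terminal(block_of, read_len: int, target: str) -> tuple[int, str | None]:
    """Longest L such that block_of(L) occurs in target (monotone in L)."""
    lo, hi = 0, read_len
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if block_of(mid) in target:
            lo = mid
        else:
            hi = mid - 1
    return lo, (block_of(lo) if lo else None)


def naive_local_align(read: str, target_seq: str, min_clip: int = 20) -> LocalHit | None:
    """Align a read end against a target by longest exact terminal block.

    Considers the read's prefix and suffix on both strands; the winner is
    the single longest block (anchor). Returns None when the anchor is
    shorter than ``min_clip`` or when the best-length placement is
    ambiguous (>= 2 candidates of equal length).
    """
    if len(read) < min_clip:
        return None
    rc = revcomp(read)
    candidates = []  # (length, block, strand, mode)
    for strand, s in (("+", read), ("-", rc)):
        for mode in ("prefix", "suffix"):
            if mode == "prefix":
                fn = lambda L, s=s: s[:L]
            else:
                fn = lambda L, s=s: s[len(s) - L :]
            L, block = _longest_terminal(fn, len(s), target_seq)
            if L >= min_clip:
                candidates.append((L, block, strand, mode))
    if not candidates:
        return None
    best_len = max(c[0] for c in candidates)
    best = [c for c in candidates if c[0] == best_len]
    placements = sum(target_seq.count(c[1]) for c in best)
    if placements != 1:
        return None
    L, block, strand, mode = best[0]
    clip = len(read) - L
    pos = target_seq.find(block)
    if mode == "prefix":
        cigar = (("M", L), ("S", clip))
    else:
        cigar = (("S", clip), ("M", L))
    return LocalHit(target_pos=pos, match_len=L, clip_len=clip, strand=strand, cigar=cigar)


def naive_end_to_end_align(
    fragment: str, target: "ExactIndex | Genome", min_clip: int = 20
) -> tuple[str, int, str] | None:
    """Unique exact full-length placement of a fragment on either strand.

    Returns (chrom, 0-based pos, strand) or None when the fragment is
    absent, occurs more than once, or is shorter than ``min_clip``.
    """
    if len(fragment) < min_clip:
        return None
    if isinstance(target, ExactIndex):
        occ = target.find_occurrences(fragment, max_hits=2)
    else:
        occ = _scan_genome(fragment, target, max_hits=2)
    return occ[0] if len(occ) == 1 else None


def _scan_genome(seq: str, genome: Genome, max_hits: int) -> list[tuple[str, int, str]]:
    out: list[tuple[str, int, str]] = []
    for strand, q in (("+", seq), ("-", revcomp(seq))):
        for name, chrom_seq in genome.items():
            start = chrom_seq.find(q)
            while start != -1:
                out.append((name, start, strand))
                if len(out) >= max_hits:
                    return out
                start = chrom_seq.find(q, start + 1)
    return out


def align_reads_for_coverage(
    reads: Sequence[tuple[str, str]],
    index: ExactIndex,
    rng: np.random.Generator,
    max_hits: int = 50,
):
    """Place reads for read-depth analysis (exact matches only).

    Multi-mapping reads are assigned uniformly at random among their
    placements (seeded), mirroring how production aligners report one hit
    for repetitive sequence; reads without an exact occurrence come back
    unmapped. Returns :class:`~mobilome.core.AlignmentRecord` objects.
    """
    from .core import AlignmentRecord

    records = []
    for read_id, seq in reads:
        occ = index.find_occurrences(seq, max_hits=max_hits)
        if not occ:
            records.append(AlignmentRecord(read_id, seq, mapped=False))
            continue
        chrom, pos, strand = occ[int(rng.integers(len(occ)))] if len(occ) > 1 else occ[0]
        records.append(
            AlignmentRecord(
                read_id,
                seq if strand == "+" else revcomp(seq),
                mapped=True,
                ref_name=chrom,
                pos=pos,
                cigar=[("M", len(seq))],
                strand=strand,
            )
        )
    return records
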