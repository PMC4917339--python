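"""Split-read, TSD-validated calling of non-reference TE insertions.

The algorithm runs in four steps per accession:

1. extract reads that do not map to the reference genome (SAM flag 4;
   mate/discordant-pair information is deliberately not used);
2. force-map those reads to a library of 5' and 3' TE-extremity targets,
   keeping alignments with exactly one terminal soft clip of >= 20 nt;
3. map each clipped fragment end-to-end back to the reference, recursively
   trimming 1 nt from the junction-proximal end on failure until the
   fragment would drop below 20 nt;
4. cluster the resulting junctions per family and genomic side and call an
   insertion where a cluster of reads clipped from one extremity overlaps
   a cluster from the other extremity by no more than twice the family's
   TSD length — the overlap *is* the reconstructed target-site
   duplication.

Filters for masked regions, pericentromeres, donor spans, control calls,
coverage outliers, cohort frequency and TE-annotation overlap are applied
afterwards, followed by relaxed re-screening (genotyping) across the
cohort.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .align import ExactIndex, LocalHit, naive_end_to_end_align, naive_local_align
from .core import (
    AlignmentRecord,
    Genome,
    GenomicInterval,
    PipelineConfig,
    TEAnnotation,
    TEFamily,
    revcomp,
)

logger = logging.getLogger(__name__)

LEFT_OF_TE = "left_of_TE"
RIGHT_OF_TE = "right_of_TE"

FILTER_FLAGS = (
    "in_mask",
    "inner_pericentromere",
    "spans_donor",
    "in_control",
    "coverage_outlier",
    "high_frequency",
    "in_te_annotation",
)


@dataclass
class ExtremityTarget:
    family: str
    te_side: str  # "5prime" | "3prime"
    seq: str


@dataclass
class SplitReadEvidence:
    """One read supporting a TE/genome junction."""

    read_id: str
    family: str
    te_side: str
    te_match_len: int
    clip_len: int
    fragment: str                  # clipped subsequence, aligned orientation
    junction_at: str               # "left" | "right" end of the fragment
    chrom: str | None = None
    junction: int | None = None
    genomic_side: str | None = None
    trims: int = 0
    orientation: str | None = None


@dataclass
class ClipCluster:
    family: str
    chrom: str
    genomic_side: str
    junction_positions: list[int]
    boundary: int
    n_reads: int
    orientation: str


@dataclass
class InsertionCall:
    family: str
    tsd_interval: GenomicInterval
    tsd_seq: str
    n_reads_left: int
    n_reads_right: int
    orientation: str
    discovered_in: str
    status: set[str] = field(default_factory=lambda: {"PASS"})

    @property
    def passed(self) -> bool:
        return self.status == {"PASS"}


# --- step (i): unmapped-read extraction ----------------------------------


def extract_unmapped(records: Iterable[AlignmentRecord]) -> list[tuple[str, str]]:
    """Query sequences of flag-4 records. Mates are treated independently."""
    return [(r.read_id, r.query_seq) for r in records if not r.mapped and r.query_seq]


# --- step (ii): forced mapping to TE extremities -------------------------


def build_extremity_library(
    te_sequences: Mapping[str, str],
    families: Sequence[TEFamily],
    config: PipelineConfig,
) -> list[ExtremityTarget]:
    """5' and 3' extremity targets (extremity_len bases) per family.

    Families without a TSD size are excluded from split-read calling.
    Sequences shorter than twice the extremity length contribute
    overlapping ends (logged).
    """
    targets: list[ExtremityTarget] = []
    el = config.extremity_len
    for fam in families:
        if fam.tsd_len is None:
            continue
        seq = te_sequences.get(fam.name)
        if not seq:
            raise ValueError(f"family {fam.name}: empty or missing TE sequence")
        if len(seq) < 2 * el:
            logger.warning(
                "family %s: sequence %d bp < 2x extremity length; "
                "5' and 3' targets overlap",
                fam.name,
                len(seq),
            )
        targets.append(ExtremityTarget(fam.name, "5prime", seq[:el]))
        targets.append(ExtremityTarget(fam.name, "3prime", seq[-el:]))
    return targets


def map_to_extremities(
    unmapped_reads: Sequence[tuple[str, str]],
    library: Sequence[ExtremityTarget],
    config: PipelineConfig,
    local_aligner: Callable[..., LocalHit | None] = naive_local_align,
) -> list[SplitReadEvidence]:
    """Keep reads with exactly one terminal soft clip >= min_clip against a
    single best extremity target; the clipped subsequence is retained for
    genomic remapping."""
    evidences: list[SplitReadEvidence] = []
    for read_id, seq in unmapped_reads:
        best: tuple[int, ExtremityTarget, LocalHit] | None = None
        tie = False
        for target in library:
            hit = local_aligner(seq, target.seq, min_clip=config.min_clip)
            if hit is None:
                continue
            if best is None or hit.match_len > best[0]:
                best = (hit.match_len, target, hit)
                tie = False
            elif hit.match_len == best[0]:
                tie = True
        if best is None or tie:
            continue
        _, target, hit = best
        if hit.clip_len < config.min_clip:
            continue
        oriented = seq if hit.strand == "+" else revcomp(seq)
        if hit.clipped_first:
            fragment = oriented[: hit.clip_len]
            junction_at = "right"  # TE part follows the fragment
        else:
            fragment = oriented[hit.match_len :]
            junction_at = "left"
        evidences.append(
            SplitReadEvidence(
                read_id=read_id,
                family=target.family,
                te_side=target.te_side,
                te_match_len=hit.match_len,
                clip_len=hit.clip_len,
                fragment=fragment,
                junction_at=junction_at,
            )
        )
    return evidences


# --- step (iii): genomic remapping with recursive clipping ---------------

_ORIENTATION = {
    (LEFT_OF_TE, "5prime"): "+",
    (LEFT_OF_TE, "3prime"): "-",
    (RIGHT_OF_TE, "3prime"): "+",
    (RIGHT_OF_TE, "5prime"): "-",
}


def map_clipped_fragment(
    evidence: SplitReadEvidence,
    genome_index: "ExactIndex | Genome",
    config: PipelineConfig,
    end_to_end_aligner: Callable[..., tuple[str, int, str] | None] = naive_end_to_end_align,
) -> SplitReadEvidence | None:
    """Place the clipped fragment on the reference.

    On failure the fragment is trimmed by 1 nt from its junction-proximal
    end (TSD/microhomology contamination sits at the junction) and retried
    until it would shrink below min_clip. The junction is the reference
    coordinate of the fragment end adjacent to the TE.
    """
    frag = evidence.fragment
    trims = 0
    while len(frag) >= config.min_clip:
        placement = end_to_end_aligner(frag, genome_index, min_clip=config.min_clip)
        if placement is not None:
            chrom, pos, strand = placement
            at_right = evidence.junction_at == "right"
            if (at_right and strand == "+") or (not at_right and strand == "-"):
                junction = pos + len(frag)
                side = LEFT_OF_TE
            else:
                junction = pos
                side = RIGHT_OF_TE
            evidence.chrom = chrom
            evidence.junction = junction
            evidence.genomic_side = side
            evidence.trims = trims
            evidence.orientation = _ORIENTATION[(side, evidence.te_side)]
            return evidence
        if evidence.junction_at == "right":
            frag = frag[:-1]
        else:
            frag = frag[1:]
        trims += 1
    return None


# --- step (iv): clustering and TSD calling -------------------------------


def _modal_boundary(positions: list[int], genomic_side: str) -> int:
    counts = Counter(positions)
    best_count = max(counts.values())
    modes = [p for p, c in counts.items() if c == best_count]
    # ties break toward the TE: rightward for left-side clusters
    return max(modes) if genomic_side == LEFT_OF_TE else min(modes)


def cluster_evidences(
    evidences: Sequence[SplitReadEvidence],
    family: TEFamily,
    config: PipelineConfig,
) -> list[ClipCluster]:
    """Single-linkage clustering of junction positions per chromosome and
    genomic side with gap <= 2 * tsd_len; chains whose span exceeds the
    bound are split at their largest internal gap."""
    if family.tsd_len is None:
        return []
    max_span = int(config.tsd_overlap_factor * family.tsd_len)
    groups: dict[tuple[str, str], list[SplitReadEvidence]] = {}
    for ev in evidences:
        if ev.family != family.name or ev.junction is None:
            continue
        groups.setdefault((ev.chrom, ev.genomic_side), []).append(ev)

    clusters: list[ClipCluster] = []

    def emit(chunk: list[SplitReadEvidence], chrom: str, side: str) -> None:
        positions = sorted(ev.junction for ev in chunk)
        if positions[-1] - positions[0] > max_span and len(chunk) > 1:
            gaps = [positions[i + 1] - positions[i] for i in range(len(positions) - 1)]
            cut = positions[int(np.argmax(gaps)) + 1]
            emit([e for e in chunk if e.junction < cut], chrom, side)
            emit([e for e in chunk if e.junction >= cut], chrom, side)
            return
        orients = Counter(e.orientation for e in chunk)
        clusters.append(
            ClipCluster(
                family=family.name,
                chrom=chrom,
                genomic_side=side,
                junction_positions=positions,
                boundary=_modal_boundary(positions, side),
                n_reads=len(chunk),
                orientation=orients.most_common(1)[0][0],
            )
        )

    for (chrom, side), evs in groups.items():
        evs = sorted(evs, key=lambda e: e.junction)
        chunk = [evs[0]]
        for ev in evs[1:]:
            if ev.junction - chunk[-1].junction <= max_span:
                chunk.append(ev)
            else:
                emit(chunk, chrom, side)
                chunk = [ev]
        emit(chunk, chrom, side)
    return clusters


def call_insertion(
    left_cluster: ClipCluster,
    right_cluster: ClipCluster,
    family: TEFamily,
    genome: Genome,
    config: PipelineConfig,
    accession: str = "sample",
) -> InsertionCall | None:
    """Call an insertion from an overlapping left/right cluster pair.

    The genomic overlap [right.boundary, left.boundary) covered by both
    flank mappings is the reconstructed TSD; it must be between 1 and
    tsd_overlap_factor * tsd_len wide, and both clusters need
    min_reads_discovery supporting reads and a consistent orientation.
    """
    if family.tsd_len is None:
        return None
    if left_cluster.chrom != right_cluster.chrom:
        return None
    if (
        left_cluster.n_reads < config.min_reads_discovery
        or right_cluster.n_reads < config.min_reads_discovery
    ):
        return None
    if left_cluster.orientation != right_cluster.orientation:
        return None
    width = left_cluster.boundary - right_cluster.boundary
    if not (1 <= width <= config.tsd_overlap_factor * family.tsd_len):
        return None
    tsd = GenomicInterval(left_cluster.chrom, right_cluster.boundary, left_cluster.boundary)
    return InsertionCall(
        family=family.name,
        tsd_interval=tsd,
        tsd_seq=genome.fetch(tsd),
        n_reads_left=left_cluster.n_reads,
        n_reads_right=right_cluster.n_reads,
        orientation=left_cluster.orientation,
        discovered_in=accession,
    )


def pair_clusters(
    clusters: Sequence[ClipCluster],
    family: TEFamily,
    genome: Genome,
    config: PipelineConfig,
    accession: str = "sample",
) -> list[InsertionCall]:
    """Greedy 1-to-1 pairing of left and right clusters per chromosome,
    preferring the pair with the most supporting reads."""
    calls: list[InsertionCall] = []
    lefts = [c for c in clusters if c.genomic_side == LEFT_OF_TE]
    rights = [c for c in clusters if c.genomic_side == RIGHT_OF_TE]
    candidates: list[tuple[int, InsertionCall, int, int]] = []
    for li, lc in enumerate(lefts):
        for ri, rc in enumerate(rights):
            call = call_insertion(lc, rc, family, genome, config, accession)
            if call is not None:
                candidates.append((call.n_reads_left + call.n_reads_right, call, li, ri))
    used_l: set[int] = set()
    used_r: set[int] = set()
    for _support, call, li, ri in sorted(
        candidates, key=lambda t: -t[0]
    ):
        if li in used_l or ri in used_r:
            continue
        used_l.add(li)
        used_r.add(ri)
        calls.append(call)
    calls.sort(key=lambda c: (c.tsd_interval.chrom, c.tsd_interval.start))
    return calls


# --- whole-accession discovery -------------------------------------------


@dataclass
class AccessionResult:
    accession: str
    calls: list[InsertionCall]
    evidences: list[SplitReadEvidence]
    n_reads_in: int
    n_unmapped: int
    n_evidences: int
    n_clusters: int


def discover_insertions(
    reads: Sequence[tuple[str, str]],
    reference: Genome,
    families: Sequence[TEFamily],
    te_sequences: Mapping[str, str],
    config: PipelineConfig,
    accession: str = "sample",
    index: ExactIndex | None = None,
    unmapped: Sequence[tuple[str, str]] | None = None,
) -> AccessionResult:
    """Run steps (i)-(iv) for one accession with the built-in aligner.

    ``unmapped`` may be supplied directly (e.g. extracted from external
    SAM alignments); otherwise reads are classified against the reference
    with the exact index.
    """
    if index is None:
        index = ExactIndex(reference, k=config.min_clip)
    if unmapped is None:
        seqs = [s for _, s in reads]
        mapped = index.classify_mapped(seqs)
        unmapped = [reads[i] for i in np.nonzero(~mapped)[0]]
    library = build_extremity_library(te_sequences, families, config)
    evidences = map_to_extremities(unmapped, library, config)
    placed = [
        ev
        for ev in (
            map_clipped_fragment(ev, index, config) for ev in evidences
        )
        if ev is not None
    ]
    fam_by_name = {f.name: f for f in families}
    calls: list[InsertionCall] = []
    n_clusters = 0
    for fam_name in sorted({ev.family for ev in placed}):
        fam = fam_by_name[fam_name]
        clusters = cluster_evidences(placed, fam, config)
        n_clusters += len(clusters)
        calls.extend(pair_clusters(clusters, fam, reference, config, accession))
    calls.sort(key=lambda c: (c.tsd_interval.chrom, c.tsd_interval.start, c.family))
    logger.info(
        "%s: %d reads in, %d unmapped, %d evidences, %d clusters, %d calls",
        accession, len(reads), len(unmapped), len(placed), n_clusters, len(calls),
    )
    return AccessionResult(
        accession=accession,
        calls=calls,
        evidences=placed,
        n_reads_in=len(reads),
        n_unmapped=len(unmapped),
        n_evidences=len(placed),
        n_clusters=n_clusters,
    )


# --- filtering ------------------------------------------------------------


def apply_filters(
    calls: Sequence[InsertionCall],
    masks: Sequence[GenomicInterval] = (),
    inner_pericentromeres: Sequence[GenomicInterval] = (),
    te_annotations: Sequence[TEAnnotation] = (),
    control_calls: Sequence[InsertionCall] = (),
    coverage_stats: tuple[float, float] | None = None,
    genotype_matrix: pd.DataFrame | None = None,
    config: PipelineConfig | None = None,
    te_filter_superfamilies: Sequence[str] = ("ATHILA", "GYPSY"),
    family_superfamily: Mapping[str, str] | None = None,
) -> list[InsertionCall]:
    """Annotate every call with each triggered status flag.

    Flags: in_mask, inner_pericentromere, spans_donor (TSD within an
    annotated copy of the same family), in_control (matching call in a
    reference-accession run), coverage_outlier (total support beyond
    median + mad_k * MAD of genome coverage), high_frequency (carrier
    fraction >= cohort_freq_filter), in_te_annotation (overlap with any TE
    annotation, restricted to the configured superfamilies). Calls with no
    flag carry PASS.
    """
    config = config or PipelineConfig()
    control_keys = {
        (c.family, c.tsd_interval.chrom, c.tsd_interval.start, c.tsd_interval.end)
        for c in control_calls
    }
    for call in calls:
        flags: set[str] = set()
        tsd = call.tsd_interval
        if any(tsd.overlaps(m) for m in masks):
            flags.add("in_mask")
        if any(tsd.overlaps(p) for p in inner_pericentromeres):
            flags.add("inner_pericentromere")
        if any(
            a.family == call.family and a.interval.contains(tsd)
            for a in te_annotations
        ):
            flags.add("spans_donor")
        if (call.family, tsd.chrom, tsd.start, tsd.end) in control_keys:
            flags.add("in_control")
        if coverage_stats is not None:
            med, mad = coverage_stats
            if call.n_reads_left + call.n_reads_right > med + config.mad_k * mad:
                flags.add("coverage_outlier")
        if genotype_matrix is not None:
            key = call_id(call)
            if key in genotype_matrix.index:
                frac = genotype_matrix.loc[key].mean()
                if frac >= config.cohort_freq_filter:
                    flags.add("high_frequency")
        if te_filter_superfamilies:
            supf = family_superfamily or {}
            for a in te_annotations:
                a_sup = supf.get(a.family, a.family)
                if a_sup in te_filter_superfamilies and tsd.overlaps(a.interval):
                    flags.add("in_te_annotation")
                    break
        call.status = flags if flags else {"PASS"}
    return list(calls)


# --- genotyping and the allele-frequency spectrum ------------------------


def call_id(call: InsertionCall) -> str:
    iv = call.tsd_interval
    return f"{call.family}:{iv.chrom}:{iv.start}-{iv.end}"


def genotype_call(
    call: InsertionCall,
    evidences_by_accession: Mapping[str, Sequence[SplitReadEvidence]],
    config: PipelineConfig,
) -> tuple[pd.Series, pd.Series]:
    """Relaxed re-screening of one call across the cohort.

    An accession is marked present when at least min_reads_genotype split
    reads (either side) have junctions within the TSD interval plus a
    +-genotype_tolerance_bp margin. Returns (presence 0/1, support count)
    per accession; the discovery accession is present by construction.
    """
    tsd = call.tsd_interval
    lo = tsd.start - config.genotype_tolerance_bp
    hi = tsd.end + config.genotype_tolerance_bp
    presence: dict[str, int] = {}
    counts: dict[str, int] = {}
    for acc, evs in evidences_by_accession.items():
        n = sum(
            1
            for ev in evs
            if ev.family == call.family
            and ev.chrom == tsd.chrom
            and ev.junction is not None
            and lo <= ev.junction <= hi
        )
        counts[acc] = n
        presence[acc] = int(n >= config.min_reads_genotype)
    if call.discovered_in in presence:
        presence[call.discovered_in] = 1
    return pd.Series(presence, name=call_id(call)), pd.Series(counts, name=call_id(call))


def build_genotype_matrix(
    calls: Sequence[InsertionCall],
    evidences_by_accession: Mapping[str, Sequence[SplitReadEvidence]],
    config: PipelineConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Calls x accessions presence/absence (1/0) and support counts."""
    rows, count_rows = [], []
    for call in calls:
        presence, counts = genotype_call(call, evidences_by_accession, config)
        rows.append(presence)
        count_rows.append(counts)
    if not rows:
        empty = pd.DataFrame(columns=list(evidences_by_accession))
        return empty, empty.copy()
    return pd.DataFrame(rows), pd.DataFrame(count_rows)


def allele_frequency_spectrum(
    genotype_matrix: pd.DataFrame,
) -> tuple[dict[int, int], dict[str, int]]:
    """Histogram of carrier counts plus the private / 2-10 / >10 classes."""
    if genotype_matrix.empty:
        raise ValueError("empty genotype matrix")
    carriers = genotype_matrix.sum(axis=1).astype(int)
    histogram = dict(sorted(Counter(carriers).items()))
    classes = {
        "private": int((carriers == 1).sum()),
        "2-10": int(((carriers >= 2) & (carriers <= 10)).sum()),
        ">10": int((carriers > 10).sum()),
    }
    return histogram, classes
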