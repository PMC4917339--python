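"""Synthetic mobilome: reference genomes, TE families, accession genomes
with TSD-flanked planted insertions, paired-end reads, and the structured
CN/climate/kinship matrices used to calibrate the association tests.

Every generator is a pure function of (config, seed): rerunning with the
same inputs yields byte-identical output, which is what makes the planted
truth sets usable for parameter-recovery benchmarking.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import Genome, GenomicInterval, TEAnnotation, TEFamily, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    rng_seed: int = 0
    n_chroms: int = 5
    chrom_len_bp: int = 400_000
    gc_target: float = 0.36          # A. thaliana-like base composition
    n_families: int = 10
    read_len: int = 100
    mean_coverage: float = 25.0
    fragment_mean: float = 400.0
    fragment_sd: float = 50.0
    error_rate: float = 0.0          # per-base substitution probability
    insertions_per_accession: int = 30
    te_len_min: int = 800
    te_len_max: int = 3000
    extremity_len: int = 300
    min_site_spacing: int = 1000
    allow_short_fragments: bool = False

    def __post_init__(self) -> None:
        for name in ("gc_target", "error_rate"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"sim config: {name} must be in [0, 1]")
        for name in ("n_chroms", "chrom_len_bp", "n_families", "read_len",
                     "te_len_min", "te_len_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"sim config: {name} must be positive")
        if self.te_len_min < 2 * self.extremity_len:
            raise ValueError("te_len_min must be >= 2 * extremity_len")


@dataclass
class PlantedInsertion:
    """Truth record for one planted non-reference insertion.

    ``site`` is the TSD interval on the *reference* genome: the tsd_len
    reference bases duplicated on both sides of the inserted TE.
    """

    accession: str
    family: str
    site: GenomicInterval
    orientation: str
    tsd_seq: str


@dataclass
class ReadPair:
    read_id: str
    mate1_seq: str
    mate2_seq: str
    true_origin: tuple[str, str, int, int] = ("", "", 0, 0)  # accession, chrom, start, end


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return _BASES[idx].tobytes().decode()


def simulate_reference(cfg: SimConfig) -> Genome:
    """Random multi-chromosome reference at the configured GC content."""
    rng = np.random.default_rng(cfg.rng_seed)
    chroms = {
        f"chr{i + 1}": _random_seq(rng, cfg.chrom_len_bp, cfg.gc_target)
        for i in range(cfg.n_chroms)
    }
    return Genome(chroms)


_SUPERFAMILIES = ["COPIA", "GYPSY", "MUDR", "HAT", "LINE", "CACTA"]


def _extremity_identity(a: str, b: str) -> float:
    n = min(len(a), len(b))
    if n == 0:
        return 0.0
    matches = sum(x == y for x, y in zip(a[:n], b[:n]))
    return matches / n


def simulate_te_families(
    cfg: SimConfig, max_retries: int = 50
) -> tuple[list[TEFamily], dict[str, str]]:
    """Generate TE families with fixed TSD sizes (uniform on 3..15 bp).

    Returns (families, full-length sequence per family). Extremities are
    the first/last ``extremity_len`` bases of the family sequence;
    rejection sampling keeps any two families' extremity identity < 80%.
    """
    rng = np.random.default_rng(cfg.rng_seed + 1)
    families: list[TEFamily] = []
    seqs: dict[str, str] = {}
    for i in range(cfg.n_families):
        name = f"TEFAM{i + 1}"
        for attempt in range(max_retries):
            length = int(rng.integers(cfg.te_len_min, cfg.te_len_max + 1))
            seq = _random_seq(rng, length, cfg.gc_target)
            e5 = seq[: cfg.extremity_len]
            e3 = seq[-cfg.extremity_len :]
            ok = True
            for prev in families:
                for a in (e5, e3):
                    for b in (prev.extremity_5, prev.extremity_3):
                        if _extremity_identity(a, b) >= 0.8:
                            ok = False
            if ok:
                break
        else:
            raise RuntimeError(
                f"could not generate dissimilar extremities for {name} "
                f"after {max_retries} retries"
            )
        fam = TEFamily(
            name=name,
            te_class="I" if i % 2 == 0 else "II",
            superfamily=_SUPERFAMILIES[i % len(_SUPERFAMILIES)],
            tsd_len=int(rng.integers(3, 16)),
            extremity_5=e5,
            extremity_3=e3,
        )
        families.append(fam)
        seqs[name] = seq
    return families, seqs


def embed_reference_copies(
    genome: Genome,
    families: Sequence[TEFamily],
    te_seqs: dict[str, str],
    cfg: SimConfig,
    copies_per_family: int = 2,
    seed_offset: int = 2,
) -> tuple[Genome, list[TEAnnotation]]:
    """Place annotated donor copies of each family into the reference.

    Reference copies make TE-interior reads mappable (so only true
    junction reads stay unmapped) and provide the annotation set used for
    copy-number estimation and the spans_donor filter. Copies replace the
    underlying sequence so chromosome lengths are unchanged.
    """
    rng = np.random.default_rng(cfg.rng_seed + seed_offset)
    chroms = {name: bytearray(seq.encode()) for name, seq in genome.items()}
    names = list(chroms)
    lengths = np.array([len(chroms[n]) for n in names], dtype=float)
    annotations: list[TEAnnotation] = []
    occupied: dict[str, list[tuple[int, int]]] = {n: [] for n in names}
    for fam in families:
        seq = te_seqs[fam.name]
        for _ in range(copies_per_family):
            for _attempt in range(200):
                ci = int(rng.choice(len(names), p=lengths / lengths.sum()))
                chrom = names[ci]
                limit = len(chroms[chrom]) - len(seq)
                if limit <= 0:
                    continue
                start = int(rng.integers(0, limit))
                end = start + len(seq)
                pad = cfg.min_site_spacing
                if any(start < e + pad and s - pad < end for s, e in occupied[chrom]):
                    continue
                chroms[chrom][start:end] = seq.encode()
                occupied[chrom].append((start, end))
                annotations.append(
                    TEAnnotation(GenomicInterval(chrom, start, end), fam.name)
                )
                break
            else:
                raise RuntimeError(
                    f"no room to place reference copy of {fam.name}"
                )
    new_genome = Genome({n: bytes(b).decode() for n, b in chroms.items()})
    return new_genome, annotations


def plant_insertions(
    genome: Genome,
    families: Sequence[TEFamily],
    te_seqs: dict[str, str],
    cfg: SimConfig,
    exclusions: Sequence[GenomicInterval] = (),
    accession: str = "acc1",
    seed_offset: int = 10,
) -> tuple[Genome, list[PlantedInsertion]]:
    """Build an accession genome carrying TSD-flanked planted insertions.

    At each site the accession genome reads
    left flank + TSD + TE(orientation) + TSD + right flank, where the TSD
    is the reference's tsd_len bases at the site. Sites are pairwise at
    least ``min_site_spacing`` apart and avoid the exclusion zones.
    """
    rng = np.random.default_rng(cfg.rng_seed + seed_offset)
    usable = [f for f in families if f.tsd_len is not None]
    if not usable:
        raise ValueError("no TSD-creating families to plant")
    names = list(genome.chromosomes)
    lengths = np.array([genome.length(n) for n in names], dtype=float)
    sites: list[tuple[TEFamily, GenomicInterval, str]] = []
    chosen: dict[str, list[int]] = {n: [] for n in names}
    n_target = cfg.insertions_per_accession
    attempts = 0
    while len(sites) < n_target:
        attempts += 1
        if attempts > 500 * n_target:
            raise RuntimeError(
                "genome too small for requested insertions at the "
                "configured spacing"
            )
        fam = usable[int(rng.integers(len(usable)))]
        ci = int(rng.choice(len(names), p=lengths / lengths.sum()))
        chrom = names[ci]
        margin = cfg.extremity_len
        limit = genome.length(chrom) - fam.tsd_len - margin
        if limit <= margin:
            continue
        pos = int(rng.integers(margin, limit))
        if any(abs(pos - p) < cfg.min_site_spacing for p in chosen[chrom]):
            continue
        site = GenomicInterval(chrom, pos, pos + fam.tsd_len)
        if any(site.overlaps(ex) for ex in exclusions):
            continue
        orientation = "+" if rng.random() < 0.5 else "-"
        sites.append((fam, site, orientation))
        chosen[chrom].append(pos)

    planted: list[PlantedInsertion] = []
    new_chroms: dict[str, str] = {}
    by_chrom: dict[str, list[tuple[TEFamily, GenomicInterval, str]]] = {
        n: [] for n in names
    }
    for fam, site, orient in sites:
        by_chrom[site.chrom].append((fam, site, orient))
    for chrom in names:
        ref = genome[chrom]
        parts: list[str] = []
        prev = 0
        for fam, site, orient in sorted(by_chrom[chrom], key=lambda t: t[1].start):
            te = te_seqs[fam.name]
            if orient == "-":
                te = revcomp(te)
            parts.append(ref[prev : site.end])  # ends with the TSD
            parts.append(te)
            prev = site.start  # next part starts with the TSD again
            planted.append(
                PlantedInsertion(
                    accession=accession,
                    family=fam.name,
                    site=site,
                    orientation=orient,
                    tsd_seq=ref[site.start : site.end],
                )
            )
        parts.append(ref[prev:])
        new_chroms[chrom] = "".join(parts)
    planted.sort(key=lambda p: (p.site.chrom, p.site.start))
    return Genome(new_chroms), planted


def simulate_reads(
    genome: Genome, cfg: SimConfig, seed_offset: int = 20
) -> list[ReadPair]:
    """Paired-end reads in standard FR orientation with substitution errors.

    The expected pair count is coverage * genome_len / (2 * read_len);
    fragments shorter than 2 * read_len are disallowed unless
    ``allow_short_fragments`` is set.
    """
    rng = np.random.default_rng(cfg.rng_seed + seed_offset)
    names = list(genome.chromosomes)
    lengths = np.array([genome.length(n) for n in names], dtype=np.int64)
    total = int(lengths.sum())
    n_pairs = int(round(cfg.mean_coverage * total / (2 * cfg.read_len)))
    rl = cfg.read_len
    min_frag = rl if cfg.allow_short_fragments else 2 * rl

    chrom_idx = rng.choice(len(names), size=n_pairs, p=lengths / lengths.sum())
    frag_lens = np.maximum(
        min_frag,
        np.rint(rng.normal(cfg.fragment_mean, cfg.fragment_sd, size=n_pairs)).astype(
            np.int64
        ),
    )
    frag_lens = np.minimum(frag_lens, lengths[chrom_idx])
    starts = (rng.random(n_pairs) * (lengths[chrom_idx] - frag_lens + 1)).astype(
        np.int64
    )
    flip = rng.random(n_pairs) < 0.5

    pairs: list[ReadPair] = []
    for i in range(n_pairs):
        chrom = names[chrom_idx[i]]
        s, fl = int(starts[i]), int(frag_lens[i])
        left = genome[chrom][s : s + rl]
        right = revcomp(genome[chrom][s + fl - rl : s + fl])
        m1, m2 = (right, left) if flip[i] else (left, right)
        pairs.append(
            ReadPair(
                read_id=f"rp{i}",
                mate1_seq=m1,
                mate2_seq=m2,
                true_origin=("", chrom, s, s + fl),
            )
        )
    if cfg.error_rate > 0:
        _apply_errors(pairs, cfg.error_rate, rng)
    return pairs


def _apply_errors(pairs: list[ReadPair], rate: float, rng: np.random.Generator) -> None:
    for pair in pairs:
        for attr in ("mate1_seq", "mate2_seq"):
            seq = getattr(pair, attr)
            hits = np.nonzero(rng.random(len(seq)) < rate)[0]
            if len(hits) == 0:
                continue
            b = bytearray(seq.encode())
            for j in hits:
                old = b[j]
                choices = [x for x in b"ACGT" if x != old]
                b[j] = choices[int(rng.integers(3))]
            setattr(pair, attr, b.decode())


def simulate_gc_gradient_reference(
    cfg: SimConfig, gc_low: float = 0.25, gc_high: float = 0.55, block_bp: int = 2000
) -> Genome:
    """Reference whose GC content sweeps between ``gc_low`` and ``gc_high``
    in blocks — the substrate for GC-bias correction experiments."""
    rng = np.random.default_rng(cfg.rng_seed)
    chroms = {}
    for i in range(cfg.n_chroms):
        parts = []
        n_blocks = (cfg.chrom_len_bp + block_bp - 1) // block_bp
        for b in range(n_blocks):
            frac = 0.5 * (1 + np.sin(2 * np.pi * b / max(n_blocks - 1, 1) * 2))
            gc = gc_low + (gc_high - gc_low) * frac
            length = min(block_bp, cfg.chrom_len_bp - b * block_bp)
            parts.append(_random_seq(rng, length, gc))
        chroms[f"chr{i + 1}"] = "".join(parts)
    return Genome(chroms)


def apply_gc_bias(
    profile,
    rng: np.random.Generator,
    p_min: float = 0.1,
    p_max: float = 1.0,
    gc_low: float = 0.25,
    gc_high: float = 0.55,
):
    """Impose a GC-dependent sampling bias on a coverage profile,
    emulating library-prep GC bias.

    Each window's base count is binomially thinned with a retention
    probability interpolated linearly from ``p_min`` at ``gc_low`` to
    ``p_max`` at ``gc_high`` window GC — a strong (10x by default)
    monotone bias curve injected at the resolution the GC correction
    operates on. Returns a new profile with biased raw coverage (and the
    corrected values cleared)."""
    from copy import deepcopy

    biased = deepcopy(profile)
    biased.corr_rc = {}
    w = profile.window_bp
    for chrom, raw in profile.raw_rc.items():
        g = profile.gc_frac[chrom]
        t = np.clip((g - gc_low) / (gc_high - gc_low), 0.0, 1.0)
        p = p_min + (p_max - p_min) * t
        bases = np.rint(raw * w).astype(np.int64)
        biased.raw_rc[chrom] = rng.binomial(bases, p) / w
    return biased


def pairs_to_alignments(pairs: Sequence[ReadPair], read_len: int):
    """Truth-placement alignment records for simulated pairs (both mates,
    full-length M), for experiments that exercise coverage statistics
    rather than the aligner."""
    from .core import AlignmentRecord

    records = []
    for p in pairs:
        _, chrom, s, e = p.true_origin
        records.append(
            AlignmentRecord(
                p.read_id + "/1", "", mapped=True, ref_name=chrom, pos=s,
                cigar=[("M", read_len)], strand="+",
            )
        )
        records.append(
            AlignmentRecord(
                p.read_id + "/2", "", mapped=True, ref_name=chrom,
                pos=e - read_len, cigar=[("M", read_len)], strand="-",
                is_read1=False,
            )
        )
    return records


def pairs_to_reads(pairs: Sequence[ReadPair]) -> list[tuple[str, str]]:
    """Flatten mate pairs to (read_id, seq); mate identity is not used by
    the caller (discordant-pair information is deliberately ignored)."""
    reads: list[tuple[str, str]] = []
    for p in pairs:
        reads.append((p.read_id + "/1", p.mate1_seq))
        reads.append((p.read_id + "/2", p.mate2_seq))
    return reads


def simulate_structured_matrices(
    n_accessions: int,
    n_families: int,
    effect_size: float,
    seed: int = 0,
    pop_shift: float = 2.0,
    structure_sd: float = 0.5,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Copy-number, climate and kinship matrices with 2-population structure.

    Climate tracks the population label (shift ``pop_shift``); per-family
    CN is baseline + effect_size * climate + a population term
    (``structure_sd``) + unit Gaussian noise. With effect_size = 0 the CN
    association with climate runs entirely through population structure,
    giving the null for partial-Mantel calibration.
    """
    if n_accessions < 10:
        raise ValueError("need at least 10 accessions")
    rng = np.random.default_rng(seed)
    acc = [f"acc{i + 1}" for i in range(n_accessions)]
    pop = np.zeros(n_accessions, dtype=int)
    pop[n_accessions // 2 :] = 1
    climate = pop_shift * pop + rng.normal(size=n_accessions)
    cn = np.empty((n_families, n_accessions))
    for f in range(n_families):
        cn[f] = (
            10.0
            + effect_size * climate
            + structure_sd * pop
            + rng.normal(size=n_accessions)
        )
    same_pop = pop[:, None] == pop[None, :]
    kinship = np.where(same_pop, 0.5, 0.1)
    np.fill_diagonal(kinship, 1.0)
    fam_names = [f"TEFAM{i + 1}" for i in range(n_families)]
    return (
        pd.DataFrame(cn, index=fam_names, columns=acc),
        pd.Series(climate, index=acc, name="climate"),
        pd.DataFrame(kinship, index=acc, columns=acc),
    )
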