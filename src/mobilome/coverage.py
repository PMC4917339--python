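"""Binned read coverage, GC correction, aberrant-region masking and
family-level copy-number estimation with a permutation test and empirical
FDR.

Depth is base-resolution: a window's raw coverage is the number of aligned
reference bases (M/D CIGAR ops) overlapping the window divided by the
window width, computed in non-overlapping 100-bp windows. Copy number per
TE family is aggregated over a "joined pseudo-annotation" of the family's
annotated copies longer than a length cutoff, normalized by each sample's
genome-wide median coverage and calibrated against the number of annotated
reference copies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import (
    AlignmentRecord,
    Genome,
    GenomicInterval,
    PipelineConfig,
    TEAnnotation,
)


@dataclass
class CoverageProfile:
    """Per-accession windowed coverage.

    Arrays are per chromosome, one entry per non-overlapping window of
    ``window_bp`` (the terminal window may be shorter).
    """

    accession: str
    window_bp: int
    chrom_lengths: dict[str, int]
    raw_rc: dict[str, np.ndarray]
    gc_frac: dict[str, np.ndarray]
    corr_rc: dict[str, np.ndarray] = field(default_factory=dict)

    def all_values(self, corrected: bool = True) -> np.ndarray:
        src = self.corr_rc if (corrected and self.corr_rc) else self.raw_rc
        return np.concatenate([src[c] for c in sorted(src)])

    @property
    def genome_median_rc(self) -> float:
        return float(np.median(self.all_values()))

    def n_windows(self, chrom: str) -> int:
        return len(self.raw_rc[chrom])

    def window_interval(self, chrom: str, i: int) -> GenomicInterval:
        start = i * self.window_bp
        end = min(start + self.window_bp, self.chrom_lengths[chrom])
        return GenomicInterval(chrom, start, end)


@dataclass(frozen=True)
class MaskSegment:
    interval: GenomicInterval
    reason: str  # high_coverage / low_coverage / low_complexity


@dataclass
class CNVCall:
    accession: str
    family: str
    cn_est: float
    p_value: float
    fdr: float
    significant: bool


def bin_coverage(
    alignments: Sequence[AlignmentRecord],
    genome: Genome,
    config: PipelineConfig,
    accession: str = "sample",
) -> CoverageProfile:
    """Base-resolution coverage in non-overlapping windows.

    Records flagged as duplicates and unmapped records are skipped. An
    alignment naming a chromosome absent from the genome is an error.
    """
    w = config.window_bp
    depth_diff: dict[str, np.ndarray] = {
        name: np.zeros(genome.length(name) + 1, dtype=np.int64)
        for name in genome
    }
    bad_chroms: set[str] = set()
    for rec in alignments:
        if not rec.mapped or rec.is_duplicate:
            continue
        if rec.ref_name not in depth_diff:
            bad_chroms.add(rec.ref_name)
            continue
        diff = depth_diff[rec.ref_name]
        clen = genome.length(rec.ref_name)
        for s, e in rec.ref_blocks():
            s = max(0, s)
            e = min(e, clen)
            if s < e:
                diff[s] += 1
                diff[e] -= 1
    if bad_chroms:
        raise ValueError(
            "alignments reference chromosomes absent from the genome: "
            + ", ".join(sorted(bad_chroms))
        )

    raw: dict[str, np.ndarray] = {}
    gc: dict[str, np.ndarray] = {}
    for name in genome:
        depth = np.cumsum(depth_diff[name][:-1])
        clen = genome.length(name)
        n_win = (clen + w - 1) // w
        edges = np.arange(0, n_win + 1) * w
        edges[-1] = clen
        csum = np.concatenate([[0], np.cumsum(depth)])
        widths = np.diff(edges)
        raw[name] = (csum[edges[1:]] - csum[edges[:-1]]) / widths
        codes = np.frombuffer(genome[name].encode(), dtype=np.uint8)
        is_gc = ((codes == ord("G")) | (codes == ord("C"))).astype(np.int64)
        gsum = np.concatenate([[0], np.cumsum(is_gc)])
        gc[name] = (gsum[edges[1:]] - gsum[edges[:-1]]) / widths
    return CoverageProfile(
        accession=accession,
        window_bp=w,
        chrom_lengths={name: genome.length(name) for name in genome},
        raw_rc=raw,
        gc_frac=gc,
    )


def gc_correct(
    profile: CoverageProfile, config: PipelineConfig, min_bin_windows: int = 10
) -> CoverageProfile:
    """Median-ratio GC correction.

    corr = raw * m / m_GC where m is the genome-wide median raw coverage
    and m_GC the median over windows sharing this window's integer GC
    percent; GC bins with fewer than ``min_bin_windows`` windows (or a
    zero median) fall back to the uncorrected value.
    """
    all_raw = np.concatenate([profile.raw_rc[c] for c in sorted(profile.raw_rc)])
    all_gc = np.concatenate([profile.gc_frac[c] for c in sorted(profile.gc_frac)])
    m = float(np.median(all_raw))
    if m == 0:
        raise ValueError("degenerate profile: genome-wide median coverage is zero")
    gc_pct = np.rint(all_gc * 100).astype(int)
    factor = np.ones(101)
    for pct in np.unique(gc_pct):
        sel = gc_pct == pct
        if sel.sum() < min_bin_windows:
            continue
        m_gc = float(np.median(all_raw[sel]))
        if m_gc > 0:
            factor[pct] = m / m_gc
    for chrom in profile.raw_rc:
        pct = np.rint(profile.gc_frac[chrom] * 100).astype(int)
        profile.corr_rc[chrom] = profile.raw_rc[chrom] * factor[pct]
    return profile


def _unscaled_mad(values: np.ndarray) -> tuple[float, float]:
    med = float(np.median(values))
    return med, float(np.median(np.abs(values - med)))


def detect_aberrant_regions(
    profile_a: CoverageProfile,
    profile_b: CoverageProfile,
    config: PipelineConfig,
) -> list[MaskSegment]:
    """Coverage-outlier mask from two reference-accession control profiles.

    A window is flagged when its corrected coverage deviates from the
    genome-wide median by more than mad_k unscaled MADs in either control;
    runs of flagged windows (allowing a single-window gap) merge into one
    segment.
    """
    stats = {}
    for prof in (profile_a, profile_b):
        stats[id(prof)] = _unscaled_mad(prof.all_values())
    segments: list[MaskSegment] = []
    w = config.window_bp
    for chrom in profile_a.raw_rc:
        n = profile_a.n_windows(chrom)
        flagged = np.zeros(n, dtype=bool)
        high = np.zeros(n, dtype=bool)
        for prof in (profile_a, profile_b):
            med, mad = stats[id(prof)]
            vals = (prof.corr_rc or prof.raw_rc)[chrom]
            dev = np.abs(vals - med) > config.mad_k * mad
            flagged |= dev
            high |= dev & (vals > med)
        idx = np.nonzero(flagged)[0]
        if len(idx) == 0:
            continue
        run_start = idx[0]
        prev = idx[0]
        for i in list(idx[1:]) + [None]:
            if i is not None and i - prev <= 2:  # one unflagged window gap
                prev = i
                continue
            start = run_start * w
            end = min((prev + 1) * w, profile_a.chrom_lengths[chrom])
            reason = (
                "high_coverage"
                if high[run_start : prev + 1].any()
                else "low_coverage"
            )
            segments.append(MaskSegment(GenomicInterval(chrom, start, end), reason))
            if i is not None:
                run_start = prev = i
    return segments


def _pseudo_annotation_windows(
    profile: CoverageProfile,
    annotations: Sequence[TEAnnotation],
    family: str,
    masks: Sequence[MaskSegment],
    config: PipelineConfig,
    gwas_mode: bool = False,
    consensus_len: int | None = None,
) -> tuple[list[tuple[str, int]], int]:
    """Windows overlapping the family's retained copies, minus masked ones."""
    if gwas_mode:
        if consensus_len is None:
            raise ValueError("gwas_mode requires the family consensus length")
        min_len = consensus_len / 2
    else:
        min_len = config.min_te_len_cnv
    copies = [
        a for a in annotations if a.family == family and a.copy_length >= min_len
    ]
    w = profile.window_bp
    windows: set[tuple[str, int]] = set()
    for a in copies:
        chrom = a.interval.chrom
        if chrom not in profile.raw_rc:
            continue
        first = a.interval.start // w
        last = (a.interval.end - 1) // w
        for i in range(first, min(last + 1, profile.n_windows(chrom))):
            windows.add((chrom, i))
    masked: set[tuple[str, int]] = set()
    for seg in masks:
        chrom = seg.interval.chrom
        if chrom not in profile.raw_rc:
            continue
        first = seg.interval.start // w
        last = (seg.interval.end - 1) // w
        for i in range(first, last + 1):
            masked.add((chrom, i))
    return sorted(windows - masked), len(copies)


def family_copy_number(
    profile: CoverageProfile,
    annotations: Sequence[TEAnnotation],
    family: str,
    reference_profile: CoverageProfile,
    config: PipelineConfig,
    masks: Sequence[MaskSegment] = (),
    gwas_mode: bool = False,
    consensus_len: int | None = None,
) -> float | None:
    """Aggregated copy number of a TE family in one accession.

    cn = n_ref_copies * [sum_w corr(acc, w) / median(acc)]
                      / [sum_w corr(ref, w) / median(ref)]
    over the family's pseudo-annotation windows. Returns None when the
    family is untestable (no retained copies / windows, or zero reference
    signal).
    """
    windows, n_copies = _pseudo_annotation_windows(
        profile, annotations, family, masks, config, gwas_mode, consensus_len
    )
    if not windows or n_copies == 0:
        return None
    acc_corr = profile.corr_rc or profile.raw_rc
    ref_corr = reference_profile.corr_rc or reference_profile.raw_rc
    acc_med = profile.genome_median_rc
    ref_med = reference_profile.genome_median_rc
    if acc_med <= 0 or ref_med <= 0:
        return None
    num = sum(acc_corr[c][i] for c, i in windows) / acc_med
    den = sum(ref_corr[c][i] for c, i in windows) / ref_med
    if den <= 0:
        return None
    return n_copies * num / den


def pseudo_annotation_values(
    profile: CoverageProfile,
    annotations: Sequence[TEAnnotation],
    family: str,
    config: PipelineConfig,
    masks: Sequence[MaskSegment] = (),
) -> np.ndarray:
    """Per-window normalized coverage over a family's pseudo-annotation."""
    windows, _ = _pseudo_annotation_windows(profile, annotations, family, masks, config)
    med = profile.genome_median_rc
    corr = profile.corr_rc or profile.raw_rc
    if med <= 0:
        raise ValueError("degenerate profile: zero genome median")
    return np.array([corr[c][i] / med for c, i in windows])


def mean_diff_permutation_p(
    acc_values: np.ndarray,
    ref_values: np.ndarray,
    n_perm: int,
    seed: int,
) -> float:
    """Paired-window label-swap permutation p for one reference.

    The statistic is |mean(acc) - mean(ref)|; the null swaps the
    accession/reference labels independently within each window (the
    windows pair naturally — they are the same loci in both samples).
    +1-corrected, so never exactly zero.
    """
    acc_values = np.asarray(acc_values, dtype=float)
    ref_values = np.asarray(ref_values, dtype=float)
    if len(ref_values) != len(acc_values):
        raise ValueError("window sets must be equal across samples")
    rng = np.random.default_rng(seed)
    diff = acc_values - ref_values
    obs = abs(diff.mean())
    signs = rng.integers(0, 2, size=(n_perm, len(diff))) * 2 - 1
    null = np.abs((signs * diff).mean(axis=1))
    return (1 + int((null >= obs - 1e-12).sum())) / (1 + n_perm)


def cnv_permutation_test(
    acc_values: np.ndarray,
    ref_values_a: np.ndarray,
    ref_values_b: np.ndarray,
    n_perm: int,
    seed: int,
) -> float | None:
    """Distribution-independent permutation test of accession vs the two
    reference replicates over paired pseudo-annotation windows.

    Runs :func:`mean_diff_permutation_p` against each reference and
    returns the maximum of the two p-values — the stringent choice, which
    makes the combined p super-uniform under the null by construction.
    Fewer than two windows -> untestable (None).
    """
    acc_values = np.asarray(acc_values, dtype=float)
    if len(acc_values) < 2:
        return None
    rng = np.random.default_rng(seed)
    p_a = mean_diff_permutation_p(
        acc_values, ref_values_a, n_perm, int(rng.integers(2**31))
    )
    p_b = mean_diff_permutation_p(
        acc_values, ref_values_b, n_perm, int(rng.integers(2**31))
    )
    return max(p_a, p_b)


def cnv_null_pvalues(
    acc_all: np.ndarray,
    ref_a_all: np.ndarray,
    ref_b_all: np.ndarray,
    n_windows: int,
    n_draws: int,
    n_perm: int,
    seed: int,
) -> np.ndarray:
    """Empirical null p-value sample by randomizing annotation labels:
    each draw assigns a random set of ``n_windows`` genome-wide windows to
    a fictive family and reruns the permutation test."""
    rng = np.random.default_rng(seed)
    out = np.empty(n_draws)
    n_total = len(acc_all)
    for d in range(n_draws):
        idx = rng.choice(n_total, size=n_windows, replace=False)
        p = cnv_permutation_test(
            acc_all[idx], ref_a_all[idx], ref_b_all[idx], n_perm,
            seed=int(rng.integers(2**31)),
        )
        out[d] = 1.0 if p is None else p
    return out


def empirical_fdr(observed_p: float, null_p_sample: np.ndarray) -> float:
    """Fraction of the randomized null at or below the observed p-value."""
    null_p_sample = np.asarray(null_p_sample)
    if null_p_sample.size == 0:
        raise ValueError("empty null p-value sample")
    return float((null_p_sample <= observed_p).mean())


def cnv_test_family(
    accession: str,
    family: str,
    profile: CoverageProfile,
    ref_profile_a: CoverageProfile,
    ref_profile_b: CoverageProfile,
    annotations: Sequence[TEAnnotation],
    config: PipelineConfig,
    null_p_sample: np.ndarray,
    masks: Sequence[MaskSegment] = (),
    seed: int = 0,
) -> CNVCall | None:
    """Full per-family CNV decision for one accession."""
    acc_vals = pseudo_annotation_values(profile, annotations, family, config, masks)
    a_vals = pseudo_annotation_values(ref_profile_a, annotations, family, config, masks)
    b_vals = pseudo_annotation_values(ref_profile_b, annotations, family, config, masks)
    p = cnv_permutation_test(acc_vals, a_vals, b_vals, config.n_perm, seed)
    if p is None:
        return None
    cn = family_copy_number(
        profile, annotations, family, ref_profile_a, config, masks
    )
    if cn is None:
        return None
    fdr = empirical_fdr(p, null_p_sample)
    return CNVCall(
        accession=accession,
        family=family,
        cn_est=cn,
        p_value=p,
        fdr=fdr,
        significant=fdr < config.cnv_fdr_threshold,
    )
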