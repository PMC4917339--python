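"""Downstream mobilome statistics.

Positional randomization nulls and enrichment tests, metagene assignment,
the carrier/non-carrier expression-ratio permutation test, methylation-
spreading classification, the kinship-controlled partial Mantel climate
association, two closed-form quantities, and truth-set benchmarking.

All permutation p-values carry the +1 correction (never exactly zero).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import GeneModel, Genome, GenomicInterval, PipelineConfig, merge_intervals

# --- positional randomization --------------------------------------------


class RandomizationNull:
    """Uniform placements over the genome minus exclusion zones.

    Placements are drawn per allowed base, so the expected count in any
    region is proportional to its unmasked length.
    """

    def __init__(
        self,
        genome_lengths: Mapping[str, int],
        exclusions: Sequence[GenomicInterval] = (),
        n_iterations: int = 10_000,
        seed: int = 0,
    ):
        self.n_iterations = n_iterations
        self.seed = seed
        merged = merge_intervals(exclusions) if exclusions else []
        allowed: list[tuple[str, int, int]] = []
        for chrom, length in genome_lengths.items():
            cursor = 0
            for ex in [m for m in merged if m.chrom == chrom]:
                if ex.start > cursor:
                    allowed.append((chrom, cursor, min(ex.start, length)))
                cursor = max(cursor, ex.end)
            if cursor < length:
                allowed.append((chrom, cursor, length))
        self.allowed = allowed
        if not allowed:
            raise ValueError("allowed space is empty")
        self._lens = np.array([e - s for _, s, e in allowed], dtype=np.int64)
        self._cum = np.concatenate([[0], np.cumsum(self._lens)])
        self.total_allowed = int(self._cum[-1])

    def draw_offsets(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Global offsets into the concatenated allowed space."""
        return rng.integers(0, self.total_allowed, size=n)

    def offsets_to_positions(self, offsets: np.ndarray) -> list[tuple[str, int]]:
        seg = np.searchsorted(self._cum, offsets, side="right") - 1
        out = []
        for s, off in zip(seg, offsets):
            chrom, start, _ = self.allowed[s]
            out.append((chrom, int(start + off - self._cum[s])))
        return out

    def sample_positions(self, n: int, iteration: int) -> list[tuple[str, int]]:
        rng = np.random.default_rng((self.seed, iteration))
        return self.offsets_to_positions(self.draw_offsets(n, rng))

    def region_membership_offsets(
        self, regions: Sequence[GenomicInterval]
    ) -> np.ndarray:
        """Boolean mask over the concatenated allowed space: which allowed
        bases fall inside ``regions`` (vectorized region counting)."""
        merged = merge_intervals(regions)
        mask = np.zeros(self.total_allowed, dtype=bool)
        for si, (chrom, start, end) in enumerate(self.allowed):
            base = int(self._cum[si])
            for r in merged:
                if r.chrom != chrom:
                    continue
                lo = max(start, r.start)
                hi = min(end, r.end)
                if lo < hi:
                    mask[base + (lo - start) : base + (hi - start)] = True
        return mask


def randomize_positions(
    n: int,
    genome: "Genome | Mapping[str, int]",
    exclusions: Sequence[GenomicInterval],
    n_iter: int,
    seed: int,
) -> RandomizationNull:
    lengths = (
        {name: genome.length(name) for name in genome}
        if isinstance(genome, Genome)
        else dict(genome)
    )
    null = RandomizationNull(lengths, exclusions, n_iterations=n_iter, seed=seed)
    null.n_items = n
    return null


@dataclass
class EnrichmentResult:
    observed: float
    expected_mean: float
    ci_low: float
    ci_high: float
    o_over_e: float
    p_value: float


def _positions_in_regions(
    positions: Sequence[tuple[str, int]], regions: Sequence[GenomicInterval]
) -> int:
    merged = merge_intervals(regions)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in merged:
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    count = 0
    for chrom, pos in positions:
        for s, e in by_chrom.get(chrom, ()):
            if s <= pos < e:
                count += 1
                break
    return count


def pericentromere_test(
    calls_by_class: Mapping[str, Sequence[tuple[str, int]]],
    pericentromeres: Sequence[GenomicInterval],
    null: RandomizationNull,
) -> tuple[dict[str, EnrichmentResult], float]:
    """Per allele-count class, observed pericentromeric fraction vs the
    randomization null, plus an overall chi-square on pooled counts."""
    if null.n_iterations <= 0:
        raise ValueError("randomization null has no iterations")
    mask = null.region_membership_offsets(pericentromeres)
    p_in = mask.mean()
    rng = np.random.default_rng(null.seed)
    results: dict[str, EnrichmentResult] = {}
    total_obs_in = 0
    total_n = 0
    for klass, positions in calls_by_class.items():
        n = len(positions)
        if n == 0:
            continue
        obs_in = _positions_in_regions(positions, pericentromeres)
        total_obs_in += obs_in
        total_n += n
        offsets = rng.integers(0, null.total_allowed, size=(null.n_iterations, n))
        null_frac = mask[offsets].mean(axis=1)
        obs_frac = obs_in / n
        exp = float(null_frac.mean())
        lo, hi = np.quantile(null_frac, [0.025, 0.975])
        tail = min(
            (1 + int((null_frac >= obs_frac).sum())),
            (1 + int((null_frac <= obs_frac).sum())),
        ) / (1 + null.n_iterations)
        results[klass] = EnrichmentResult(
            observed=obs_frac,
            expected_mean=exp,
            ci_low=float(lo),
            ci_high=float(hi),
            o_over_e=obs_frac / exp if exp > 0 else math.inf,
            p_value=min(1.0, 2 * tail),
        )
    if total_n == 0:
        raise ValueError("no calls in any stratum")
    expected = np.array([total_n * p_in, total_n * (1 - p_in)])
    observed = np.array([total_obs_in, total_n - total_obs_in])
    chi_p = float(sps.chisquare(observed, expected).pvalue)
    return results, chi_p


def window_enrichment(
    positions: Sequence[tuple[str, int]],
    genome_lengths: Mapping[str, int],
    null: RandomizationNull,
    config: PipelineConfig,
) -> list[tuple[GenomicInterval, int, float]]:
    """Windows whose insertion count sits in the configured upper tail of
    the pooled null per-window count distribution.

    Returns (window, observed count, empirical upper-tail probability) for
    each enriched window.
    """
    w = config.enrich_window_bp
    chroms = sorted(genome_lengths)
    n_win = {c: (genome_lengths[c] + w - 1) // w for c in chroms}
    win_offset = {}
    total_windows = 0
    for c in chroms:
        win_offset[c] = total_windows
        total_windows += n_win[c]

    def window_ids(pos_list: Sequence[tuple[str, int]]) -> np.ndarray:
        return np.array(
            [win_offset[c] + p // w for c, p in pos_list if c in win_offset],
            dtype=np.int64,
        )

    obs_counts = np.bincount(window_ids(positions), minlength=total_windows)

    n = len(positions)
    rng = np.random.default_rng(null.seed)
    # pooled null per-window counts over all iterations (zeros included)
    max_count = 0
    tally: dict[int, int] = {}
    seg_chrom = [chrom for chrom, _, _ in null.allowed]
    seg_start = np.array([s for _, s, _ in null.allowed])
    for _ in range(null.n_iterations):
        offsets = null.draw_offsets(n, rng)
        seg = np.searchsorted(null._cum, offsets, side="right") - 1
        gpos = seg_start[seg] + (offsets - null._cum[seg])
        wid = np.array(
            [win_offset[seg_chrom[s]] for s in seg], dtype=np.int64
        ) + gpos // w
        counts = np.bincount(wid)
        for c in np.unique(counts[counts > 0]):
            tally[int(c)] = tally.get(int(c), 0) + int((counts == c).sum())
        max_count = max(max_count, int(counts.max(initial=0)))
    pooled_total = null.n_iterations * total_windows
    nonzero = sum(tally.values())
    tally[0] = pooled_total - nonzero
    # survival: fraction of pooled null window counts >= x
    counts_sorted = sorted(tally)
    sf = {}
    running = 0
    for c in sorted(tally, reverse=True):
        running += tally[c]
        sf[c] = running / pooled_total

    def survival(x: int) -> float:
        vals = [c for c in counts_sorted if c >= x]
        if not vals:
            return 0.0
        return sf[min(vals)]

    enriched = []
    for c in chroms:
        for i in range(n_win[c]):
            cnt = int(obs_counts[win_offset[c] + i])
            if cnt == 0:
                continue
            p_tail = survival(cnt)
            if p_tail <= config.enrich_tail:
                iv = GenomicInterval(c, i * w, min((i + 1) * w, genome_lengths[c]))
                enriched.append((iv, cnt, p_tail))
    return enriched


# --- metagene assignment --------------------------------------------------

_HIERARCHY = ("five_prime_UTR", "three_prime_UTR", "exon", "intron")


def metagene_assign(
    chrom: str, pos: int, gene_models: Sequence[GeneModel]
) -> tuple[str, int | None, str | None]:
    """Assign a position to the genic feature hierarchy.

    Returns (feature class, signed distance, gene id). Positions inside a
    gene follow the stepwise hierarchy 5'UTR > 3'UTR > exon > intron (a
    position inside the gene but in no annotated feature counts as
    intron). Intergenic positions get the distance to the closest gene,
    negative when upstream of the gene's 5' end in the gene's orientation.
    """
    kinds_here: list[tuple[int, str]] = []
    for gene in gene_models:
        if not gene.interval.contains_pos(chrom, pos):
            continue
        hit = False
        for kind, iv in gene.features:
            if iv.contains_pos(chrom, pos):
                kinds_here.append((_HIERARCHY.index(kind), gene.gene_id))
                hit = True
        if not hit:
            kinds_here.append((_HIERARCHY.index("intron"), gene.gene_id))
    if kinds_here:
        rank, gid = min(kinds_here)
        return _HIERARCHY[rank], None, gid
    # intergenic: nearest gene on this chromosome
    best: tuple[int, GeneModel] | None = None
    for gene in gene_models:
        if gene.interval.chrom != chrom:
            continue
        d = max(gene.interval.start - pos, pos - (gene.interval.end - 1), 0)
        if best is None or d < best[0]:
            best = (d, gene)
    if best is None:
        return "intergenic", None, None
    d, gene = best
    if gene.interval.strand == "+":
        signed = -d if pos < gene.interval.start else d
    else:
        signed = -d if pos >= gene.interval.end else d
    return "intergenic", signed, gene.gene_id


# --- expression-ratio permutation test -----------------------------------


@dataclass
class ExpressionImpact:
    gene_id: str
    call_id: str
    ratio: float
    n_carriers: int


def genes_near_calls(
    gene_models: Sequence[GeneModel],
    call_intervals: Mapping[str, GenomicInterval],
    within_bp: int = 1000,
) -> dict[str, str]:
    """Genes with an insertion call within ``within_bp`` -> call id."""
    out: dict[str, str] = {}
    for gene in gene_models:
        gi = gene.interval
        for cid, iv in call_intervals.items():
            if iv.chrom != gi.chrom:
                continue
            if iv.start < gi.end + within_bp and gi.start - within_bp < iv.end:
                out[gene.gene_id] = cid
                break
    return out


def expression_ratio_test(
    expression: pd.DataFrame,
    genotypes: pd.DataFrame,
    gene_to_call: Mapping[str, str],
    n_iter: int = 10_000,
    seed: int = 0,
) -> tuple[list[ExpressionImpact], float, float, np.ndarray]:
    """Carrier/non-carrier expression ratios vs a label-randomized null.

    For each gene near a call, the statistic is the ratio of the carrier
    median to the non-carrier median expression (genes whose non-carrier
    median is zero are excluded). The null draws ``n_iter`` random gene
    sets of the same size and reassigns carrier labels uniformly at
    random, preserving each call's carrier count; observed and pooled null
    ratio distributions are compared with a two-sample KS test.

    Returns (impacts, ks statistic, ks p-value, null ratio sample).
    """
    rng = np.random.default_rng(seed)
    accs = list(expression.columns)
    genotypes = genotypes.reindex(columns=accs)
    impacts: list[ExpressionImpact] = []
    carrier_counts: list[int] = []
    for gene_id, cid in gene_to_call.items():
        if gene_id not in expression.index or cid not in genotypes.index:
            continue
        geno = genotypes.loc[cid].to_numpy()
        expr = expression.loc[gene_id].to_numpy(dtype=float)
        carriers = geno == 1
        k = int(carriers.sum())
        if k == 0 or k == len(accs):
            continue
        non_med = float(np.median(expr[~carriers]))
        if non_med == 0:
            continue
        ratio = float(np.median(expr[carriers])) / non_med
        impacts.append(ExpressionImpact(gene_id, cid, ratio, k))
        carrier_counts.append(k)
    if not impacts:
        raise ValueError("no testable genes (all excluded)")

    n_genes = len(impacts)
    expr_mat = expression.to_numpy(dtype=float)
    n_all, n_acc = expr_mat.shape
    null_ratios = np.empty(n_iter * n_genes)
    ks = np.asarray(carrier_counts)
    chunk = max(1, int(2e6 // n_acc))
    samples = [(i, g) for i in range(n_iter) for g in range(n_genes)]
    pos = 0
    for start in range(0, len(samples), chunk):
        batch = samples[start : start + chunk]
        m = len(batch)
        gene_idx = rng.integers(0, n_all, size=m)
        k_batch = np.array([ks[g] for _, g in batch])
        order = np.argsort(rng.random((m, n_acc)), axis=1)
        rows = expr_mat[gene_idx]
        shuffled = np.take_along_axis(rows, order, axis=1)
        for j in range(m):
            k = k_batch[j]
            med_c = np.median(shuffled[j, :k])
            med_n = np.median(shuffled[j, k:])
            null_ratios[pos] = med_c / med_n if med_n != 0 else np.nan
            pos += 1
    null_ratios = null_ratios[np.isfinite(null_ratios)]
    obs = np.array([im.ratio for im in impacts])
    ks_res = sps.ks_2samp(obs, null_ratios)
    return impacts, float(ks_res.statistic), float(ks_res.pvalue), null_ratios


# --- methylation spreading ------------------------------------------------


@dataclass
class MethylationSpread:
    call_id: str
    side: str  # left | right
    extent_bp: int
    klass: str  # none | short | intermediate | long


def methylation_spread_classify(
    carrier_profile: np.ndarray,
    noncarrier_profile: np.ndarray,
    config: PipelineConfig,
    call_id: str = "",
    side: str = "right",
) -> MethylationSpread:
    """Classify how far TE-associated methylation spreads into the flank.

    Profiles are per-window (meth_window_bp) cohort averages ordered
    outward from the TSD. The extent is the distance to the first of two
    consecutive windows where the carrier minus non-carrier difference
    drops below the threshold; classes are none (no spread), short
    (<= spread_short_bp), intermediate, and long (> spread_long_bp).
    """
    carrier = np.asarray(carrier_profile, dtype=float)
    non = np.asarray(noncarrier_profile, dtype=float)
    if carrier.shape != non.shape:
        raise ValueError("cohort profiles must have equal length")
    below = (carrier - non) < config.meth_diff_threshold
    n = len(below)
    extent_windows = n
    for i in range(n - 1):
        if below[i] and below[i + 1]:
            extent_windows = i
            break
    if n == 1 and below[0]:
        extent_windows = 0
    extent = extent_windows * config.meth_window_bp
    if extent == 0:
        klass = "none"
    elif extent <= config.spread_short_bp:
        klass = "short"
    elif extent <= config.spread_long_bp:
        klass = "intermediate"
    else:
        klass = "long"
    return MethylationSpread(call_id=call_id, side=side, extent_bp=extent, klass=klass)


# --- partial Mantel -------------------------------------------------------


@dataclass
class MantelResult:
    family: str
    r_partial: float
    p_value: float
    n_permutations: int


def _upper(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(mat.shape[0], 1)
    return mat[iu]


def _safe_r(a: np.ndarray, b: np.ndarray) -> float:
    # correlation with a constant vector carries no information -> 0
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _partial_r(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> float:
    r_xy = _safe_r(x, y)
    r_xz = _safe_r(x, z)
    r_yz = _safe_r(y, z)
    denom = math.sqrt((1 - r_xz**2) * (1 - r_yz**2))
    if denom == 0:
        return 0.0
    return (r_xy - r_xz * r_yz) / denom


def partial_mantel(
    cn_vector: Sequence[float] | pd.Series,
    climate_vector: Sequence[float] | pd.Series,
    kinship: np.ndarray | pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
    family: str = "",
) -> MantelResult:
    """Partial Mantel correlation between copy-number and climate
    distances, controlling for kinship.

    CN and climate distances are absolute pairwise differences; kinship
    becomes a distance as 1 - kinship. Significance comes from permuting
    the accession order of the CN distance matrix; the p-value is
    two-sided on |r| with the +1 correction.
    """
    cn = np.asarray(cn_vector, dtype=float)
    cl = np.asarray(climate_vector, dtype=float)
    k = np.asarray(kinship, dtype=float)
    n = len(cn)
    if n < 6:
        raise ValueError(
            "need at least 6 accessions (and ~10+ for useful permutation "
            "resolution)"
        )
    if np.isnan(cn).any() or np.isnan(cl).any() or np.isnan(k).any():
        raise ValueError("missing values are not allowed")
    dx = np.abs(cn[:, None] - cn[None, :])
    dy = np.abs(cl[:, None] - cl[None, :])
    dz = 1.0 - k
    x, y, z = _upper(dx), _upper(dy), _upper(dz)
    r_obs = _partial_r(x, y, z)
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        xp = _upper(dx[np.ix_(perm, perm)])
        if abs(_partial_r(xp, y, z)) >= abs(r_obs) - 1e-12:
            n_ge += 1
    p = (1 + n_ge) / (1 + n_perm)
    return MantelResult(family=family, r_partial=float(r_obs), p_value=p, n_permutations=n_perm)


# --- closed forms ---------------------------------------------------------


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test threshold alpha / m."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def variance_explained(maf: float, beta: float, var_y: float) -> float:
    """Fraction of phenotypic variance explained by one SNP:
    2 * MAF * (1 - MAF) * beta^2 / var_y."""
    if not (0 < maf <= 0.5):
        raise ValueError("maf must be in (0, 0.5]")
    if var_y <= 0:
        raise ValueError("var_y must be positive")
    return 2 * maf * (1 - maf) * beta**2 / var_y


def prob_missing(f: float, fn_rate: float, n: int, k: int) -> float:
    """Probability of missing a non-reference insertion through both
    detection approaches: fn_rate * C(n, n-k) * f^(n-k) * (1-f)^k."""
    if not (0 <= f <= 1):
        raise ValueError("f must be in [0, 1]")
    if not (0 <= fn_rate <= 1):
        raise ValueError("fn_rate must be in [0, 1]")
    if not (0 <= k <= n):
        raise ValueError("need 0 <= k <= n")
    return fn_rate * math.comb(n, n - k) * f ** (n - k) * (1 - f) ** k


# --- benchmarking ---------------------------------------------------------


@dataclass
class BenchmarkRates:
    n_truth: int
    n_calls: int
    tp: int
    fp: int
    fn: int

    @property
    def fn_rate(self) -> float:
        return self.fn / self.n_truth if self.n_truth else 0.0

    @property
    def fdr(self) -> float:
        return self.fp / (self.fp + self.tp) if (self.fp + self.tp) else 0.0


def benchmark_rates(
    truth_set: Sequence[tuple[str, GenomicInterval]],
    call_set: Sequence[tuple[str, GenomicInterval]],
    match_tolerance_bp: int = 100,
) -> BenchmarkRates:
    """FN/FP/FDR of a call set against a ground-truth insertion set.

    A call matches a truth record when families agree and the TSD interval
    starts lie within ``match_tolerance_bp``; matching is 1-to-1, greedy
    by distance.
    """
    candidates: list[tuple[int, int, int]] = []
    for ti, (tfam, tiv) in enumerate(truth_set):
        for ci, (cfam, civ) in enumerate(call_set):
            if tfam != cfam or tiv.chrom != civ.chrom:
                continue
            d = abs(tiv.start - civ.start)
            if d <= match_tolerance_bp:
                candidates.append((d, ti, ci))
    used_t: set[int] = set()
    used_c: set[int] = set()
    tp = 0
    for d, ti, ci in sorted(candidates):
        if ti in used_t or ci in used_c:
            continue
        used_t.add(ti)
        used_c.add(ci)
        tp += 1
    return BenchmarkRates(
        n_truth=len(truth_set),
        n_calls=len(call_set),
        tp=tp,
        fp=len(call_set) - tp,
        fn=len(truth_set) - tp,
    )
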