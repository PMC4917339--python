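# Methods

This note documents the models and procedures the package implements,
the tunable parameters and their defaults, what the synthetic data
emulate (and do not), and the numerical choices made where the design
was genuinely open.

## Coordinates and formats

All internal coordinates are 0-based, half-open. Conversion to the
1-based conventions of SAM and GFF3 happens only in `mobilome.io`, so no
other module ever reasons about format origins. SAM is consumed as plain
text with an optional header; records whose CIGAR contains ops outside
{M, I, D, S} are rejected with a warning and counted, never silently
repaired. Parsers reject records violating type invariants rather than
correcting them.

## Split-read insertion calling

TE families create target-site duplications (TSDs) of fixed,
family-specific size (3–15 bp) on insertion: the insertion-site sequence
appears once in the reference but twice — flanking the TE — in a carrier
genome. Reads that straddle a TE/genome junction therefore fail to map
end-to-end to the reference, map partially onto a TE extremity, and
their clipped genomic remainders from the two extremities overlap by
exactly the TSD when remapped. The caller turns that signature into
calls in four steps:

1. **Unmapped extraction** — reads with the SAM unmapped flag. Mate
   (discordant-pair) information is deliberately not used; each mate is
   treated as an independent single-end read.
2. **Forced extremity mapping** — local alignment of each unmapped read
   against 5′ and 3′ extremity targets (300 bp per end, per family).
   Kept: alignments with exactly one terminal soft clip, anchor and clip
   both ≥ `min_clip` = 20 nt, with a unique best family target (ties are
   discarded). Families without a TSD (e.g. Helitrons) have no targets
   and can never yield a call.
3. **Recursive genomic remapping** — each clipped fragment is placed
   end-to-end on the reference, requiring a unique exact location. On
   failure, one nucleotide is trimmed from the fragment's
   *junction-proximal* end (TSD/microhomology contamination sits at the
   junction; the trim direction is a design choice) and the placement is
   retried, stopping before the fragment would shrink below 20 nt. The
   junction coordinate is the fragment end adjacent to the TE, derived
   from the placement strand and which read end was clipped.
4. **Dual-cluster TSD calling** — junctions are clustered per family,
   chromosome and genomic side by single-linkage with gap
   ≤ 2 × tsd_len (chains wider than the bound are split at their largest
   internal gap). A cluster's boundary is the modal junction, ties broken
   toward the TE. A left-of-TE cluster (boundary = TSD end) pairing with
   a right-of-TE cluster (boundary = TSD start) yields a call when both
   have ≥ `min_reads_discovery` = 5 reads, orientations agree, and the
   boundary overlap is between 1 and 2 × tsd_len — the overlap is the
   reconstructed TSD interval, and the TE orientation follows from which
   extremity anchors which side. Cluster pairing is greedy 1-to-1 by
   total support.

Both clusters require ≥ 5 reads at discovery: the genotyping relaxation
"two rather than ten" implies the discovery total was ten, i.e. five per
side. Genotyping across the cohort reuses the stored per-accession
evidences (steps 2–3) and marks presence at ≥ `min_reads_genotype` = 2
junctions inside the TSD interval ± 2 bp; the ±2 bp tolerance absorbs
1-nt trimming jitter.

Post-call filters annotate, rather than delete: `in_mask` (coverage
outlier mask), `inner_pericentromere`, `spans_donor` (TSD inside an
annotated copy of the same family), `in_control` (also called in a
reference-accession re-sequencing run), `coverage_outlier` (total
support > median genome coverage + 3 MAD), `high_frequency` (carried by
≥ 50% of the cohort), and `in_te_annotation` (overlap with annotated TE
copies, applied to a configurable superfamily list defaulting to
ATHILA/GYPSY). These deterministic rules replace interactive visual
inspection. A call with no flags carries `PASS`.

## Alignment

The algorithm needs only three alignment behaviours, so the package
ships an exact-match engine (`mobilome.align`): a 20-mer seed-and-verify
index over the reference answers (a) is this read an exact substring of
the genome on either strand (unmapped-read classification), (b) does
this fragment occur exactly once (end-to-end placement), and (c) what is
the longest exact terminal block of this read within a short extremity
target (local alignment). Ambiguity — two or more equal-quality
placements — always maps to "unmapped", a conservative, deterministic
choice. Aligners are injected dependencies: production data can flow in
as SAM text from any external aligner, and the tests cross-check the
built-in engine against exhaustive brute-force scans.

With exact matching, sequencing errors make a read unmappable rather
than mismatched; the simulator's substitution errors therefore stress
the extraction and trimming logic, not a scoring model. Indel errors and
quality scores are out of scope.

## Coverage and copy number

Coverage is base-resolution: a window's raw value is the number of
aligned reference bases (M/D CIGAR ops) overlapping the window divided
by the window width, in non-overlapping 100-bp windows. Duplicates
(flagged) are skipped.

GC correction is median-ratio per integer GC percent:
`corr = raw × m / m_GC`, with `m` the genome-wide median and `m_GC` the
median of windows sharing the window's GC percent; bins with fewer than
10 windows fall back to the raw value. This preserves the global median
by construction and flattens any bias expressible as a function of
window GC. The flattening experiment injects its bias by binomially
thinning each window's base count as a function of that window's GC —
an explicit idealization: bias acting at fragment scale leaves a
residual variance component (window GC is a noisy proxy of fragment GC)
that no window-keyed correction can remove.

Aberrant-region masks come from two reference-accession control
profiles: windows deviating from the genome median by more than
3 unscaled MADs (no 1.4826 consistency factor) in either control are
flagged, and runs of flagged windows merge across single-window gaps.
Low-complexity masks are accepted as input BED rather than recomputed.

Family copy number aggregates over a "joined pseudo-annotation" of the
family's annotated copies ≥ 300 bp (or ≥ half the consensus length in
GWAS mode), excluding masked windows:

    cn = n_ref_copies × [Σ_w corr(acc,w)/median(acc)] / [Σ_w corr(ref,w)/median(ref)]

which is scale-invariant in each sample's sequencing depth. A family
with no retained copies is untestable, not zero.

The CNV decision uses a distribution-independent permutation test. The
published description does not state the statistic; the package uses
|mean(acc) − mean(ref)| with accession/reference labels swapped
independently per window — windows are the same loci in both samples, so
the swap test conditions on locus effects. The reported p-value is the
maximum over the two reference replicates (the stringent choice), which
makes the combined p-value super-uniform under the null by construction
(measured type-I ≈ 0.003 at α = 0.05); the single-comparison p-value is
exposed separately (`mean_diff_permutation_p`) and is calibrated. All
permutation p-values carry the +1 correction, so the empirical FDR —
the fraction of a label-randomized null sample at or below the observed
p — is well defined; significance requires FDR < 10⁻⁵.

## Downstream statistics

**Positional nulls.** Random placements are uniform per allowed base
(genome minus masks, inner pericentromeres and donor spans).
Pericentromeric enrichment is evaluated per allele-count stratum
(private / shared 2–10 / shared > 10) with null-quantile 95% CIs and an
overall chi-square; 10-kb window enrichment declares a window enriched
when its count falls in the configured upper tail (default 5 × 10⁻⁵) of
the pooled null per-window count distribution.

**Metagene.** A position inside a gene takes the first matching class in
the hierarchy 5′ UTR > 3′ UTR > exon > intron (inside the gene but in no
annotated feature counts as intron); intergenic positions get the
distance to the closest gene, negative upstream of the gene's 5′ end in
the gene's own orientation. Every position receives exactly one class.

**Expression.** For each gene with an insertion call within 1 kb, the
statistic is carrier-median over non-carrier-median expression (genes
with a zero non-carrier median are excluded and logged). The null
redraws random gene sets of the same size and reassigns carrier labels
uniformly at random *preserving each call's carrier count* — the
published description does not state count preservation, but preserving
it makes the null exchangeable with the observed statistic. Observed and
pooled null ratio distributions are compared by a two-sample KS test.
The iteration count defaults to 10⁴ at desk scale (the analysis was
published at 10⁶); it is a flag.

**Methylation spreading.** Carrier and non-carrier cohort methylation is
averaged in 50-bp windows outward from the TSD; the spreading extent is
the distance to the first of two consecutive windows where the
carrier-minus-non-carrier difference drops below 0.2. Classes: none
(extent 0), short (≤ 300 bp), intermediate, long (> 1 kb). The 0.2
threshold and the two-consecutive-window stopping rule are this
package's choices (only the 300 bp / 1 kb landmarks are given by the
source analysis); both are configurable.

**Climate association.** Partial Mantel correlation between CN distance
and climate distance controlling kinship distance, with CN and climate
distances as absolute pairwise differences and kinship converted to
distance as 1 − kinship (pluggable metrics; these constructions are
defaults). Significance permutes the accession order of the CN distance
matrix, two-sided on |r|, +1-corrected. Under unconfounded nulls the
test is calibrated (measured type-I 0.035–0.04 at α = 0.05). Under the
structured-matrices null — climate tracking population structure and CN
carrying a population term — the measured type-I is ≈ 0.08 at α = 0.05:
the known mild liberality of raw-permutation partial Mantel under
confounding, reported here as a property of the method rather than
hidden by restricted permutations. The multiple-testing threshold for
12 climate variables is Bonferroni 0.01/12 = 8.33 × 10⁻⁴.

**Closed forms.** σ²_SNP = 2·MAF·(1−MAF)·β²/σ²_y, and
P(f) = FN·C(n, n−k)·f^(n−k)·(1−f)^k for the probability of jointly
missing an insertion of minor-allele frequency f. The binomial
coefficient generalizes a formula printed with n = 12 literal; the
package takes n as a parameter.

**Benchmarking.** Calls match truth records 1-to-1 (greedy by distance)
when families agree and TSD starts lie within 100 bp. FN rate = FN/truth
and FDR = FP/(FP+TP); with 142 truth insertions and 64 misses the FN
rate is 45%. Note that FP = 15, TP = 78 gives FDR = 16.1% by this
standard formula; the corresponding published figure (15.3%) cannot be
reconstructed from the printed counts, and the package keeps the
standard definition.

## Synthetic mobilome

The generator is a pure function of (config, seed) — identical inputs
give byte-identical outputs. Defaults describe the emulated study
conditions: 100-bp paired-end FR reads, 25× coverage, fragment length
400 ± 50, TSD sizes uniform on 3–15 bp, TE families of 0.8–3 kb with
mutually dissimilar extremities (< 80% identity, rejection-sampled),
insertions ≥ 1 kb apart, substitution-only sequencing errors
(default 0). Reference genomes are iid base draws at a target GC of
0.36; donor copies of each family are embedded into the reference so
that TE-interior reads map (only true junction reads stay unmapped) and
the annotation set exists for CN estimation and the donor-span filter.

Accession genomes carry, at each planted site,
flank + TSD + TE(orientation) + TSD + flank, where the TSD is the
reference sequence at the site — so re-extracting the flanks of any
planted TE reproduces the TSD exactly, and the planted table is an exact
truth set.

What the simulation does not emulate — and therefore what passing tests
do not establish about real data: mismatch-tolerant alignment and
mapping-quality ambiguity, indels, PCR duplicates, quality-score error
profiles, diverged/degenerate TE copies, and nested or truncated
insertions. Insertions that land inside repeated sequence (e.g. within a
donor TE copy) are genuinely missed by the caller because their junction
fragments have no unique placement; at the default densities this costs
a few percent sensitivity, which is the realistic failure mode of
split-read calling in repeats.

The structured-matrices generator for association testing uses two
populations of equal size: climate = 2·pop + N(0,1), per-family
CN = 10 + effect·climate + 0.5·pop + N(0,1), kinship 0.5 within /
0.1 between populations (1 on the diagonal). With effect = 0, any
CN–climate association runs entirely through population structure —
the null against which the partial Mantel correction is measured.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` run everything at desk scale,
chosen so the full suite completes in minutes on one CPU: the
parameter-recovery benchmark uses a 2-Mb, 5-chromosome reference with
10 families, 30 planted insertions and 25× reads (≈ 515k reads);
calibrations use 200 null replicates at 199–499 permutations each;
randomization nulls default to 10⁴ iterations (a flag scales to the
published 10⁶). Every stochastic component takes an explicit seed;
`--threads` does not exist as a tunable precisely because results must
not depend on scheduling.

## Known limitations

- Exact-match alignment requires error-free junction evidence: per-base
  error ε leaves ≈ (1−ε)^100 of reads usable, so sensitivity degrades
  quickly beyond ε ≈ 1%. Real-aligner SAM input is the intended path for
  noisy data.
- The caller does not call reference-TE absences, discordant-pair-only
  insertions, or somatic mosaics; Helitron-like TSD-less families are
  out of scope by design.
- Copy-number estimates are family aggregates; no per-copy segmentation
  or breakpoint refinement is attempted.
- The partial Mantel permutation scheme is the field-standard raw
  permutation and inherits its mild anti-conservatism under strong
  confounding (see above).
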