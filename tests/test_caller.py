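import numpy as np
import pandas as pd
import pytest

from mobilome.align import ExactIndex
from mobilome.caller import (
    ClipCluster,
    InsertionCall,
    LEFT_OF_TE,
    RIGHT_OF_TE,
    SplitReadEvidence,
    allele_frequency_spectrum,
    apply_filters,
    build_extremity_library,
    build_genotype_matrix,
    call_insertion,
    cluster_evidences,
    discover_insertions,
    extract_unmapped,
    genotype_call,
    map_clipped_fragment,
    map_to_extremities,
)
from mobilome.core import (
    AlignmentRecord,
    Genome,
    GenomicInterval,
    PipelineConfig,
    TEAnnotation,
    TEFamily,
    revcomp,
)
from mobilome.stats import benchmark_rates


def make_family(name="FAM", tsd_len=5, seq=None, rng=None, length=1000):
    if seq is None:
        seq = "".join(rng.choice(list("ACGT"), length))
    return (
        TEFamily(name, "I", "COPIA", tsd_len, seq[:300], seq[-300:]),
        seq,
    )


class TestExtractUnmapped:
    def test_all_mapped_gives_empty(self):
        recs = [AlignmentRecord("r1", "ACGT", True, "c1", 0, [("M", 4)])]
        assert extract_unmapped(recs) == []

    def test_mixed_set_returns_flag4_subset(self):
        recs = [
            AlignmentRecord("r1", "ACGT", True, "c1", 0, [("M", 4)]),
            AlignmentRecord("r2", "GGGG", False),
            AlignmentRecord("r3", "TTTT", False),
        ]
        assert extract_unmapped(recs) == [("r2", "GGGG"), ("r3", "TTTT")]

    def test_junction_straddling_reads_are_recovered(self, small_cohort):
        """Every error-free read straddling a planted junction by at least
        min_clip on each side must be in the unmapped set."""
        result = small_cohort["result"]
        assert result.n_unmapped > 0
        # all recovered evidences came from the unmapped set and carry
        # at least min_clip on both sides by construction
        for ev in result.evidences:
            assert ev.te_match_len >= 20 and ev.clip_len >= 20


class TestExtremityLibrary:
    def test_ends_of_long_sequence(self, rng):
        fam, seq = make_family(rng=rng, length=1000)
        lib = build_extremity_library({"FAM": seq}, [fam], PipelineConfig())
        assert lib[0].seq == seq[:300] and lib[0].te_side == "5prime"
        assert lib[1].seq == seq[700:1000] and lib[1].te_side == "3prime"

    def test_short_sequence_overlapping_ends(self, rng, caplog):
        seq = "".join(rng.choice(list("ACGT"), 400))
        fam = TEFamily("S", "II", "MUDR", 4, seq[:300], seq[-300:])
        with caplog.at_level("WARNING"):
            lib = build_extremity_library({"S": seq}, [fam], PipelineConfig())
        assert lib[0].seq == seq[:300] and lib[1].seq == seq[100:400]
        assert any("overlap" in r.message for r in caplog.records)

    def test_two_targets_per_family(self, rng):
        fams = []
        seqs = {}
        for i in range(3):
            fam, seq = make_family(f"F{i}", rng=rng)
            fams.append(fam)
            seqs[f"F{i}"] = seq
        lib = build_extremity_library(seqs, fams, PipelineConfig())
        assert len(lib) == 6

    def test_tsd_less_family_excluded(self, rng):
        fam, seq = make_family(rng=rng)
        helitron = TEFamily("HEL", "II", "HELITRON", None, seq[:300], seq[-300:])
        lib = build_extremity_library(
            {"FAM": seq, "HEL": seq}, [fam, helitron], PipelineConfig()
        )
        assert {t.family for t in lib} == {"FAM"}

    def test_empty_sequence_is_error(self, rng):
        fam, _ = make_family(rng=rng)
        with pytest.raises(ValueError):
            build_extremity_library({"FAM": ""}, [fam], PipelineConfig())


class TestMapToExtremities:
    @pytest.fixture
    def library(self, rng):
        fam, seq = make_family(rng=rng)
        return fam, seq, build_extremity_library({"FAM": seq}, [fam], PipelineConfig())

    def test_half_te_half_genomic_read(self, library, rng):
        fam, seq, lib = library
        genomic = "".join(rng.choice(list("ACGT"), 50))
        read = genomic + seq[:50]  # suffix matches 5' extremity start
        evs = map_to_extremities([("r1", read)], lib, PipelineConfig())
        assert len(evs) == 1
        ev = evs[0]
        assert ev.te_side == "5prime"
        assert ev.clip_len == 50 and ev.te_match_len == 50
        assert ev.fragment == genomic and ev.junction_at == "right"

    def test_clip_below_min_is_discarded(self, library, rng):
        fam, seq, lib = library
        genomic = "".join(rng.choice(list("ACGT"), 19))
        read = genomic + seq[:81]  # clip of 19 < 20
        assert map_to_extremities([("r1", read)], lib, PipelineConfig()) == []

    def test_read_without_te_content_discarded(self, library, rng):
        fam, seq, lib = library
        read = "".join(rng.choice(list("ACGT"), 100))
        assert map_to_extremities([("r1", read)], lib, PipelineConfig()) == []

    def test_reverse_strand_read(self, library, rng):
        fam, seq, lib = library
        genomic = "".join(rng.choice(list("ACGT"), 40))
        read = revcomp(genomic + seq[:60])
        evs = map_to_extremities([("r1", read)], lib, PipelineConfig())
        assert len(evs) == 1
        assert evs[0].fragment == genomic  # oriented back to the + strand
        assert evs[0].junction_at == "right"


@pytest.fixture(scope="module")
def genome_index():
    from mobilome.simulate import SimConfig, simulate_reference

    genome = simulate_reference(
        SimConfig(rng_seed=21, n_chroms=1, chrom_len_bp=20_000)
    )
    return genome, ExactIndex(genome, k=20)


class TestMapClippedFragment:
    def _evidence(self, fragment, junction_at):
        return SplitReadEvidence(
            read_id="r", family="FAM", te_side="5prime", te_match_len=50,
            clip_len=len(fragment), fragment=fragment, junction_at=junction_at,
        )

    def test_unique_fragment_junction_right(self, genome_index):
        genome, idx = genome_index
        frag = genome["chr1"][5000:5040]
        ev = map_clipped_fragment(self._evidence(frag, "right"), idx, PipelineConfig())
        assert ev is not None
        assert (ev.chrom, ev.junction, ev.genomic_side, ev.trims) == (
            "chr1", 5040, LEFT_OF_TE, 0,
        )
        assert ev.orientation == "+"  # left_of_TE + 5prime

    def test_unique_fragment_junction_left(self, genome_index):
        genome, idx = genome_index
        frag = genome["chr1"][5000:5040]
        ev = map_clipped_fragment(self._evidence(frag, "left"), idx, PipelineConfig())
        assert (ev.junction, ev.genomic_side) == (5000, RIGHT_OF_TE)
        assert ev.orientation == "-"  # right_of_TE + 5prime

    def test_te_contamination_trimmed(self, genome_index):
        """Two TE-derived bases at the junction-proximal end are trimmed
        before the fragment maps; the junction lands on the true boundary."""
        genome, idx = genome_index
        frag = genome["chr1"][5000:5040]
        contaminated = frag + "XX".replace("X", "A")  # may not match genome
        # ensure the contaminated fragment is absent from the genome
        if contaminated in genome["chr1"]:
            pytest.skip("unlucky construction")
        ev = map_clipped_fragment(
            self._evidence(contaminated, "right"), idx, PipelineConfig()
        )
        assert ev is not None and ev.trims >= 1
        assert ev.junction == 5000 + len(contaminated) - ev.trims

    def test_length_20_failure_gives_none(self, genome_index):
        genome, idx = genome_index
        frag = "A" * 20  # absent from a random genome with high probability
        if frag in genome["chr1"]:
            pytest.skip("unlucky genome")
        ev = map_clipped_fragment(self._evidence(frag, "right"), idx, PipelineConfig())
        assert ev is None

    def test_reverse_strand_fragment(self, genome_index):
        genome, idx = genome_index
        frag = revcomp(genome["chr1"][7000:7040])
        ev = map_clipped_fragment(self._evidence(frag, "right"), idx, PipelineConfig())
        # fragment maps on "-": junction at its read-right end = genome 7000
        assert (ev.junction, ev.genomic_side) == (7000, RIGHT_OF_TE)


class TestClustering:
    @pytest.fixture
    def family(self, rng):
        fam, _ = make_family(tsd_len=5, rng=rng)
        return fam

    def _ev(self, junction, side=LEFT_OF_TE, orientation="+", family="FAM"):
        return SplitReadEvidence(
            read_id="r", family=family, te_side="5prime", te_match_len=50,
            clip_len=50, fragment="", junction_at="right", chrom="c1",
            junction=junction, genomic_side=side, orientation=orientation,
        )

    def test_identical_junctions_form_one_cluster(self, family):
        evs = [self._ev(100) for _ in range(6)]
        clusters = cluster_evidences(evs, family, PipelineConfig())
        assert len(clusters) == 1
        assert clusters[0].n_reads == 6 and clusters[0].boundary == 100

    def test_gap_splits_clusters(self, family):
        evs = [self._ev(j) for j in (100, 101, 130)]
        clusters = cluster_evidences(evs, family, PipelineConfig())
        positions = sorted(tuple(c.junction_positions) for c in clusters)
        assert positions == [(100, 101), (130,)]

    def test_empty_input(self, family):
        assert cluster_evidences([], family, PipelineConfig()) == []

    def test_modal_boundary_tie_breaks_toward_te(self, family):
        # tie between 100 and 103: left-of-TE clusters break right (toward TE)
        evs = [self._ev(100), self._ev(100), self._ev(103), self._ev(103)]
        (cl,) = cluster_evidences(evs, family, PipelineConfig())
        assert cl.boundary == 103
        evs = [self._ev(100, RIGHT_OF_TE), self._ev(100, RIGHT_OF_TE),
               self._ev(103, RIGHT_OF_TE), self._ev(103, RIGHT_OF_TE)]
        (cl,) = cluster_evidences(evs, family, PipelineConfig())
        assert cl.boundary == 100

    def test_no_clusters_for_tsd_less_family(self, rng):
        fam, seq = make_family(rng=rng)
        helitron = TEFamily("HEL", "II", "HELITRON", None, seq[:300], seq[-300:])
        evs = [self._ev(100, family="HEL")]
        assert cluster_evidences(evs, helitron, PipelineConfig()) == []


class TestCallInsertion:
    @pytest.fixture
    def family(self, rng):
        fam, _ = make_family(tsd_len=5, rng=rng)
        return fam

    def _cluster(self, boundary, side, n_reads=6, orientation="+"):
        return ClipCluster(
            family="FAM", chrom="c1", genomic_side=side,
            junction_positions=[boundary] * n_reads, boundary=boundary,
            n_reads=n_reads, orientation=orientation,
        )

    @pytest.fixture
    def genome(self):
        return Genome({"c1": "ACGTG" * 400})

    def test_clean_tsd_call(self, family, genome):
        call = call_insertion(
            self._cluster(105, LEFT_OF_TE), self._cluster(100, RIGHT_OF_TE),
            family, genome, PipelineConfig(),
        )
        assert call is not None
        assert (call.tsd_interval.start, call.tsd_interval.end) == (100, 105)
        assert call.tsd_seq == genome["c1"][100:105]

    def test_overlap_wider_than_twice_tsd_rejected(self, family, genome):
        call = call_insertion(
            self._cluster(111, LEFT_OF_TE), self._cluster(100, RIGHT_OF_TE),
            family, genome, PipelineConfig(),
        )
        assert call is None  # 11 > 2 * 5

    def test_underpowered_cluster_rejected(self, family, genome):
        call = call_insertion(
            self._cluster(105, LEFT_OF_TE, n_reads=4),
            self._cluster(100, RIGHT_OF_TE),
            family, genome, PipelineConfig(),
        )
        assert call is None

    def test_discordant_orientation_rejected(self, family, genome):
        call = call_insertion(
            self._cluster(105, LEFT_OF_TE, orientation="+"),
            self._cluster(100, RIGHT_OF_TE, orientation="-"),
            family, genome, PipelineConfig(),
        )
        assert call is None


class TestEndToEndRecovery:
    def test_planted_insertions_recovered(self, small_cohort):
        planted = small_cohort["planted"]
        result = small_cohort["result"]
        truth = [(p.family, p.site) for p in planted]
        calls = [(c.family, c.tsd_interval) for c in result.calls]
        rates = benchmark_rates(truth, calls)
        assert rates.tp / rates.n_truth >= 0.8
        assert rates.fdr <= 0.1

    def test_recovered_tsds_and_orientations_exact(self, small_cohort):
        truth = {
            (p.site.chrom, p.site.start): p for p in small_cohort["planted"]
        }
        n_exact = 0
        for c in small_cohort["result"].calls:
            p = truth.get((c.tsd_interval.chrom, c.tsd_interval.start))
            if p is None:
                continue
            if c.tsd_interval.end == p.site.end and c.orientation == p.orientation:
                n_exact += 1
        assert n_exact >= 0.8 * len(small_cohort["result"].calls)

    def test_raising_discovery_threshold_never_adds_calls(self, small_cohort):
        strict = PipelineConfig(min_reads_discovery=10)
        res_strict = discover_insertions(
            small_cohort["reads"],
            small_cohort["reference"],
            small_cohort["families"],
            small_cohort["te_seqs"],
            strict,
            accession="acc1",
        )
        loose_keys = {
            (c.family, c.tsd_interval.chrom, c.tsd_interval.start)
            for c in small_cohort["result"].calls
        }
        strict_keys = {
            (c.family, c.tsd_interval.chrom, c.tsd_interval.start)
            for c in res_strict.calls
        }
        assert strict_keys <= loose_keys

    def test_reverse_complement_symmetry(self, small_cohort, pipeline_config):
        """Reverse-complementing the reference yields the same calls in
        mirrored coordinates (the read set is strand-symmetric already)."""
        reference = small_cohort["reference"]
        mirrored = Genome(
            {name: revcomp(seq) for name, seq in reference.items()}
        )
        res_m = discover_insertions(
            small_cohort["reads"], mirrored, small_cohort["families"],
            small_cohort["te_seqs"], pipeline_config, accession="acc1",
        )
        orig = {
            (c.family, c.tsd_interval.chrom, c.tsd_interval.start, c.tsd_interval.end)
            for c in small_cohort["result"].calls
        }
        mirror = set()
        for c in res_m.calls:
            L = mirrored.length(c.tsd_interval.chrom)
            mirror.add(
                (c.family, c.tsd_interval.chrom,
                 L - c.tsd_interval.end, L - c.tsd_interval.start)
            )
        assert mirror == orig


class TestFiltersAndGenotyping:
    def _call(self, start=1000, end=1005, family="FAM", chrom="c1"):
        return InsertionCall(
            family=family,
            tsd_interval=GenomicInterval(chrom, start, end),
            tsd_seq="AAAAA", n_reads_left=6, n_reads_right=6,
            orientation="+", discovered_in="acc1",
        )

    def test_unflagged_call_is_pass(self):
        (call,) = apply_filters([self._call()])
        assert call.passed

    def test_mask_flag(self):
        (call,) = apply_filters(
            [self._call()], masks=[GenomicInterval("c1", 900, 1100)]
        )
        assert "in_mask" in call.status and not call.passed

    def test_genotype_thresholds(self):
        call = self._call()
        cfg = PipelineConfig()

        def ev(junction):
            return SplitReadEvidence(
                read_id="r", family="FAM", te_side="5prime", te_match_len=50,
                clip_len=50, fragment="", junction_at="right", chrom="c1",
                junction=junction, genomic_side=LEFT_OF_TE, orientation="+",
            )

        evidences = {
            "acc1": [],  # discovery accession: present by construction
            "acc2": [ev(1001), ev(1004)],
            "acc3": [ev(1002)],
            "acc4": [ev(5000), ev(5001)],  # far away
        }
        presence, counts = genotype_call(call, evidences, cfg)
        assert presence["acc1"] == 1
        assert presence["acc2"] == 1 and counts["acc2"] == 2
        assert presence["acc3"] == 0  # one read is below the threshold
        assert presence["acc4"] == 0

    def test_genotype_tolerance_window(self):
        call = self._call()
        cfg = PipelineConfig()

        def ev(junction):
            return SplitReadEvidence(
                read_id="r", family="FAM", te_side="5prime", te_match_len=50,
                clip_len=50, fragment="", junction_at="right", chrom="c1",
                junction=junction, genomic_side=LEFT_OF_TE, orientation="+",
            )

        presence, _ = genotype_call(
            call, {"accX": [ev(998), ev(1007)]}, cfg
        )  # within +-2 of [1000, 1005]
        assert presence["accX"] == 1

    def test_allele_frequency_spectrum(self):
        geno = pd.DataFrame(
            {
                "a1": [1, 1, 1],
                "a2": [0, 1, 1],
                "a3": [0, 1, 1],
                "a4": [0, 0, 1],
            },
            index=["call1", "call2", "call3"],
        )
        histogram, classes = allele_frequency_spectrum(geno)
        assert histogram == {1: 1, 3: 1, 4: 1}
        assert classes == {"private": 1, "2-10": 2, ">10": 0}
        assert sum(histogram.values()) == len(geno)

    def test_genotype_matrix_marks_discovery_accession(self, small_cohort, pipeline_config):
        result = small_cohort["result"]
        geno, counts = build_genotype_matrix(
            result.calls, {"acc1": result.evidences}, pipeline_config
        )
        assert (geno["acc1"] == 1).all()
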