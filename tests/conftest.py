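import numpy as np
import pytest

from mobilome.caller import discover_insertions
from mobilome.core import PipelineConfig
from mobilome.simulate import (
    SimConfig,
    embed_reference_copies,
    pairs_to_reads,
    plant_insertions,
    simulate_reads,
    simulate_reference,
    simulate_te_families,
)


@pytest.fixture(scope="session")
def pipeline_config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_cohort(pipeline_config):
    """A compact synthetic accession: 2 x 200 kb reference with embedded
    donor TE copies, 10 planted TSD-flanked insertions, 25x error-free
    reads, plus the discovery result."""
    sim = SimConfig(
        rng_seed=1,
        n_chroms=2,
        chrom_len_bp=200_000,
        n_families=5,
        mean_coverage=25,
        insertions_per_accession=10,
    )
    base = simulate_reference(sim)
    families, te_seqs = simulate_te_families(sim)
    reference, annotations = embed_reference_copies(base, families, te_seqs, sim)
    acc_genome, planted = plant_insertions(
        reference, families, te_seqs, sim, accession="acc1"
    )
    pairs = simulate_reads(acc_genome, sim)
    reads = pairs_to_reads(pairs)
    result = discover_insertions(
        reads, reference, families, te_seqs, pipeline_config, accession="acc1"
    )
    return {
        "sim": sim,
        "base": base,
        "reference": reference,
        "annotations": annotations,
        "families": families,
        "te_seqs": te_seqs,
        "acc_genome": acc_genome,
        "planted": planted,
        "pairs": pairs,
        "reads": reads,
        "result": result,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
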