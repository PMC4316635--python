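import numpy as np
import pytest

from mutline import (AnnotationSet, CDSFeature, ReferenceGenome,
                     SimulationConfig, generate_genome, simulate_ma,
                     simulate_read_summaries)


@pytest.fixture
def rng():
    return np.random.default_rng(20141223)


@pytest.fixture
def toy_genome():
    """Two 10-bp scaffolds; origin 0, terminus 10."""
    return ReferenceGenome([("s1", "ACGTACGTAC"), ("s2", "GGGGCCCCAT")],
                           origin_pos=0, terminus_pos=10)


@pytest.fixture(scope="session")
def error_free_sim():
    """Small error-free MA simulation shared by calling/stat tests."""
    cfg = SimulationConfig(genome_length=60_000, n_lines=5, seed=11,
                           base_sub_rate=2e-6, per_read_error=0.0,
                           depth_mean=80.0, topology_amplitude=0.0,
                           context_multipliers=np.ones(64),
                           indel_rate=5e-8)
    genome, annotations = generate_genome(cfg)
    truth = simulate_ma(genome, annotations, cfg)
    matrix, indel_summaries = simulate_read_summaries(genome, truth, cfg)
    return cfg, genome, annotations, truth, matrix, indel_summaries
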