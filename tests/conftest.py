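import numpy as np
import pytest

from estmine import (
    build_condition_designs,
    generate_transcriptome,
    simulate_est_libraries,
)


@pytest.fixture(scope="session")
def small_transcriptome():
    """60 genes, bimodal GC3, 5 variant genes, 2 paralog pairs."""
    return generate_transcriptome(
        n_genes=60,
        gc3_modes=[(0.40, 0.5), (0.80, 0.5)],
        n_allelic_variants=5,
        n_paralog_pairs=2,
        seed=11,
    )


@pytest.fixture(scope="session")
def clean_library(small_transcriptome):
    """Zero-error, adapter-free, polyA-free reads from two libraries."""
    genes, truth = small_transcriptome
    designs, _ = build_condition_designs(
        genes, n_dev=1, n_stress=1, n_de=0, n_reads=500, seed=7
    )
    reads, full_truth = simulate_est_libraries(
        genes, designs, truth=truth,
        polyA_length={"kind": "constant", "value": 0},
    )
    return genes, designs, reads, full_truth


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)
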