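import numpy as np
import pytest

from regulonkit import reconstruct
from regulonkit.synthetic_cohort import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort exercising every pipeline stage."""
    cfg = CohortConfig(
        n_genomes=4,
        genome_length=150_000,
        n_tf_groups=2,
        decoy_fraction=0.0,
        seed=7,
    )
    genomes, tf_table, truth = generate_cohort(cfg)
    return genomes, tf_table, truth


@pytest.fixture(scope="session")
def small_reconstruction(small_cohort):
    genomes, tf_table, truth = small_cohort
    recon = reconstruct(
        genomes, tf_table, truth.protein_seqs, truth.ortholog_map
    )
    return recon, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20210)
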