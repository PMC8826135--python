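import numpy as np
import pytest

from driftscope.simulate import CohortConfig, build_cohort


def small_config(seed: int = 7, **overrides) -> CohortConfig:
    """A reduced cohort used by most integration tests: 15 genes, 2 tissues,
    smaller libraries, same divergence and read geometry as the default."""
    base = dict(
        seed=seed,
        n_conserved=5, n_decreased=5, n_increased=5,
        n_cnv_gains=2, n_premature_stop=1,
        tissues=("testis", "brain"),
        n_rna_per_genotype=4, n_dna_per_genotype=3,
        rna_pairs_per_library=4000, dna_depth=30.0,
        n_background_genes=6, background_mean=400.0,
    )
    base.update(overrides)
    return CohortConfig(**base)


@pytest.fixture(scope="session")
def small_cohort():
    return build_cohort(small_config())


@pytest.fixture(scope="session")
def null_cohort():
    cfg = CohortConfig.null(
        seed=11, n_conserved=10, tissues=("testis", "brain"),
        n_rna_per_genotype=2, n_dna_per_genotype=3,
        rna_pairs_per_library=800, dna_depth=50.0)
    return build_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
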