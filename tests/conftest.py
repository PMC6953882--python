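import numpy as np
import pytest

from transmqtl.config import CausalLocus, SimConfig
from transmqtl import simulate


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """Desk-scale cohort shared across tests (session-scoped: treat as
    read-only)."""
    return SimConfig(n_lines=120, n_snps=600, n_te=80, n_families=12, seed=11)


@pytest.fixture(scope="session")
def population(small_cfg):
    return simulate.simulate_population(small_cfg)


@pytest.fixture(scope="session")
def annotation(small_cfg):
    return simulate.simulate_te_annotation(small_cfg)


@pytest.fixture(scope="session")
def counts(small_cfg, population, annotation):
    genotypes, _ = population
    return simulate.simulate_methylomes(genotypes, annotation, small_cfg)


@pytest.fixture(scope="session")
def binned_counts(small_cfg, population, annotation):
    genotypes, _ = population
    return simulate.simulate_methylomes(genotypes, annotation, small_cfg, binned=True)


@pytest.fixture(scope="session")
def panel(small_cfg, annotation):
    return simulate.simulate_mutant_panel(annotation, small_cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def null_locus(**kw) -> CausalLocus:
    defaults = dict(label="L0", target_class="CMT2", effect=0.0,
                    cross_effect=0.0, maf=0.3, cline_slope=0.0, chrom=1)
    defaults.update(kw)
    return CausalLocus(**defaults)
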