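import dataclasses

import pytest

import burdenlab.synth as synth


@pytest.fixture(scope="session")
def small_config() -> synth.SimConfig:
    """A compact but structurally complete study configuration."""
    return synth.SimConfig(seed=7, n_genes=400, n_mutants=30)


@pytest.fixture(scope="session")
def catalog(small_config):
    return synth.gen_gene_catalog(small_config)


@pytest.fixture(scope="session")
def library(catalog, small_config):
    return synth.gen_burden_library(catalog, small_config)


@pytest.fixture(scope="session")
def compendium(catalog, small_config):
    return synth.gen_mutant_compendium(catalog, small_config)


@pytest.fixture(scope="session")
def noise_free_config(small_config):
    return dataclasses.replace(small_config, noise_log2_sd=0.0)
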