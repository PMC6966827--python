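import numpy as np
import pytest

from splicestress.config import SimConfig
from splicestress import synthetic as syn


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(n_genes=60, n_lines=6, n_events=50, n_variants=2000, seed=1)


@pytest.fixture(scope="session")
def small_genes(small_cfg):
    return syn.gen_gene_models(small_cfg)


@pytest.fixture(scope="session")
def small_ratios(small_cfg, small_genes):
    ratios, truth = syn.gen_ratio_samples(small_genes, small_cfg)
    return ratios, truth


@pytest.fixture(scope="session")
def small_retention(small_cfg, small_genes):
    return syn.gen_retention_counts(small_genes, small_cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
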