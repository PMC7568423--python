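import numpy as np
import pytest

from genoprio import synthetic


@pytest.fixture(scope="session")
def small_truth():
    """A desk-scale study: 100 genes x 1000 SNPs, 5 planted colocalized genes."""
    return synthetic.make_truth(seed=101, n_planted=5, n_genes=100,
                                n_snps=1000, n_samples_panel=300)


@pytest.fixture(scope="session")
def small_panel(small_truth):
    return synthetic.simulate_ld_panel(small_truth)


@pytest.fixture(scope="session")
def small_gwas(small_truth, small_panel):
    return synthetic.simulate_gwas(small_truth)


@pytest.fixture(scope="session")
def small_eqtl(small_truth, small_panel):
    return synthetic.simulate_eqtl(small_truth, small_panel, "monocytes")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
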