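import numpy as np
import pytest

import gpcv


@pytest.fixture(scope="session")
def small_panel() -> gpcv.GenotypeMatrix:
    """50 lines x 200 markers, MAF in [0.1, 0.5]."""
    return gpcv.sim_genotypes(50, 200, 0.1, 0.5, seed=101)


@pytest.fixture(scope="session")
def additive_trait(small_panel):
    spec = gpcv.TraitSimSpec(
        n_qtl_additive=40, n_pairs_epistatic=0, h2_additive=0.5, seed=202
    )
    return gpcv.sim_phenotypes(small_panel, spec)


@pytest.fixture(scope="session")
def medium_panel() -> gpcv.GenotypeMatrix:
    """300 lines x 250 markers, used where estimation needs a decent n."""
    return gpcv.sim_genotypes(300, 250, 0.1, 0.5, seed=303)


@pytest.fixture(scope="session")
def medium_trait(medium_panel):
    spec = gpcv.TraitSimSpec(
        n_qtl_additive=60, n_pairs_epistatic=0, h2_additive=0.5, seed=404
    )
    return gpcv.sim_phenotypes(medium_panel, spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
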