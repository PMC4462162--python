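import numpy as np
import pytest

import famvar as fv

np.seterr(over="ignore", invalid="ignore", divide="ignore")


@pytest.fixture(scope="session")
def family_table():
    """Mid-size family table with the default study conditions."""
    table, truth = fv.simulate_family_phenotypes(n_families=400, seed=101)
    return table, truth


@pytest.fixture(scope="session")
def family_table_untruncated():
    """Family table without recurrent-ascertainment zero truncation."""
    table, truth = fv.simulate_family_phenotypes(
        n_families=400, seed=102, recurrent=False
    )
    return table, truth


@pytest.fixture(scope="session")
def genotype_panel():
    """Small genotype panel with a planted polygenic phenotype."""
    g, y, truth = fv.simulate_genotype_phenotype(
        n_ind=400, n_snp=800, h2_snp=0.5, seed=103
    )
    return g, y, truth
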