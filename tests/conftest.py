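import numpy as np
import pandas as pd
import pytest

from dupsnp import synthetic_data as sd


@pytest.fixture(scope="session")
def genome():
    return sd.make_genome(n_contigs=30, mean_length=10_000, duplicated_fraction=0.3, seed=11)


@pytest.fixture(scope="session")
def panel():
    return sd.make_panel({"farm": 20, "wild": 10}, haploid_sample=True, seed=12)


@pytest.fixture(scope="session")
def pedigree():
    return sd.make_pedigree(n_families=2, n_offspring=10, seed=13)


@pytest.fixture(scope="session")
def marker_map():
    return {f"chr{c}": (np.arange(1, 81)) * 50_000 for c in range(1, 4)}


@pytest.fixture(scope="session")
def family_data(pedigree, marker_map):
    """(GenotypeMatrix, TruthLabels) with zero male recombination, no error."""
    return sd.simulate_family_genotypes(pedigree, marker_map, male_recomb=0.0, seed=14)


@pytest.fixture(scope="session")
def random_genotypes():
    rng = np.random.default_rng(15)
    return pd.DataFrame(
        rng.integers(0, 3, size=(40, 96)).astype(np.int8),
        index=[f"ps{i + 1}" for i in range(40)],
        columns=[f"s{j + 1}" for j in range(96)],
    )
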