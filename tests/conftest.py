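import numpy as np
import pandas as pd
import pytest

from funburd.assoc import association_grid
from funburd.genesets import GeneSetCollection, build_tdep_sets, expression_proportion
from funburd.synthetic import SyntheticConfig, simulate_cohort


@pytest.fixture(scope="session")
def cohort():
    """Default-condition synthetic cohort, shared across tests."""
    return simulate_cohort(SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def trait_types(cohort):
    return {t.name: t.kind for t in cohort.config.trait_specs}


@pytest.fixture(scope="session")
def grid(cohort, trait_types):
    """Association grid on the true marker sets of the shared cohort."""
    return association_grid(
        cohort.burden, cohort.phenotypes, cohort.covariates, trait_types
    )


@pytest.fixture(scope="session")
def tdep_collection(cohort):
    return build_tdep_sets(expression_proportion(cohort.expression))


@pytest.fixture()
def overlapping_collection():
    """Twelve overlapping 30-gene sets in a 150-gene universe."""
    rng = np.random.default_rng(42)
    universe = [f"g{i:03d}" for i in range(150)]
    sets = {}
    for j in range(12):
        core = rng.choice(universe, size=20, replace=False)
        shared = universe[:10]  # all sets share a common block
        sets[f"set{j:02d}"] = sorted(set(core) | set(shared))
    return GeneSetCollection(sets, universe=universe)
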