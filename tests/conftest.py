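import numpy as np
import pytest

from annoherit import (
    ClassSpec,
    SimScenario,
    assign_annotations,
    simulate_genotypes,
    simulate_phenotypes,
)


@pytest.fixture(scope="session")
def small_scenario():
    """300 individuals x 2000 SNPs with h2 planted in missense + background."""
    return SimScenario(
        n_individuals=300,
        n_snps=2000,
        seed=11,
        class_h2={"missense": 0.3},
        residual_h2_background=0.2,
    )


@pytest.fixture(scope="session")
def small_data(small_scenario):
    genotypes = simulate_genotypes(small_scenario)
    annotations = assign_annotations(small_scenario, genotypes)
    design, truth = simulate_phenotypes(small_scenario, genotypes, annotations)
    return genotypes, annotations, design, truth


@pytest.fixture
def disjoint_scenario():
    """Two disjoint top-level causal classes plus a neutral remainder."""
    return SimScenario(
        n_individuals=250,
        n_snps=1500,
        seed=5,
        class_spec=(
            ClassSpec("classA", 0.25),
            ClassSpec("classB", 0.25),
            ClassSpec("rest", 0.5),
        ),
        class_h2={"classA": 0.3, "classB": 0.1},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
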