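import numpy as np
import pytest

from phyloroot.models import SubstitutionModel
from phyloroot.simulate import WorldConfig, make_benchmark, sample_species_tree


@pytest.fixture(scope="session")
def poisson_model():
    return SubstitutionModel.poisson()


@pytest.fixture(scope="session")
def small_world():
    """A compact two-kingdom world: 8 ingroup + 3 outgroup leaves."""
    cfg = WorldConfig(n_classes_per_kingdom=2, n_species_per_class=2,
                      n_outgroup_phyla=3, species_per_outgroup_phylum=1,
                      seed=7)
    tree, taxonomy = sample_species_tree(cfg)
    return cfg, tree, taxonomy


@pytest.fixture(scope="session")
def benchmark500():
    """The 500-family screening benchmark at its standard event rates.

    Session-scoped: generation is the expensive step and several tests
    score different aspects of the same dataset.
    """
    return make_benchmark(WorldConfig(), 500, event_rates=(0.2, 0.1, 0.1),
                          n_sites_range=(300, 600), seed=1)


def random_binary_tree(rng, n_leaves, rooted=False):
    from phyloroot.trees import random_topology
    names = [f"t{i}" for i in range(n_leaves)]
    return random_topology(names, rng, rooted=rooted)
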