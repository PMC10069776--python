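import numpy as np
import pytest

import phyloimpute as pi
from phyloimpute.traits import apply_transforms


@pytest.fixture(scope="session")
def worked_example():
    return pi.make_worked_example()


@pytest.fixture(scope="session")
def sim80():
    """An 80-tip simulated tree + trait table (shared, read-only)."""
    spec = pi.default_simulation_spec(n_taxa=80, seed=11)
    tree = pi.simulate_tree(spec)
    table = pi.simulate_traits(tree, spec)
    return spec, tree, table


@pytest.fixture(scope="session")
def near80(sim80):
    """Model-scale near-complete-case table from the 80-tip simulation."""
    _, tree, table = sim80
    near = apply_transforms(pi.build_near_complete_case(table))
    return tree, near


@pytest.fixture(scope="session")
def predictors80(near80):
    _, near = near80
    return {t: pi.select_auxiliary_traits(near, t) for t in near.trait_names}
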