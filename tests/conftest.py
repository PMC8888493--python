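import numpy as np
import pytest
from hypothesis import settings

import nutriscape as ns

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def paper_grid():
    """The 10-ratio x 4-dilution reference diet grid."""
    return ns.build_diet_grid()


@pytest.fixture(scope="session")
def paper_records(paper_grid):
    """One full simulated experiment under the reference design."""
    return ns.simulate_experiment(
        paper_grid, 20, ns.default_surface_params(), seed=20260930
    )


@pytest.fixture(scope="session")
def small_records(paper_grid):
    """A cheaper dataset (5 flies per sex per diet) for slow-ish stages."""
    return ns.simulate_experiment(
        paper_grid, 5, ns.default_surface_params(), seed=11
    )


@pytest.fixture(scope="session")
def grid_coords(paper_grid):
    return np.array([[d.protein_pct, d.carbohydrate_pct] for d in paper_grid])
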