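import numpy as np
import pytest

from synspheroid import ModelParams, SeedingSpec, baseline_params


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_seeding():
    return SeedingSpec(n_cells=60, ratio=(1, 1))


@pytest.fixture
def baseline():
    return baseline_params()


def make_state(cells, side=15, params=None, dim=2):
    """Hand-built state: `cells` maps coordinate tuples to phenotype."""
    from synspheroid.dynamics import SimulationState
    from synspheroid.lattice import Lattice

    n_sites = side**dim
    occupancy = [-1] * n_sites
    positions = []
    phenotypes = []
    for i, (p, phen) in enumerate(sorted(cells.items())):
        flat = 0
        for k, v in enumerate(p):
            flat = flat * side + v
        occupancy[flat] = i
        positions.append(flat)
        phenotypes.append(int(phen))
    lattice = Lattice(
        dim=dim, side=side, seeding_radius=side / 2,
        occupancy=occupancy, positions=positions, phenotypes=phenotypes,
    )
    return SimulationState(lattice, params or ModelParams())
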