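import numpy as np
import pytest

from podburst.dynamics import attach_seeds, build_rod, simulate_release
from podburst.energetics import landscape, reference_valve
from podburst.params import load_reference
from podburst.units import to_si


@pytest.fixture(scope="session")
def ref():
    return load_reference()


@pytest.fixture(scope="session")
def hinged_valve(ref):
    return reference_valve(ref, "hinged")


@pytest.fixture(scope="session")
def boxed_valve(ref):
    return reference_valve(ref, "boxed")


@pytest.fixture(scope="session")
def hinged_landscape(hinged_valve):
    return landscape(hinged_valve)


@pytest.fixture(scope="session")
def coiling_run(ref, hinged_valve, hinged_landscape):
    """One reference coiling simulation with seeds, shared across tests."""
    rod = build_rod(hinged_valve, hinged_landscape, 80)
    seeds = attach_seeds(rod, ref.n_seeds, to_si(ref.seed_mass, "mg"),
                         ref.tether_k, ref.tether_c,
                         to_si(ref.tether_delta_c, "um"))
    return simulate_release(rod, seeds, dt=1e-7, T=8e-3)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
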