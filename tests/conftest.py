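import numpy as np
import pytest

from rb82dose.physics import decay_constant, load_nuclide, load_schedule
from rb82dose.synthetic import default_phantom, simulate_frames
from rb82dose.tacs import add_remainder, extract_tacs
from rb82dose.kinetics import tia_table

INJECTED_MBQ = 407.0


@pytest.fixture(scope="session")
def nuclide():
    return load_nuclide()


@pytest.fixture(scope="session")
def schedule():
    return load_schedule()


@pytest.fixture(scope="session")
def lam(nuclide):
    return decay_constant(nuclide)


@pytest.fixture(scope="session")
def noiseless_study(nuclide, schedule, lam):
    """Default 11-organ phantom, noiseless frames, TACs with remainder,
    fitted TIA table -- the shared end-to-end fixture."""
    labels, kinetics = default_phantom(seed=1, injected_MBq=INJECTED_MBQ)
    dyn = simulate_frames(labels, kinetics, schedule, nuclide, noise_scale=0.0)
    tacs = add_remainder(extract_tacs(dyn, labels, INJECTED_MBQ), dyn, labels)
    tia = tia_table(tacs, lam)
    return {
        "labels": labels,
        "kinetics": kinetics,
        "dynamic": dyn,
        "tacs": tacs,
        "tia": tia,
        "injected_MBq": INJECTED_MBQ,
    }
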