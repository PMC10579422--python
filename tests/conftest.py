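import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from syntherm.simulate import SimulationScenario, simulate
from syntherm.thermo import ATM_PA, ThermodynamicState

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def b01():
    """Noiseless default-scenario batch run, shared across tests."""
    return simulate(SimulationScenario.default())


def random_admissible_state(rng: np.random.Generator) -> ThermodynamicState:
    """A random culture snapshot within the physically admissible ranges."""

    def logu(lo, hi):
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    return ThermodynamicState(
        temperature=float(rng.uniform(290.0, 340.0)),
        ph=float(rng.uniform(6.5, 9.0)),
        solutes={
            "propionate": logu(1e-4, 0.1),
            "acetate": logu(1e-4, 0.1),
            "formate": logu(1e-5, 0.01),
        },
        gases={
            "H2": logu(0.5, 1000.0),
            "CO2": logu(0.02, 1.0) * ATM_PA,
            "CH4": logu(0.01, 2.0) * ATM_PA,
        },
    )
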