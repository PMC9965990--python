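import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ketopbpk as k

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: loose-but-adequate solver options for tests that compare simulations
FAST_SOLVER = {"rtol": 1e-6, "atol": 1e-8}


@pytest.fixture(scope="session")
def individual():
    return k.build_reference_individual()


@pytest.fixture(scope="session")
def ktz():
    return k.load_compound("ketoconazole")


@pytest.fixture(scope="session")
def m1():
    return k.load_compound("m1")


@pytest.fixture(scope="session")
def m2():
    return k.load_compound("m2")


@pytest.fixture(scope="session")
def trio(ktz, m1, m2):
    return [ktz, m1, m2]


@pytest.fixture(scope="session")
def single_400_fasted(individual, trio):
    """One shared 400 mg fasted tablet simulation over 48 h."""
    from ketopbpk.absorption import DoseEvent, KETOCONAZOLE_TABLET
    from ketopbpk.engine import assemble_rhs, build_network, simulate

    net = build_network(trio, "P+M1+M2")
    reg = [DoseEvent("ketoconazole", 400.0, 0.0, KETOCONAZOLE_TABLET, "fasted")]
    model = assemble_rhs(individual, trio, net, reg, "fasted")
    return simulate(model, 48.0, 0.1, solver_opts=FAST_SOLVER)
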