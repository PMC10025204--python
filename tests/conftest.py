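import io

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from relpot import (
    DoseResponseTable,
    EndpointSimConfig,
    ExpressionSimConfig,
    simulate_endpoint_table,
    simulate_expression_matrix,
)


@pytest.fixture
def expression_text():
    """Two probes, three samples, concentrations 0/50/100."""
    return (
        "Sample\ts1\ts2\ts3\n"
        "Concentration\t0\t50\t100\n"
        "P1\t8.0\t8.5\t9.0\n"
        "P2\t7.0\t6.5\t6.0\n"
    )


@pytest.fixture
def endpoint_text():
    """One substance, two experiments, four records."""
    return (
        "substance\texperiment\tconcentration\tresponse\n"
        "PFOA\texp1\t0\t100.0\n"
        "PFOA\texp1\t100\t150.0\n"
        "PFOA\texp2\t0\t110.0\n"
        "PFOA\texp2\t100\t160.0\n"
    )


@pytest.fixture
def stream():
    return lambda text: io.StringIO(text)


@pytest.fixture(scope="session")
def noise_free_endpoint():
    cfg = EndpointSimConfig(sigma=0.0, seed=42)
    return cfg, *simulate_endpoint_table(cfg)


@pytest.fixture(scope="session")
def noisy_endpoint():
    cfg = EndpointSimConfig(seed=7)
    return cfg, *simulate_endpoint_table(cfg)


@pytest.fixture(scope="session")
def small_matrix_sim():
    """Compact matrix for pipeline tests (fast enough for the full screen)."""
    cfg = ExpressionSimConfig(n_probes=120, n_sets=6, n_regulated_sets=3,
                              set_size=8, seed=11)
    return cfg, *simulate_expression_matrix(cfg)


@pytest.fixture
def two_substance_table():
    """Noise-free table where substance B is 3x as potent as A."""
    cfg = EndpointSimConfig(rpfs={"A": 1.0, "B": 3.0}, index_substance="A",
                            index_b=60.0, sigma=0.0, seed=1)
    table, truth = simulate_endpoint_table(cfg)
    return table, truth
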