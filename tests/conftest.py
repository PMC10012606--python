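import pytest
from hypothesis import HealthCheck, settings

from csfsg import MicrovilliGeometry, TransportParameters, build_flux_profile
from csfsg.presets import FIXED_CASES, case_to_model_inputs, mean_parameter_values

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def central_case():
    """Geometry/transport pair yielding the central production fixture."""
    return case_to_model_inputs(FIXED_CASES["central"])


@pytest.fixture(scope="session")
def mean_case():
    """Geometry/transport pair at the means of the marginal table."""
    return case_to_model_inputs(mean_parameter_values())


@pytest.fixture(scope="session", params=sorted(FIXED_CASES))
def fixed_case(request):
    """Each of the three bracketing fixture parameter sets."""
    return request.param, case_to_model_inputs(FIXED_CASES[request.param])
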