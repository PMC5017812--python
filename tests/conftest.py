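import pytest
from hypothesis import HealthCheck, settings

from lnaclamp.fixtures import FixtureSpec, make_forward_fixture, make_reverse_fixture
from lnaclamp.workflows import design_forward_primer, design_host_clamps

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def forward_fixture():
    return make_forward_fixture(FixtureSpec(seed=7))


@pytest.fixture(scope="session")
def reverse_fixture():
    return make_reverse_fixture(FixtureSpec(seed=7))


@pytest.fixture(scope="session")
def primer_result(forward_fixture):
    return design_forward_primer(forward_fixture.alignment)


@pytest.fixture(scope="session")
def clamp_designs(reverse_fixture):
    aln, anchor = reverse_fixture.alignment, reverse_fixture.anchor_col
    designs = design_host_clamps(aln, anchor)
    # key by representative plant for readable assertions
    return {k.split("(")[1].rstrip(")"): v for k, v in designs.items()}
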