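import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")

from oncoaddict import (
    CellStateVector,
    MycSchedule,
    RateParameters,
    build_parameters,
)


@pytest.fixture
def lymphoma_competent() -> RateParameters:
    return build_parameters("lymphoma", "competent", {})


@pytest.fixture
def lymphoma_deficient() -> RateParameters:
    return build_parameters("lymphoma", "deficient", {})


@pytest.fixture
def growth_then_off() -> MycSchedule:
    """MYC on for a 10-day growth phase, then inactivated."""
    return MycSchedule("on", ((10.0, "off"),))


@pytest.fixture
def million_m_cells() -> CellStateVector:
    return CellStateVector(M=1_000_000)


def zeroed(**active) -> RateParameters:
    """RateParameters with every rate 0 except the ones given."""
    base = dict(
        k_M_prolif=0, k_M_apop=0, k_N_prolif=0, k_N_apop=0, k_diff=0,
        k_senesc=0, k_relapse=0, k_wake=0, k_E_prolif=0, k_E_apop=0,
        k_D_apop=0, k_inactivation=0, k_activation=0, tau_apop=0.0,
    )
    base.update(active)
    return RateParameters(**base)
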