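import pytest

from runpower import RECORD_FIXTURES, PACE_FIXTURES


@pytest.fixture(scope="session")
def wr_men():
    """Men's world-record profile (t_c=6.26, v_m=411.72, gamma_s=0.0999,
    gamma_l=0.0536)."""
    return RECORD_FIXTURES["WR_men"].profile()


@pytest.fixture(scope="session")
def wr_women():
    return RECORD_FIXTURES["WR_women"].profile()


@pytest.fixture(scope="session")
def vdot40():
    """Recreational-runner profile fitted to VDOT=40 reference times
    (t_c=12.35, v_m=214.88, gamma_l=0.051, gamma_s=0.096)."""
    return PACE_FIXTURES["VDOT40"].profile()
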