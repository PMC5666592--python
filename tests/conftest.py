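import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vdmr import HarmonizedInstrument, HarmonizedRecord, make_fixture_instrument

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def build_instrument(gamma, outcome_beta, gamma_se=None, outcome_se=None):
    """Construct a HarmonizedInstrument directly from effect arrays."""
    gamma = np.asarray(gamma, dtype=float)
    outcome_beta = np.asarray(outcome_beta, dtype=float)
    gamma_se = np.full_like(gamma, 0.1) if gamma_se is None else np.asarray(gamma_se, float)
    outcome_se = (
        np.full_like(gamma, 0.02) if outcome_se is None else np.asarray(outcome_se, float)
    )
    records = [
        HarmonizedRecord(
            rsid=f"rs{i + 1}",
            exposure_beta=float(gamma[i]),
            exposure_se=float(gamma_se[i]),
            outcome_beta=float(outcome_beta[i]),
            outcome_se=float(outcome_se[i]),
        )
        for i in range(gamma.size)
    ]
    return HarmonizedInstrument(records=records)


@pytest.fixture(scope="session")
def fixture_instrument():
    """The published four-variant 25(OH)D instrument with a null outcome."""
    return make_fixture_instrument()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
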