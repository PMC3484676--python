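import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

_BASES = np.array(list("ACGT"))


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


@pytest.fixture(scope="session")
def panel():
    from regulonkit.motifs import bundled_pwms

    return bundled_pwms()


@pytest.fixture(scope="session")
def probe_pwm():
    """A wide PWM with minimal self-overlap, used for null-distribution checks."""
    from regulonkit.motifs import pwm_from_consensus

    return pwm_from_consensus(
        "probe",
        "CCTACCAATCTC",
        [0.85, 0.80, 0.88, 0.82, 0.90, 0.86, 0.79, 0.83, 0.87, 0.81, 0.77, 0.84],
    )
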