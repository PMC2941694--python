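import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def planted_cohort():
    """Small cohort where three SNPs carry strong, independent main effects."""
    from nutrinet.encoding import encode
    from nutrinet.synthetic import SimSpec, simulate

    spec = SimSpec(
        n_subjects=300,
        n_genotype=8,
        n_nutrition=6,
        seed=42,
        main_effects={"SNP01": 3.0, "SNP02": -2.5, "SNP03": 2.5},
        interactions={},
        target_c2_fraction=0.5,
    )
    result = simulate(spec)
    return result, encode(result.cohort)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
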