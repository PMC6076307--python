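import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from edslung import ann, preclassify, spiro, synthdata  # noqa: E402


@pytest.fixture
def uniform_table() -> preclassify.SignificanceFactorTable:
    """Equal weights, no inversion: probability = affirmative fraction."""
    return preclassify.SignificanceFactorTable(
        asthma=(1.0,) * 7, copd=(1.0,) * 7, asthma_inverted_questions=frozenset()
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def small_network(rng) -> ann.NetworkWeights:
    return ann.init_weights(S=5, N=3, R=1, rng=rng)


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small but fully featured labeled synthetic cohort."""
    return synthdata.generate_cohort(synthdata.default_spec("realistic", n=60, seed=5))


def measurement(
    vc=4.0, fev1=2.5, fvc=3.5, tiffeneau=None, pct_pred=None
) -> spiro.SpirometryMeasurement:
    return spiro.SpirometryMeasurement(
        vc=vc, fev1=fev1, fvc=fvc, tiffeneau=tiffeneau, fev1_percent_predicted=pct_pred
    )
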