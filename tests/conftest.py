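import pytest
from hypothesis import HealthCheck, settings

from simon2stage import TwoStageDesign

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def optimal_small() -> TwoStageDesign:
    """Simon optimal design for pi0=0.05, pi1=0.20, alpha=0.05, power 90%."""
    return TwoStageDesign(n1=21, n2=20, r1=1, rt=4)


@pytest.fixture(scope="session")
def minimax_mid() -> TwoStageDesign:
    """Simon minimax design for pi0=0.40, pi1=0.60, alpha=0.05, power 90%."""
    return TwoStageDesign(n1=29, n2=25, r1=12, rt=27)


@pytest.fixture(scope="session")
def optimal_mid() -> TwoStageDesign:
    """Simon optimal design for pi0=0.30, pi1=0.50, alpha=0.05, power 90%."""
    return TwoStageDesign(n1=24, n2=39, r1=8, rt=24)


@pytest.fixture(scope="session")
def toy() -> TwoStageDesign:
    """Smallest useful design: n1=2, r1=0, n2=2, rt=2."""
    return TwoStageDesign(n1=2, n2=2, r1=0, rt=2)


# (design, pi0, pi1) triples used across test modules
DESIGN_SCENARIOS = [
    (TwoStageDesign(21, 20, 1, 4), 0.05, 0.20),
    (TwoStageDesign(29, 25, 12, 27), 0.40, 0.60),
    (TwoStageDesign(24, 39, 8, 24), 0.30, 0.50),
]
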