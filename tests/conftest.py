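import numpy as np
import pytest

from redback.design import StudyDesign
from redback.growth import GrowthParams
from redback.scr import SCRParams
from redback.synthetic import TruthParams


@pytest.fixture(scope="session")
def field_growth_truth() -> GrowthParams:
    """Additive growth coefficients anchored at the fitted field values:
    mature-female K 0.237, successional effect +0.102, male effect +0.434."""
    return GrowthParams(
        L_male=43.569, L_female=52.164, beta0_K=0.237, beta1_K=0.102, beta2_K=0.434
    )


@pytest.fixture(scope="session")
def mature_scr_truth() -> SCRParams:
    """Fitted mature-plot SCR values (density per m^2, sigma/tau in m)."""
    return SCRParams(phi=0.996, sigma=3.496, lam=0.019, density=0.613, tau=0.99)


@pytest.fixture(scope="session")
def field_truth(mature_scr_truth, field_growth_truth) -> TruthParams:
    return TruthParams(scr=mature_scr_truth, growth=field_growth_truth)


@pytest.fixture(scope="session")
def default_design() -> StudyDesign:
    return StudyDesign()


@pytest.fixture(scope="session")
def small_design() -> StudyDesign:
    """A compact design for fast fitting tests: tight state space suited to
    a small movement scale."""
    return StudyDesign(buffer=4.0)


@pytest.fixture(scope="session")
def small_truth(field_growth_truth) -> TruthParams:
    """High-detection, small-sigma scenario so short chains are informative."""
    return TruthParams(
        scr=SCRParams(phi=0.95, sigma=1.4, lam=0.12, density=0.35, tau=0.6),
        growth=field_growth_truth,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
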