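import numpy as np
import pytest

from skitech.io import CLASSES, SubTechnique
from skitech.synth import SessionPlan, default_templates, generate_session


@pytest.fixture(scope="session")
def templates():
    return default_templates()


@pytest.fixture(scope="session")
def mixed_session():
    """A small noisy session covering all eight classes."""
    plan = SessionPlan(blocks=[(c, 4) for c in CLASSES], noise=0.1, seed=42)
    return generate_session(plan)


@pytest.fixture()
def dia_plan():
    return SessionPlan(blocks=[(SubTechnique.DIA, 10)], noise=0.0, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
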