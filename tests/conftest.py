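import numpy as np
import pytest

from reachat.tumor_model import SubpopParams, TumorState, default_params


@pytest.fixture(scope="session")
def params() -> SubpopParams:
    """Shipped synthetic typical parameter values."""
    return default_params()


@pytest.fixture()
def init_mixed() -> TumorState:
    """Reference sweep initial state: 180 mm^3 sensitive + 20 mm^3 resistant."""
    return TumorState(0.0, 180.0, 20.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


def draw_params(rng: np.random.Generator, base: SubpopParams, spread: float = 0.15) -> SubpopParams:
    """Log-normal parameter draw around the typical values (test helper)."""
    updates = {
        name: getattr(base, name) * float(np.exp(spread * rng.standard_normal()))
        for name in ("r_h", "r_a", "K_h", "K_a", "a", "h", "E_osi")
    }
    return SubpopParams(**updates)
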