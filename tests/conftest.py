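import numpy as np
import pytest

from octafractal.slab_io import OCTASlab, Plexus
from octafractal.synthetic_data import generate_plexus


@pytest.fixture(scope="session")
def healthy_slab() -> OCTASlab:
    """Default intact synthetic plexus at the standard 256 px resolution."""
    return generate_plexus(0.5, 0.0, seed=42)


@pytest.fixture(scope="session")
def ischemic_slab() -> OCTASlab:
    return generate_plexus(0.5, 0.6, seed=42)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)


def make_slab(pixels: np.ndarray, eye_id: str = "eye", plexus: Plexus = Plexus.SCP) -> OCTASlab:
    return OCTASlab(eye_id=eye_id, plexus=plexus, pixels=np.asarray(pixels, dtype=np.uint8))
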