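import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from petsegtex import PETVolume, PhantomConfig, VOIMask, generate_phantom

SPACING = (4.7, 4.7, 3.27)


def make_volume(values, spacing=SPACING) -> PETVolume:
    return PETVolume(np.asarray(values, dtype=float), spacing)


def make_mask(mask, spacing=SPACING, provenance="truth") -> VOIMask:
    return VOIMask(np.asarray(mask, dtype=bool), spacing, provenance)


@pytest.fixture(scope="session")
def default_phantom():
    """One default phantom shared by read-only tests."""
    return generate_phantom(PhantomConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
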