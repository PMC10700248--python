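import numpy as np
import pytest

from ovaseg.phantom import PhantomConfig, generate_phantom
from ovaseg.volume_io import LabelMap, Volume


@pytest.fixture(scope="session")
def small_phantom():
    """One deterministic phantom scan shared by read-only tests."""
    return generate_phantom(PhantomConfig(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def toy_volume():
    vals = np.arange(4 * 5 * 6, dtype=np.float32).reshape(4, 5, 6)
    return Volume(vals, spacing=(5.0, 0.7, 0.7), scan_id="toy")


@pytest.fixture()
def toy_labels():
    lab = np.zeros((4, 5, 6), dtype=np.uint8)
    lab[1:3, 1:3, 1:3] = 1
    lab[3, 4, 4] = 2
    return LabelMap(lab, spacing=(5.0, 0.7, 0.7), scan_id="toy")
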