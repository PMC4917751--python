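import numpy as np
import pytest

from edwave.calibration import default_params
from edwave.signal_io import Epoch
from edwave.synth import SynthConfig, generate_epoch


@pytest.fixture(scope="session")
def table_params():
    """The packaged default (sharp, sw) parameter sets."""
    return default_params()


@pytest.fixture(scope="session")
def synth_cfg():
    return SynthConfig()


@pytest.fixture(scope="session")
def sharp_epoch(synth_cfg):
    """One sharp-train epoch with ground-truth annotations."""
    return generate_epoch("sharp", synth_cfg, seed=42)


@pytest.fixture(scope="session")
def ssw_epoch(synth_cfg):
    return generate_epoch("ssw", synth_cfg, seed=43)


@pytest.fixture(scope="session")
def normal_epoch(synth_cfg):
    return generate_epoch("normal", synth_cfg, seed=44)[0]


def make_epoch(samples, fs=1600.0, **kw):
    return Epoch(samples=np.asarray(samples, dtype=float), fs=fs, **kw)
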