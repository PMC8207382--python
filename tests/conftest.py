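import math

import numpy as np
import pytest

from shellbands import ShellParams, Band, BandConfig
from shellbands.synthesis import (
    default_shell,
    default_allometric_shell,
    default_band_config,
)


@pytest.fixture
def iso_shell() -> ShellParams:
    """Isometric reference shell (all growth rates 0.08/rad, 4 whorls)."""
    return default_shell()


@pytest.fixture
def allo_shell() -> ShellParams:
    """Allometric shell with the axial rate above the radial rate."""
    return default_allometric_shell()


@pytest.fixture
def five_bands() -> BandConfig:
    """Five-banded configuration at the baseline positions/widths."""
    return default_band_config()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
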