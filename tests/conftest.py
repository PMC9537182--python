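import numpy as np
import pytest

from nucimport import synth
from nucimport.volume import MonotoneTimeMap


@pytest.fixture(scope="session")
def volmap():
    """Default synthetic embryo volume map (exponential NCV trajectory)."""
    return synth.default_embryo_volmap()


@pytest.fixture(scope="session")
def linear_volmap():
    """Map with linear NCV(t) = t/100 and linear V_nuc(t) = 1e-9 * t liters."""
    t = np.linspace(1.0, 100.0, 12)
    return MonotoneTimeMap(t, t / 100.0, 1e-9 * t)
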