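import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from polysynergy.io import KdMatrix
from polysynergy.simulate import GrowthParams
from polysynergy import synthetic


@pytest.fixture
def small_kd() -> KdMatrix:
    """3 drugs x 4 kinases with one non-binder cell."""
    return KdMatrix(pd.DataFrame(
        [[10.0, 400.0, 600.0, np.nan],
         [5.0, np.nan, 49.0, 100.0],
         [1000.0, 2000.0, np.nan, 30000.0]],
        index=["dA", "dB", "dC"],
        columns=["k1", "k2", "k3", "k4"]))


@pytest.fixture(scope="session")
def demo_system():
    """The calibrated demo signaling system (shared; treat as read-only)."""
    return synthetic.demo_system()


@pytest.fixture(scope="session")
def demo_system_nogrowth():
    return synthetic.demo_system(growth=GrowthParams(pgrowth0=0))
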