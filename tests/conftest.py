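import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from smx.benchmarks import lorenz_series


@pytest.fixture(scope="session")
def lorenz_x() -> np.ndarray:
    """x-component of a 12000-sample Lorenz trajectory (dt = 0.01), shared
    across the embedding/LLE tests."""
    return lorenz_series(12000, dt=0.01)[:, 0]
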