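import numpy as np
import pandas as pd
import pytest

from demism import load_miner_safety
from demism.panel import DEFAULT_SCALE, ExpertPanel


@pytest.fixture(scope="session")
def fixture_T() -> pd.DataFrame:
    """Bundled 20x20 miner-safety total relation matrix."""
    return load_miner_safety()


@pytest.fixture
def tiny_panel() -> ExpertPanel:
    """2 factors, 1 expert, off-diagonals H."""
    grids = np.array([[["No", "H"], ["H", "No"]]], dtype=object)
    return ExpertPanel(factors=["a", "b"], experts=["e1"], grids=grids,
                       scale=DEFAULT_SCALE)
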