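import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from combostat import AnalysisConfig, ConcentrationGrid, PlateBatch, SimSpec
from combostat.simulate import make_batch


@pytest.fixture
def null_spec() -> SimSpec:
    """Default Bliss-null screen spec (7x9 grid, K=4, heteroscedastic noise)."""
    return SimSpec(seed=42)


@pytest.fixture
def null_batch(null_spec) -> PlateBatch:
    return make_batch(null_spec)


@pytest.fixture
def fast_config() -> AnalysisConfig:
    return AnalysisConfig(B=200, seed=7)


def make_manual_batch(S, concs_A=None, concs_B=None) -> PlateBatch:
    """Batch from an explicit (J+1, I+1, K) survival array."""
    S = np.asarray(S, dtype=float)
    J1, I1, _ = S.shape
    grid = ConcentrationGrid(
        concs_A if concs_A is not None else np.arange(1.0, I1),
        concs_B if concs_B is not None else np.arange(1.0, J1),
    )
    return PlateBatch(grid=grid, S=S)
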