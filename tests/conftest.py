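import numpy as np
import pytest

from gapredox import (
    GapTimeSeries,
    RedoxState,
    SyntheticGapConfig,
    Thermo,
    gen_gap_pair,
)


@pytest.fixture
def thermo() -> Thermo:
    return Thermo(300.0)


@pytest.fixture
def marcus_pair():
    """A Marcus-consistent synthetic reduced/oxidized pair (i.i.d., n=20000)."""
    config = SyntheticGapConfig(
        delta_a_true=6.81,
        lambda_true=1.01,
        n_frames=20000,
        tau_corr=0.0,
        seed=2024,
    )
    return gen_gap_pair(config), config


@pytest.fixture
def small_series(thermo) -> GapTimeSeries:
    return GapTimeSeries(
        state=RedoxState.REDUCED,
        times=np.array([0.0, 0.1, 0.2]),
        gaps=np.array([7.5, 7.9, 7.7]),
        thermo=thermo,
    )
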