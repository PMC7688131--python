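import numpy as np
import pytest

from ras6m import dose_response as dr

SIX_DOSES = np.array([20.0, 10.0, 2.0, 1.0, 0.2, 0.1])


@pytest.fixture
def six_doses():
    """The six standard screening concentrations (uM)."""
    return SIX_DOSES.copy()


@pytest.fixture
def make_points():
    """Factory: exact (optionally noisy) 4PL points at given doses."""

    def _make(a, d, c, b, doses=SIX_DOSES, replicates=1, noise_sd=0.0, seed=0):
        rng = np.random.default_rng(seed)
        conc = np.repeat(np.asarray(doses, dtype=float), replicates)
        growth = dr.four_pl(conc, a, d, c, b)
        if noise_sd:
            growth = growth + rng.normal(0.0, noise_sd, size=conc.shape)
        return dr.points_from_arrays(conc, growth)

    return _make
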