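import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # local oracle helpers

from extremeimpact import AnnualSeries


@pytest.fixture
def rng():
    return np.random.default_rng(20030801)


@pytest.fixture
def linear_series():
    """y = 3 + 2 t over 2000..2009 - exactly linear."""
    years = np.arange(2000, 2010)
    return AnnualSeries(years, 3.0 + 2.0 * (years - 2000))


@pytest.fixture
def random_series(rng):
    def make(n=30, start=1979, trend=0.3, sd=2.0):
        years = np.arange(start, start + n)
        values = 50 + trend * (years - start) + rng.normal(0, sd, n)
        return AnnualSeries(years, values)

    return make
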