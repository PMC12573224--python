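import numpy as np
import pytest

from dendrosync.ringio import RingWidthSeries, SiteMeta


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def simple_series():
    return RingWidthSeries("TST01", "S1", 1990,
                           np.array([1.0, 2.0, 3.0]))


@pytest.fixture
def site_meta():
    return SiteMeta("S1", 47.2, 25.5, "contraction",
                    stand_age=120.0, n_trees=22)


def make_series(rng, tree_id="T01", site_id="S1", first_year=1950, n=74,
                mean=1.2, sd=0.25):
    widths = np.exp(rng.normal(np.log(mean), sd, size=n))
    return RingWidthSeries(tree_id, site_id, first_year, widths)
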