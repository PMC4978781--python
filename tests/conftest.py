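import numpy as np
import pytest

from irtlink import fixture_calibration_tables, load_fixtures


@pytest.fixture(scope="session")
def fixtures():
    return load_fixtures()


@pytest.fixture(scope="session")
def calib_tables():
    """(source, target, cov_source, cov_target) from the packaged example."""
    return fixture_calibration_tables()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)


def random_item(rng, c_max=0.4):
    """A random plausible 3PL item."""
    from irtlink import Item3PL

    return Item3PL(
        a=float(rng.uniform(0.4, 2.5)),
        b=float(rng.uniform(-2.5, 2.5)),
        c=float(rng.uniform(0.0, c_max)),
    )
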