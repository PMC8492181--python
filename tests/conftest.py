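import numpy as np
import pytest
from hypothesis import settings

from txmodels import MechanisticParams, builtin_fixtures

settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def fixtures():
    return builtin_fixtures()


@pytest.fixture(scope="session")
def random_mechanistic():
    """A reproducible batch of log-uniform mechanistic parameter sets."""

    def draw(n, lo=-3.0, hi=1.0, seed=0, require_reducible=None):
        rng = np.random.default_rng(seed)
        out = []
        while len(out) < n:
            a, ar, b, br, c = 10.0 ** rng.uniform(lo, hi, 5)
            p = MechanisticParams(a=a, a_rev=ar, b=b, b_rev=br, c=c, d=1.0, tau=1.0)
            dlt = br + c - a - a**2 / ar
            if require_reducible is True and dlt <= 1e-6:
                continue
            if require_reducible is False and dlt >= -1e-6:
                continue
            out.append(p)
        return out

    return draw
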