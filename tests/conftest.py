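import numpy as np
import pytest
from hypothesis import settings

import betaburrx as bb

settings.register_profile("default", derandomize=True, deadline=None, max_examples=25)
settings.load_profile("default")


@pytest.fixture(scope="session")
def glass():
    """The 63 glass-fibre strengths as a SampleVector."""
    return bb.load_glass_fiber().sample


@pytest.fixture(scope="session")
def p_ref():
    """Canonical four-parameter test point."""
    return bb.BBXParams(2.0, 3.0, 0.5, 1.5)


def bisect_quantile(prob, p, lo=1e-12, hi=100.0, tol=1e-12):
    """Independent quantile oracle: bisection on the CDF."""
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if bb.bbx_cdf(mid, p) < prob:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


@pytest.fixture(scope="session")
def quantile_oracle():
    return bisect_quantile
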