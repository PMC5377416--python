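import math

import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


def hypergeom_tail_oracle(N: int, n: int, m: int, k: int) -> float:
    """Brute-force binomial-coefficient upper tail P(X >= k).

    Exact integer arithmetic (independent of scipy and of the package's
    log-space implementation), divided once at the end.
    """
    hi = min(n, m)
    if k <= 0:
        return 1.0
    if k > hi:
        return 0.0
    num = 0
    for i in range(k, hi + 1):
        if m - i > N - n:
            continue
        num += math.comb(n, i) * math.comb(N - n, m - i)
    return num / math.comb(N, m)


@pytest.fixture(scope="session")
def study_table():
    from mirmeta.datasets import load_study_table

    return load_study_table()


@pytest.fixture(scope="session")
def hub_network():
    from mirmeta.datasets import load_hub_network

    return load_hub_network()


@pytest.fixture(scope="session")
def study_by_id(study_table):
    return {s.study_id: s for s in study_table}
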