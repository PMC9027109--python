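import numpy as np
import pytest

from mcsampen import Signal, fixtures


@pytest.fixture(scope="session")
def toy_signal() -> Signal:
    """(0,0,1,0,0,1,0): at m=1, r=0.5 it has A=6, B=2, SampEn=log 3."""
    return fixtures()["toy"]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1729)


def random_test_signals(count, max_n, seed=815):
    """A mixed bag of short random signals: Gaussian, AR(1), quantized walk.

    Quantization produces ties and exact repeats, exercising the
    closed-tolerance comparison.
    """
    gen = np.random.default_rng(seed)
    out = []
    for k in range(count):
        n = int(gen.integers(10, max_n + 1))
        kind = k % 3
        if kind == 0:
            u = gen.standard_normal(n)
        elif kind == 1:
            eps = gen.standard_normal(n)
            u = np.empty(n)
            u[0] = eps[0]
            for i in range(1, n):
                u[i] = 0.7 * u[i - 1] + eps[i]
        else:
            u = np.round(gen.standard_normal(n).cumsum() * 2) / 2
        out.append(u)
    return out
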