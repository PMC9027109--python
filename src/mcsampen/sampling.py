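"""Uniform sampling of index subsets without replacement.

The Monte-Carlo entropy estimator repeatedly draws N0 distinct
template indices from {0..N-1}.  The workhorse is the Hidden Shuffle
sampler, which emits a uniformly distributed N0-subset using O(N0)
arithmetic operations and RNG draws regardless of the population size
N — crucial when N is in the millions and N0 in the thousands.  A
partial Fisher–Yates sampler (O(N) memory) is provided behind the same
interface for cross-validation, and an exhaustive subset enumerator
serves as the oracle for the distributional theory tests.

All samplers are deterministic given a seed or a
``numpy.random.Generator``.
"""

from __future__ import annotations

import math
from itertools import combinations
from typing import Iterator

import numpy as np

from ._kernels import hidden_shuffle_batch_kernel

__all__ = [
    "hidden_shuffle",
    "hidden_shuffle_batch",
    "fisher_yates_sample",
    "enumerate_subsets",
]

_MAX_ENUMERATION = 10**6


def coerce_rng(rng):
    """Accept a Generator, an integer seed, or any duck-typed source.

    Seeds are always explicit (never wall-clock).  Objects exposing
    the Generator drawing methods pass through untouched, which lets
    tests instrument draw counts.
    """
    if isinstance(rng, np.random.Generator):
        return rng
    if isinstance(rng, (int, np.integer)):
        return np.random.default_rng(int(rng))
    if rng is not None and callable(getattr(rng, "random", None)):
        return rng
    raise ValueError("pass an explicit integer seed or numpy Generator")


def _check_sample_size(N: int, n0: int) -> None:
    if n0 < 1:
        raise ValueError(f"sample size must be >= 1, got {n0}")
    if n0 > N:
        raise ValueError(f"cannot draw {n0} distinct indices from a population of {N}")


def hidden_shuffle(N: int, n0: int, rng) -> np.ndarray:
    """Draw a uniform n0-subset of {0..N-1} with O(n0) work.

    Sequential Hidden Shuffle sampling: every one of the C(N, n0)
    subsets is equally likely, the number of RNG draws is bounded by a
    constant multiple of n0 independent of N, and the result is
    deterministic given the seed.  Returned sorted ascending.
    """
    _check_sample_size(N, n0)
    gen = coerce_rng(rng)
    out = np.empty(n0, dtype=np.int64)
    pos = 0
    H = 0
    i = 0
    if N > n0:
        # Phase 1: how many "high" items survive the virtual shuffle.
        H = n0
        while i < n0:
            q = 1.0 - (N - n0) / (N - i)
            i += int(math.log(1.0 - gen.random()) / math.log(1.0 - q))
            if i < n0:
                p_i = 1.0 - (N - n0) / (N - i)
                if gen.random() * q < p_i:
                    H -= 1
            i += 1
    L = n0 - H
    # Phase 2: high items as descending uniform order statistics on
    # {n0..N-1}; collisions reroute to the low range.
    a = 1.0
    while H > 0:
        s_old = n0 + int(a * (N - n0))
        a = a * (1.0 - gen.random()) ** (1.0 / H)
        s = n0 + int(a * (N - n0))
        if s < s_old:
            out[pos] = (N - 1) - s
            pos += 1
        else:
            L += 1
        H -= 1
    # Phase 3: sequential sampling of the L low items from {0..n0-1}.
    i = 0
    while L > 0:
        u01 = gen.random()
        s = 0
        F = L / (n0 - i)
        while F < u01 and s < (n0 - L - i):
            F = 1.0 - (1.0 - L / (n0 - i - s - 1)) * (1.0 - F)
            s += 1
        L -= 1
        i += s + 1
        out[pos] = (N - 1) - (i - 1)
        pos += 1
    out.sort()
    return out


def hidden_shuffle_batch(N: int, n0: int, draws: int, seed: int) -> np.ndarray:
    """Many independent Hidden Shuffle draws via the compiled kernel.

    Returns a (draws, n0) int64 array; rows are not sorted.  This is
    the sampler the Monte-Carlo estimator uses internally, exposed so
    its distribution can be tested directly.
    """
    _check_sample_size(N, n0)
    if draws < 1:
        raise ValueError("draws must be >= 1")
    return hidden_shuffle_batch_kernel(N, n0, draws, int(seed))


def fisher_yates_sample(N: int, n0: int, rng) -> np.ndarray:
    """Uniform n0-subset via a partial Fisher–Yates shuffle.

    O(N) memory reference sampler used to cross-validate the Hidden
    Shuffle contract.  Returned sorted ascending.
    """
    _check_sample_size(N, n0)
    gen = coerce_rng(rng)
    pool = np.arange(N, dtype=np.int64)
    for k in range(n0):
        j = int(gen.integers(k, N))
        pool[k], pool[j] = pool[j], pool[k]
    out = pool[:n0].copy()
    out.sort()
    return out


def enumerate_subsets(N: int, n0: int) -> Iterator[tuple[int, ...]]:
    """Yield every n0-subset of {0..N-1} exactly once (ascending tuples).

    Guarded against combinatorial explosion: C(N, n0) must not exceed
    10^6.  Used as the exhaustive oracle for expectation/variance
    checks.
    """
    _check_sample_size(N, n0)
    total = math.comb(N, n0)
    if total > _MAX_ENUMERATION:
        raise ValueError(
            f"C({N}, {n0}) = {total} subsets exceeds the enumeration guard "
            f"of {_MAX_ENUMERATION}"
        )
    return combinations(range(N), n0)
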