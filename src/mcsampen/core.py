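"""Exact sample entropy by direct template-pair counting.

Sample entropy (SampEn) quantifies the irregularity of a univariate
time series ``u`` of length ``n``.  For a template length ``m`` and
tolerance ``r``, consider the ``N = n - m - 1`` overlapping templates
``u[i:i+m]`` and ``u[i:i+m+1]``.  Two templates *match* when their
Chebyshev (maximum-norm) distance is at most ``r``.  Writing ``A`` for
the number of unordered matched template pairs at length ``m`` and
``B`` for the count at length ``m + 1``,

    SampEn(u, m, r) = -log(B / A)        if A > 0 and B > 0,
                      -log(2 / (N(N-1))) otherwise,

with the natural logarithm.  ``B/A`` is the empirical conditional
probability that templates agreeing for ``m`` steps also agree at the
next step, so larger SampEn means a less predictable series.

Conventions
-----------
* ``N = n - m - 1`` templates at *both* lengths (the final sample is
  reached only as the last component of length-(m+1) templates).  Some
  SampEn codebases use ``n - m`` templates at length m instead; counts
  then differ slightly.
* Template indices are 0-based: template ``i`` covers ``u[i:i+m]``.
* Matching uses the closed tolerance ``<= r``.
* Normalization divides by the (population) standard deviation only;
  no centering, since Chebyshev distances are translation-invariant.

Counting is quadratic in ``N`` and delegated to compiled kernels; for
long series prefer the Monte-Carlo estimator in
:mod:`mcsampen.estimator`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._kernels import per_template_counts_kernel, range_count_kernel

__all__ = [
    "Signal",
    "EntropyParams",
    "MatchCounts",
    "SampEnResult",
    "chebyshev_distance",
    "normalize_signal",
    "direct_range_count",
    "match_counts",
    "sample_entropy_exact",
]


@dataclass(frozen=True)
class Signal:
    """A univariate real-valued series.

    Wraps a contiguous float64 array; ``sd`` is the population
    standard deviation of the raw values.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.ascontiguousarray(self.values, dtype=np.float64)
        if arr.ndim != 1:
            raise ValueError("signal must be one-dimensional")
        if arr.size == 0:
            raise ValueError("signal is empty")
        if not np.all(np.isfinite(arr)):
            raise ValueError("signal contains non-finite values")
        object.__setattr__(self, "values", arr)

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def sd(self) -> float:
        return float(self.values.std())

    def template_count(self, m: int) -> int:
        """Number of templates N = n - m - 1 available at length m."""
        return self.n - m - 1


@dataclass(frozen=True)
class EntropyParams:
    """Template length ``m`` and tolerance ``r``.

    ``normalized`` records whether ``r`` is meant against a unit-SD
    signal (the usual convention; r = 0.15 assumes it).
    """

    m: int = 4
    r: float = 0.15
    normalized: bool = True

    def __post_init__(self) -> None:
        _check_params(self.m, self.r)


def _check_params(m: int, r: float) -> None:
    if int(m) != m or m < 1:
        raise ValueError(f"template length m must be a positive integer, got {m}")
    if r < 0:
        raise ValueError(f"tolerance r must be nonnegative, got {r}")


def as_signal(signal) -> Signal:
    """Coerce an array-like (or pass through a Signal) to :class:`Signal`."""
    if isinstance(signal, Signal):
        return signal
    return Signal(np.asarray(signal, dtype=np.float64))


def _require_length(sig: Signal, m: int) -> int:
    N = sig.template_count(m)
    if N < 2:
        raise ValueError(
            f"series of length {sig.n} is too short for m={m}: "
            f"need n >= m + 3 so that N = n - m - 1 >= 2"
        )
    return N


def chebyshev_distance(a, b) -> float:
    """Maximum absolute componentwise difference of two equal-length vectors."""
    av = np.asarray(a, dtype=np.float64)
    bv = np.asarray(b, dtype=np.float64)
    if av.shape != bv.shape or av.ndim != 1 or av.size < 1:
        raise ValueError(
            f"expected two equal-length 1-d vectors, got shapes {av.shape} and {bv.shape}"
        )
    return float(np.max(np.abs(av - bv)))


def normalize_signal(signal) -> Signal:
    """Rescale a signal to unit standard deviation (no centering).

    Raises ``ValueError`` for a constant signal (sd = 0), for which a
    tolerance on the unit-SD scale is meaningless.
    """
    sig = as_signal(signal)
    sd = sig.sd
    if sd <= 0.0:
        raise ValueError("cannot normalize a constant signal (standard deviation is 0)")
    return Signal(sig.values / sd)


def _validate_indices(idx, N: int) -> np.ndarray:
    arr = np.ascontiguousarray(idx, dtype=np.int64)
    if arr.ndim != 1:
        raise ValueError("index set must be one-dimensional")
    if arr.size and (arr.min() < 0 or arr.max() >= N):
        raise ValueError(
            f"template indices must lie in [0, {N}); got range "
            f"[{arr.min()}, {arr.max()}]"
        )
    if np.unique(arr).size != arr.size:
        raise ValueError("template indices must be distinct")
    return arr


def direct_range_count(signal, idx, m: int, r: float) -> int:
    """Count unordered template pairs within tolerance, by direct sweep.

    Parameters
    ----------
    signal : Signal or array-like
        The raw series.
    idx : array-like of int, or None
        0-based template indices to compare (None means all N).
    m : int
        Template length used for the comparison.
    r : float
        Chebyshev tolerance.

    Returns the number of unordered pairs {i, j} with
    ``chebyshev(u[i:i+m], u[j:j+m]) <= r``.
    """
    sig = as_signal(signal)
    _check_params(m, r)
    # idx entries must leave room for a length-m template; when m+1
    # windows are counted on indices drawn for template count
    # N = n - m - 1 this always holds.
    max_start = sig.n - m
    if max_start < 1:
        raise ValueError(f"series of length {sig.n} has no length-{m} template")
    if idx is None:
        idx = np.arange(_require_length(sig, m), dtype=np.int64)
    arr = _validate_indices(idx, max_start)
    return int(range_count_kernel(sig.values, arr, m, float(r)))


@dataclass(frozen=True)
class MatchCounts:
    """Per-template and total matched-pair counts at lengths m and m+1."""

    per_template_a: np.ndarray
    per_template_b: np.ndarray
    a: int
    b: int
    n_templates: int

    def __post_init__(self) -> None:
        # Totals are half the per-template sums: each unordered pair
        # increments two templates.
        assert int(self.per_template_a.sum()) == 2 * self.a
        assert int(self.per_template_b.sum()) == 2 * self.b


def match_counts(signal, m: int, r: float) -> MatchCounts:
    """All-pairs match counts over the full template set.

    ``a`` (length m) and ``b`` (length m+1) are unordered pair counts;
    ``per_template_a[i]`` is the number of other templates matching
    template ``i`` at length m (``A_i``), likewise ``per_template_b``.
    """
    sig = as_signal(signal)
    _check_params(m, r)
    N = _require_length(sig, m)
    A_i, B_i = per_template_counts_kernel(sig.values, m, float(r))
    assert A_i.size == N
    return MatchCounts(
        per_template_a=A_i,
        per_template_b=B_i,
        a=int(A_i.sum()) // 2,
        b=int(B_i.sum()) // 2,
        n_templates=N,
    )


@dataclass(frozen=True)
class SampEnResult:
    """Sample entropy with its pair counts and degeneracy flag."""

    value: float
    a: int
    b: int
    degenerate: bool
    n_templates: int
    method: str = "exact"


def sample_entropy_exact(signal, m: int = 4, r: float = 0.15) -> SampEnResult:
    """Exact sample entropy -log(B/A) by direct counting.

    When no matched pair exists at either length (A = 0 or B = 0) the
    conventional fallback ``-log(2 / (N(N-1)))`` is returned with
    ``degenerate=True``: the largest entropy resolvable with N
    templates (one matched pair out of N(N-1)/2).
    """
    counts = match_counts(signal, m, r)
    N = counts.n_templates
    if counts.a > 0 and counts.b > 0:
        value = -math.log(counts.b / counts.a)
        degenerate = False
    else:
        value = -math.log(2.0 / (N * (N - 1)))
        degenerate = True
    return SampEnResult(
        value=value,
        a=counts.a,
        b=counts.b,
        degenerate=degenerate,
        n_templates=N,
    )
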