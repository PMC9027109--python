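"""Moments of the subsampled pair-count estimators, and their oracle.

Let B_l be the per-template match counts of a series (either length-m
counts A_l or length-(m+1) counts B_l — the formulas are identical in
form) with unordered total B = (1/2) sum_l B_l over N templates.  For
a uniform random N0-subset s of the template indices, the subsample
pair rate B~(s) / (N0 (N0 - 1)) is an unbiased estimator of the full
rate:

    E[B~ / (N0(N0-1))] = B / (N(N-1)),

and its variance has the closed form Var = C_N0 / N0, where C_N0 is a
sum of four combinatorial terms in (B, sum_l B_l^2, N, N0) — see
:func:`variance_formula` — bounded by 0 < C_N0 < 1 + 1/(2(N0-1)).
The variance therefore decays like 1/N0 with a constant that never
exceeds ~1.5, which is what makes small subsamples informative.

:func:`enumerated_moments` computes the same moments by brute force:
it evaluates the pair count on *every* N0-subset and takes the exact
population mean and variance under the uniform measure.  It is the
independent oracle against which the closed forms are verified (and
the only route for N0 in {2, 3}, where the four-term formula is used
with its third term vanishing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import _check_params, _require_length, as_signal
from .estimator import single_experiment
from .sampling import enumerate_subsets

__all__ = [
    "VarianceReport",
    "EnumeratedMoments",
    "expectation_formula",
    "variance_formula",
    "enumerated_moments",
]


def expectation_formula(pairs: float, N: int, N0: int) -> float:
    """Expected subsample pair rate E[B~/(N0(N0-1))] = B/(N(N-1)).

    ``pairs`` is the unordered matched-pair total (A or B) over the
    full N templates.  The subsample size N0 affects only validity
    (N0 > 1), not the value — that is the unbiasedness statement.
    """
    if N0 <= 1:
        raise ValueError(f"subsample size N0 must exceed 1, got {N0}")
    if N < 2:
        raise ValueError(f"need at least 2 templates, got N={N}")
    if pairs < 0:
        raise ValueError("pair count cannot be negative")
    return pairs / (N * (N - 1))


@dataclass(frozen=True)
class VarianceReport:
    """Closed-form variance of a subsample pair-rate estimator.

    ``c_n0`` is the variance constant (Var = c_n0 / N0), ``terms`` its
    four additive components, ``bound`` the theoretical ceiling
    1 + 1/(2(N0-1)).  ``boundary_zero`` flags the degenerate
    no-matches case where c_n0 = 0 sits on the lower boundary of the
    strict bound (the bound presumes at least one match).
    """

    c_n0: float
    variance: float
    bound: float
    terms: tuple[float, float, float, float]
    boundary_zero: bool


def variance_formula(per_template, N: int, N0: int) -> VarianceReport:
    """Var[B~/(N0(N0-1))] = C_N0 / N0 from per-template counts.

    ``per_template`` is the sequence of per-template match counts
    (B_l, or A_l for the length-m side); the unordered total is
    B = (1/2) sum_l B_l.  The four terms of C_N0 are

        t1 = B / ((N0-1) N (N-1))
        t2 = (N0-2) (sum B_l^2 - 2B) / ((N0-1) N (N-1) (N-2))
        t3 = (N0-2)(N0-3) (B^2 - sum B_l^2 + B)
             / ((N0-1) N (N-1) (N-2) (N-3))
        t4 = -N0 B^2 / (N^2 (N-1)^2)

    Requires N >= 4 (the denominators divide by (N-2)(N-3)) and
    2 <= N0 <= N; for N0 in {2, 3} the third (and for N0 = 2 also the
    second) term has a vanishing coefficient.
    """
    counts = np.asarray(per_template, dtype=np.float64)
    if counts.ndim != 1 or counts.size != N:
        raise ValueError(f"expected {N} per-template counts, got shape {counts.shape}")
    if np.any(counts < 0):
        raise ValueError("per-template counts cannot be negative")
    total2 = counts.sum()
    if total2 % 2 != 0:
        raise ValueError("per-template counts must sum to an even number (2x pairs)")
    if N < 4:
        raise ValueError(f"variance formula requires N >= 4, got N={N}")
    if N0 < 2 or N0 > N:
        raise ValueError(f"need 2 <= N0 <= N, got N0={N0}, N={N}")
    B = total2 / 2.0
    sq = float((counts**2).sum())
    t1 = B / ((N0 - 1) * N * (N - 1))
    t2 = (N0 - 2) * (sq - 2.0 * B) / ((N0 - 1) * N * (N - 1) * (N - 2))
    t3 = (
        (N0 - 2)
        * (N0 - 3)
        * (B * B - sq + B)
        / ((N0 - 1) * N * (N - 1) * (N - 2) * (N - 3))
    )
    t4 = -N0 * B * B / (float(N) * N * (N - 1) * (N - 1))
    c = t1 + t2 + t3 + t4
    bound = 1.0 + 1.0 / (2.0 * (N0 - 1))
    return VarianceReport(
        c_n0=c,
        variance=c / N0,
        bound=bound,
        terms=(t1, t2, t3, t4),
        boundary_zero=(B == 0.0),
    )


@dataclass(frozen=True)
class EnumeratedMoments:
    """Exact subsample-rate moments from exhaustive enumeration."""

    a_mean: float
    a_var: float
    b_mean: float
    b_var: float
    n_subsets: int


def enumerated_moments(signal, m: int, r: float, N0: int) -> EnumeratedMoments:
    """Exact mean/variance of the subsample pair rates, by brute force.

    Evaluates A~ and B~ on every N0-subset of the N template indices
    (uniform measure) and returns the population mean and variance of
    A~/(N0(N0-1)) and B~/(N0(N0-1)).  Guarded to C(N, N0) <= 10^6
    subsets.
    """
    sig = as_signal(signal)
    _check_params(m, r)
    N = _require_length(sig, m)
    if N0 < 2 or N0 > N:
        raise ValueError(f"need 2 <= N0 <= N, got N0={N0}, N={N}")
    denom = N0 * (N0 - 1)
    a_rates = []
    b_rates = []
    for subset in enumerate_subsets(N, N0):
        idx = np.asarray(subset, dtype=np.int64)
        a, b = single_experiment(sig, idx, m, r)
        a_rates.append(a / denom)
        b_rates.append(b / denom)
    a_arr = np.asarray(a_rates)
    b_arr = np.asarray(b_rates)
    return EnumeratedMoments(
        a_mean=float(a_arr.mean()),
        a_var=float(a_arr.var()),
        b_mean=float(b_arr.mean()),
        b_var=float(b_arr.var()),
        n_subsets=a_arr.size,
    )
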