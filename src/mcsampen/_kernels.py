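"""Compiled inner loops: Chebyshev pair counting and sequential subset sampling.

Everything here is quadratic (pair counting) or performance-critical
(drawing millions of subset indices), so it is compiled with numba.
The kernels operate on contiguous float64/int64 arrays and 0-based
template indices; validation happens in the calling modules.
"""

import math

import numba as nb
import numpy as np


@nb.njit(cache=True)
def range_count_kernel(u, idx, m, r):
    """Unordered pairs {i, j} in ``idx`` whose length-``m`` templates match.

    Templates are u[i:i+m]; a match is Chebyshev distance <= r.  The
    inner comparison loop aborts on the first out-of-tolerance
    component.
    """
    L = idx.shape[0]
    count = 0
    for ii in range(L):
        si = idx[ii]
        for jj in range(ii + 1, L):
            sj = idx[jj]
            ok = True
            for l in range(m):
                if abs(u[si + l] - u[sj + l]) > r:
                    ok = False
                    break
            if ok:
                count += 1
    return count


@nb.njit(cache=True)
def fused_pair_count_kernel(u, idx, m, r):
    """Matched pairs at lengths m and m+1 in one sweep.

    An (m+1)-match implies an m-match of the prefix, so the m+1 check
    runs only for pairs that already matched at length m.  Returns
    (a, b, comps) where comps counts template-pair distance
    evaluations under the two-pass semantics (2 per unordered pair:
    one rho at length m, one at length m+1).

    Templates are first gathered into a contiguous (L, m+1) buffer;
    the scattered subset indices would otherwise defeat the cache in
    the O(L^2) sweep.
    """
    L = idx.shape[0]
    T = np.empty((L, m + 1))
    for i in range(L):
        base = idx[i]
        for l in range(m + 1):
            T[i, l] = u[base + l]
    a = 0
    b = 0
    comps = 0
    for ii in range(L):
        for jj in range(ii + 1, L):
            comps += 2
            ok = True
            for l in range(m):
                if abs(T[ii, l] - T[jj, l]) > r:
                    ok = False
                    break
            if ok:
                a += 1
                if abs(T[ii, m] - T[jj, m]) <= r:
                    b += 1
    return a, b, comps


@nb.njit(cache=True)
def per_template_counts_kernel(u, m, r):
    """Per-template match counts A_i (length m) and B_i (length m+1).

    Full all-pairs sweep over the N = len(u) - m - 1 templates; each
    matching pair increments both endpoints, so sum(A_i) = 2*A.
    """
    N = u.shape[0] - m - 1
    A = np.zeros(N, np.int64)
    B = np.zeros(N, np.int64)
    for i in range(N):
        for j in range(i + 1, N):
            ok = True
            for l in range(m):
                if abs(u[i + l] - u[j + l]) > r:
                    ok = False
                    break
            if ok:
                A[i] += 1
                A[j] += 1
                if abs(u[i + m] - u[j + m]) <= r:
                    B[i] += 1
                    B[j] += 1
    return A, B


@nb.njit(cache=True)
def hidden_shuffle_fill(N, n, out):
    """Fill ``out`` (length n) with a uniform n-subset of {0..N-1}.

    Sequential Hidden Shuffle sampling: O(n) arithmetic operations and
    RNG draws irrespective of N.  Uses numba's internal np.random
    state, so callers must seed it (np.random.seed inside a jitted
    scope) for reproducibility.  The emitted order is two monotone
    blocks, not globally sorted.
    """
    pos = 0
    H = 0
    i = 0
    if N > n:
        # Phase 1: count "high" items surviving the virtual shuffle.
        H = n
        while i < n:
            q = 1.0 - (N - n) / (N - i)
            i += int(math.log(1.0 - np.random.random()) / math.log(1.0 - q))
            if i < n:
                p_i = 1.0 - (N - n) / (N - i)
                if np.random.random() * q < p_i:
                    H -= 1
            i += 1
    L = n - H
    # Phase 2: high items via descending order statistics of uniforms;
    # collisions are rerouted to the low range.
    a = 1.0
    while H > 0:
        s_old = n + int(a * (N - n))
        a = a * (1.0 - np.random.random()) ** (1.0 / H)
        s = n + int(a * (N - n))
        if s < s_old:
            out[pos] = (N - 1) - s
            pos += 1
        else:
            L += 1
        H -= 1
    # Phase 3: sequential sampling of L low items from {0..n-1}.
    i = 0
    while L > 0:
        u01 = np.random.random()
        s = 0
        F = L / (n - i)
        while F < u01 and s < (n - L - i):
            F = 1.0 - (1.0 - L / (n - i - s - 1)) * (1.0 - F)
            s += 1
        L -= 1
        i += s + 1
        out[pos] = (N - 1) - (i - 1)
        pos += 1


@nb.njit(cache=True)
def hidden_shuffle_batch_kernel(N, n, draws, seed):
    """Draw ``draws`` independent n-subsets of {0..N-1}; rows unsorted."""
    np.random.seed(seed)
    out = np.empty((draws, n), np.int64)
    buf = np.empty(n, np.int64)
    for d in range(draws):
        hidden_shuffle_fill(N, n, buf)
        out[d, :] = buf
    return out


@nb.njit(cache=True)
def mc_kernel(u, m, r, n0, n1, seed):
    """n1 independent subsampled counting experiments of size n0.

    Each experiment draws a uniform n0-subset of the N = len(u)-m-1
    template indices via Hidden Shuffle and counts matched pairs at
    lengths m and m+1.  Returns the per-experiment count arrays and
    the total number of template-pair distance evaluations.
    """
    np.random.seed(seed)
    N = u.shape[0] - m - 1
    a_counts = np.empty(n1, np.int64)
    b_counts = np.empty(n1, np.int64)
    idx = np.empty(n0, np.int64)
    comps = 0
    for k in range(n1):
        hidden_shuffle_fill(N, n0, idx)
        a, b, c = fused_pair_count_kernel(u, idx, m, r)
        a_counts[k] = a
        b_counts[k] = b
        comps += c
    return a_counts, b_counts, comps
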