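"""Independent brute-force references for the test suite.

Everything here is written against the definitions only — sliding
windows plus explicit pairwise maxima — and never calls into the
package's counting kernels, so it can serve as the oracle for them.
"""

import numpy as np


def templates(u, m, width=None):
    """The N = len(u) - m - 1 templates of width ``width`` (default m).

    Both the length-m and length-(m+1) template sets contain the same
    N members, indexed by start position.
    """
    u = np.asarray(u, dtype=float)
    N = u.size - m - 1
    return np.lib.stride_tricks.sliding_window_view(u, width or m)[:N]


def brute_per_template_counts(u, m, r):
    """Per-template match counts at lengths m and m+1 by full broadcasting."""
    Xm = templates(u, m)
    Xm1 = templates(u, m, width=m + 1)
    dm = np.abs(Xm[:, None, :] - Xm[None, :, :]).max(axis=2)
    dm1 = np.abs(Xm1[:, None, :] - Xm1[None, :, :]).max(axis=2)
    np.fill_diagonal(dm, np.inf)
    np.fill_diagonal(dm1, np.inf)
    return (dm <= r).sum(axis=1), (dm1 <= r).sum(axis=1)


def brute_totals(u, m, r):
    """Unordered matched-pair totals (A, B)."""
    a_i, b_i = brute_per_template_counts(u, m, r)
    return int(a_i.sum()) // 2, int(b_i.sum()) // 2


def brute_entropy(u, m, r):
    """Sample entropy straight from the definition, with its fallback."""
    u = np.asarray(u, dtype=float)
    N = u.size - m - 1
    a, b = brute_totals(u, m, r)
    if a > 0 and b > 0:
        return -np.log(b / a)
    return -np.log(2.0 / (N * (N - 1)))


def brute_subset_counts(u, idx, m, r):
    """(A~, B~) for an index subset, by explicit python loops."""
    u = np.asarray(u, dtype=float)
    idx = list(idx)
    a = b = 0
    for ii in range(len(idx)):
        for jj in range(ii + 1, len(idx)):
            i, j = idx[ii], idx[jj]
            if max(abs(u[i + l] - u[j + l]) for l in range(m)) <= r:
                a += 1
                if abs(u[i + m] - u[j + m]) <= r:
                    b += 1
    return a, b
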