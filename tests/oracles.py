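"""Independent oracles used by the test suite.

Kept deliberately naive and separate from the library code paths they
check: exhaustive path enumeration for the slope-constrained DTW and a
direct normal-equations solve for OLS.
"""

import numpy as np


def brute_force_constrained_dtw(S, T) -> float:
    """Minimum squared-error distance over all slope-constrained block paths.

    Enumerates every path built from the step blocks (1,1), (2,3), (3,2)
    (with their fixed within-block pairings) from (0,0) to (m,m) by plain
    recursion, no memoization.  Only feasible for small m.
    """
    S = np.asarray(S, float)
    T = np.asarray(T, float)
    m = len(S)

    def d(i, j):  # 1-based
        return (S[i - 1] - T[j - 1]) ** 2

    best = [np.inf]

    def rec(i, j, cost):
        if i == m and j == m:
            best[0] = min(best[0], cost)
            return
        if i > m or j > m:
            return
        # (1,1): pair (i+1, j+1)
        if i + 1 <= m and j + 1 <= m:
            rec(i + 1, j + 1, cost + d(i + 1, j + 1))
        # (2,3): pairs (i+1, j+1), (i+2, j+2), (i+2, j+3)
        if i + 2 <= m and j + 3 <= m:
            rec(i + 2, j + 3, cost + d(i + 1, j + 1) + d(i + 2, j + 2) + d(i + 2, j + 3))
        # (3,2): pairs (i+1, j+1), (i+2, j+2), (i+3, j+2)
        if i + 3 <= m and j + 2 <= m:
            rec(i + 3, j + 2, cost + d(i + 1, j + 1) + d(i + 2, j + 2) + d(i + 3, j + 2))

    rec(0, 0, 0.0)
    return best[0]


def ols_normal_equations(X, y):
    """(intercept, coefficients) from a direct normal-equations solve."""
    A = np.column_stack([np.ones(len(X)), X])
    beta = np.linalg.solve(A.T @ A, A.T @ y)
    return beta[0], beta[1:]
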