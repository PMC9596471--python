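"""Slope-constrained dynamic time warping between equal-length spectra.

Nanopore translocation speed varies along a molecule, so an empirical
spectrum S and a theoretical spectrum T of the same length m are aligned by
DTW.  Unconstrained DTW suffers from the singularity problem (a short
window matched against a long one), so warping here is restricted to three
step blocks,

* ``(1,1)`` — one point of S against one point of T,
* ``(2,3)`` — two points of S against three points of T,
* ``(3,2)`` — three points of S against two points of T,

whose reachable local slopes are exactly {1, 2/3, 3/2}: the ratio between
any two matched time periods stays within [2/3, 3/2], i.e. 6 points of T
are consumed by between 4 and 9 points of S.  The pair cost is the squared
error d(s, t) = (s - t)^2 and an (m+1) x (m+1) table is filled in O(m^2).

Both inputs must be z-normalized; the match score is the Pearson
correlation of the two sequences read along the optimal warp path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "WarpPath",
    "AlignmentResult",
    "constrained_dtw",
    "pcc",
    "pcc_on_path",
    "check_slope_constraint",
    "unconstrained_dtw_distance",
]

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


# Step blocks as (di, dj, pair offsets from the block end (i, j)).
# (2,3): pairs (i-1, j-2), (i, j-1), (i, j); (3,2) symmetric.  The middle
# point of the longer side pairs with the later point of the shorter side,
# so every index is matched exactly once per block and the cost is additive.
_BLOCKS = (
    (1, 1, ((0, 0),)),
    (2, 3, ((-1, -2), (0, -1), (0, 0))),
    (3, 2, ((-2, -1), (-1, 0), (0, 0))),
)


@njit(cache=True)
def _dtw_table(s, t):  # pragma: no cover - numba kernel
    m = s.shape[0]
    D = np.full((m + 1, m + 1), np.inf)
    D[0, 0] = 0.0
    for i in range(1, m + 1):
        si = s[i - 1]
        for j in range(1, m + 1):
            d11 = (si - t[j - 1]) ** 2
            best = D[i - 1, j - 1] + d11
            if i >= 2 and j >= 3:
                c = (
                    D[i - 2, j - 3]
                    + (s[i - 2] - t[j - 3]) ** 2
                    + (si - t[j - 2]) ** 2
                    + d11
                )
                if c < best:
                    best = c
            if i >= 3 and j >= 2:
                c = (
                    D[i - 3, j - 2]
                    + (s[i - 3] - t[j - 2]) ** 2
                    + (s[i - 2] - t[j - 1]) ** 2
                    + d11
                )
                if c < best:
                    best = c
            D[i, j] = best
    return D


@dataclass(frozen=True)
class WarpPath:
    """Monotone matching between two length-m spectra.

    ``pairs`` are 1-based index pairs (i, j) from (1, 1) to (m, m);
    ``blocks`` records the step-block sequence ((di, dj), ...) realizing it.
    """

    pairs: tuple
    blocks: tuple
    m: int


@dataclass(frozen=True)
class AlignmentResult:
    distance: float
    path: WarpPath
    pcc: float


def _block_cost(s, t, i, j, offsets) -> float:
    return sum((s[i + oi - 1] - t[j + oj - 1]) ** 2 for oi, oj in offsets)


def _traceback(D, s, t) -> WarpPath:
    m = len(s)
    i, j = m, m
    blocks_rev = []
    while (i, j) != (0, 0):
        target = D[i, j]
        chosen = None
        for di, dj, offsets in _BLOCKS:  # deterministic priority: (1,1),(2,3),(3,2)
            pi, pj = i - di, j - dj
            if pi < 0 or pj < 0 or not np.isfinite(D[pi, pj]):
                continue
            cand = D[pi, pj] + _block_cost(s, t, i, j, offsets)
            if abs(cand - target) <= 1e-9 * max(1.0, abs(target)):
                chosen = (di, dj, offsets)
                break
        if chosen is None:  # pragma: no cover - defensive
            raise RuntimeError(f"traceback stuck at cell ({i}, {j})")
        di, dj, offsets = chosen
        blocks_rev.append((di, dj, i, j))
        i, j = i - di, j - dj
    pairs = []
    for di, dj, bi, bj in reversed(blocks_rev):
        offsets = next(o for d1, d2, o in _BLOCKS if (d1, d2) == (di, dj))
        pairs.extend((bi + oi, bj + oj) for oi, oj in offsets)
    return WarpPath(
        pairs=tuple(pairs),
        blocks=tuple((di, dj) for di, dj, _, _ in reversed(blocks_rev)),
        m=m,
    )


def _require_normalized(x, name) -> np.ndarray:
    x = np.asarray(x, float)
    if abs(x.mean()) > 1e-6 or abs(x.std() - 1.0) > 1e-6:
        raise ValueError(f"{name} is not z-normalized (mean 0, SD 1 required)")
    return x


def constrained_dtw(S, T) -> AlignmentResult:
    """Optimal slope-constrained warp between z-normalized S and T.

    Returns the total squared-error distance, one optimal warp path
    (deterministic tie-break preferring (1,1), then (2,3), then (3,2))
    and the Pearson correlation along the path.
    """
    S = _require_normalized(S, "S")
    T = _require_normalized(T, "T")
    if len(S) != len(T):
        raise ValueError(f"length mismatch: {len(S)} vs {len(T)}")
    if len(S) < 3:
        raise ValueError("spectra must have at least 3 points")
    D = _dtw_table(np.ascontiguousarray(S), np.ascontiguousarray(T))
    path = _traceback(D, S, T)
    return AlignmentResult(float(D[-1, -1]), path, pcc_on_path(S, T, path))


def pcc(X, Y) -> float:
    """Pearson correlation coefficient of two equal-length vectors."""
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if X.shape != Y.shape or X.ndim != 1 or len(X) < 2:
        raise ValueError("inputs must be 1-D, equal length >= 2")
    if X.std() == 0 or Y.std() == 0:
        raise ValueError("undefined correlation for a constant input")
    return float(np.corrcoef(X, Y)[0, 1])


def pcc_on_path(S, T, path: WarpPath) -> float:
    """PCC of S and T read along the warp path (each pair contributes once)."""
    idx = np.array(path.pairs, int)
    return pcc(np.asarray(S, float)[idx[:, 0] - 1], np.asarray(T, float)[idx[:, 1] - 1])


def check_slope_constraint(path: WarpPath, window: int = 6, lo: int = 4, hi: int = 9) -> None:
    """Audit a warp path against the slope constraint.

    Raises ``ValueError`` if any run of ``window`` consecutive T indices is
    matched by fewer than ``lo`` or more than ``hi`` S indices, or if either
    side stalls for more than two consecutive pairs (a singularity).
    """
    pairs = np.array(path.pairs, int)
    m = path.m
    if tuple(pairs[0]) != (1, 1) or tuple(pairs[-1]) != (m, m):
        raise ValueError("path does not span (1,1)..(m,m)")
    if np.any(np.diff(pairs, axis=0) < 0):
        raise ValueError("path is not monotone")
    for col, name in ((0, "S"), (1, "T")):
        run = 1
        for a, b in zip(pairs[:-1, col], pairs[1:, col]):
            run = run + 1 if a == b else 1
            if run > 2:
                raise ValueError(f"singularity: {name} index repeated {run} times")
    for col, name in ((0, "S"), (1, "T")):
        if len(np.unique(pairs[:, col])) != m:
            raise ValueError(f"path does not cover every {name} index")
    # min/max S index matched to each T index
    min_i = np.full(m + 1, np.iinfo(int).max)
    max_i = np.zeros(m + 1, int)
    for i, j in pairs:
        min_i[j] = min(min_i[j], i)
        max_i[j] = max(max_i[j], i)
    for j0 in range(1, m - window + 2):
        span = max_i[j0 + window - 1] - min_i[j0] + 1
        if not lo <= span <= hi:
            raise ValueError(
                f"slope constraint violated: T window [{j0}, {j0 + window - 1}] "
                f"matched by {span} S points (allowed {lo}..{hi})"
            )


def unconstrained_dtw_distance(S, T) -> float:
    """Classic DTW (steps (1,0), (0,1), (1,1); squared error).

    Reference lower bound for the constrained distance; used for sanity
    checks, not in the analysis pipeline.
    """
    S = np.asarray(S, float)
    T = np.asarray(T, float)
    m, n = len(S), len(T)
    D = np.full((m + 1, n + 1), np.inf)
    D[0, 0] = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            d = (S[i - 1] - T[j - 1]) ** 2
            D[i, j] = d + min(D[i - 1, j - 1], D[i - 1, j], D[i, j - 1])
    return float(D[m, n])
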