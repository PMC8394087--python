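"""Longitudinal (temporal) alignment of two pullbacks by dynamic time warping.

The per-frame-pair cost is ``d(i, j) = 1 - |CC(i, j)|`` where CC is the
Pearson cross-correlation of the two frames' pixel vectors, so the cost
needs no segmentation or morphological features.  The accumulated cost
follows the regularized recurrence

    D(i, j) = d(i, j) + min(D(i, j-1) + C, D(i-1, j) + C, D(i-1, j-1)),

where the regularizer ``C >= 0`` penalizes vertical/horizontal steps and
thereby favours diagonal (one-to-one) matching while still allowing
one frame to correspond to several frames of the other pullback.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .io_core import FramePairMatch, Pullback, WarpingPath

__all__ = [
    "DtwConfig",
    "DtwResult",
    "cross_correlation",
    "frame_dissimilarity",
    "cost_matrix",
    "dtw_accumulate",
    "backtrack",
    "register_longitudinal",
]


@dataclasses.dataclass(frozen=True)
class DtwConfig:
    """DTW stage parameters.

    diagonal_regularizer
        The additive cost C charged to vertical and horizontal steps
        (on the [0, 1] dissimilarity scale).
    open_boundaries
        When true (default), the alignment is a subsequence match: the
        path may start and end anywhere along one pullback while fully
        covering the other, accommodating partially overlapping
        pullbacks.  :func:`register_longitudinal` evaluates both
        orientations and keeps the one with the lower per-step average
        cost.  (Freeing the start on both sequences at once makes the
        unnormalized recurrence prefer arbitrarily short near-corner
        paths, so that formulation is not used.)
    max_band
        Optional Sakoe-Chiba band half-width restricting the path to a
        corridor around the (scaled) main diagonal; ``None`` disables it.
    """

    diagonal_regularizer: float = 0.05
    open_boundaries: bool = True
    max_band: int | None = None

    def __post_init__(self) -> None:
        if self.diagonal_regularizer < 0:
            raise ValueError("diagonal_regularizer must be >= 0")
        if self.max_band is not None and self.max_band < 0:
            raise ValueError("max_band must be >= 0 when given")


@dataclasses.dataclass
class DtwResult:
    """Cost matrix, accumulated matrix, warping path and its total cost.

    ``transposed`` records whether the open-boundary alignment was
    carried out on the transposed cost matrix (pullback A treated as
    the subsequence); ``accumulated`` is shaped accordingly, while
    ``path`` always indexes (frame of A, frame of B).
    """

    cost_matrix: np.ndarray
    accumulated: np.ndarray
    path: WarpingPath
    total_cost: float
    transposed: bool = False


def cross_correlation(frame_a: np.ndarray, frame_b: np.ndarray) -> float:
    """Pearson correlation of the flattened pixel vectors, in [-1, 1].

    A constant frame carries no alignment information; if either frame
    is constant the correlation is defined as 0 (with a warning).
    """
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"frame shapes differ: {a.shape} vs {b.shape}")
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        warnings.warn("constant frame in cross-correlation; returning 0", stacklevel=2)
        return 0.0
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def frame_dissimilarity(frame_a: np.ndarray, frame_b: np.ndarray) -> float:
    """Dissimilarity ``1 - |CC|`` in [0, 1]."""
    return 1.0 - abs(cross_correlation(frame_a, frame_b))


def cost_matrix(pullback_a: Pullback, pullback_b: Pullback) -> np.ndarray:
    """Pairwise dissimilarities, entry (i, j) = ``1 - |CC(a_i, b_j)|``.

    Vectorized over both stacks; constant frames yield dissimilarity 1
    against everything (their correlation is defined as 0).
    """
    if pullback_a.frame_shape != pullback_b.frame_shape:
        raise ValueError(
            f"frame shapes differ across pullbacks: "
            f"{pullback_a.frame_shape} vs {pullback_b.frame_shape}"
        )
    a = pullback_a.frames.reshape(len(pullback_a), -1).astype(float)
    b = pullback_b.frames.reshape(len(pullback_b), -1).astype(float)
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    const_a, const_b = na == 0.0, nb == 0.0
    if const_a.any() or const_b.any():
        warnings.warn("constant frame(s) in cost matrix; correlation set to 0",
                      stacklevel=2)
    na = np.where(const_a, 1.0, na)
    nb = np.where(const_b, 1.0, nb)
    cc = (a / na[:, None]) @ (b / nb[:, None]).T
    cc[const_a, :] = 0.0
    cc[:, const_b] = 0.0
    return np.clip(1.0 - np.abs(cc), 0.0, 1.0)


def _band_mask(n: int, m: int, half_width: int) -> np.ndarray:
    """Boolean mask of cells inside the Sakoe-Chiba corridor."""
    i = np.arange(n)[:, None]
    j = np.arange(m)[None, :]
    diag = i * ((m - 1) / (n - 1)) if n > 1 else np.zeros_like(i, dtype=float)
    return np.abs(diag - j) <= half_width


def dtw_accumulate(costs: np.ndarray, config: DtwConfig = DtwConfig()) -> np.ndarray:
    """Accumulated cost matrix D under the regularized recurrence.

    Closed boundaries: D(0,0) = d(0,0) and the first row/column are
    accumulated with the +C step penalty.  Open boundaries
    (subsequence alignment): the first column is initialized to the
    raw costs, so the path may start at any row while covering every
    column; run on the transposed costs for the other orientation.
    """
    d = np.asarray(costs, dtype=float)
    if d.ndim != 2 or d.size == 0 or not np.all(np.isfinite(d)):
        raise ValueError("costs must be a finite 2-D array")
    n, m = d.shape
    C = config.diagonal_regularizer
    inside = (
        _band_mask(n, m, config.max_band)
        if config.max_band is not None
        else np.ones((n, m), dtype=bool)
    )
    D = np.full((n, m), np.inf)
    if config.open_boundaries:
        D[:, 0] = d[:, 0]
        for j in range(1, m):
            D[0, j] = D[0, j - 1] + d[0, j] + C
    else:
        D[0, 0] = d[0, 0]
        for j in range(1, m):
            D[0, j] = D[0, j - 1] + d[0, j] + C
        for i in range(1, n):
            D[i, 0] = D[i - 1, 0] + d[i, 0] + C
    for i in range(1, n):
        row_d = d[i]
        prev = D[i - 1]
        cur = D[i]
        for j in range(1, m):
            if not inside[i, j]:
                continue
            best = prev[j - 1]
            v = prev[j] + C
            if v < best:
                best = v
            h = cur[j - 1] + C
            if h < best:
                best = h
            if np.isfinite(best):
                cur[j] = row_d[j] + best
    return D


def _predecessor(D: np.ndarray, i: int, j: int, C: float) -> tuple[int, int]:
    """Predecessor of (i, j) under the recurrence; ties favour the
    diagonal, then the vertical, then the horizontal step."""
    diag = D[i - 1, j - 1]
    vert = D[i - 1, j] + C
    horiz = D[i, j - 1] + C
    if diag <= vert and diag <= horiz:
        return i - 1, j - 1
    if vert <= horiz:
        return i - 1, j
    return i, j - 1


def backtrack(D: np.ndarray, config: DtwConfig = DtwConfig()) -> WarpingPath:
    """Trace the optimal warping path back through the accumulated matrix.

    For closed boundaries the path runs from (n-1, m-1) back to (0, 0).
    For open boundaries the end cell is the minimum of the last column
    (the bottom-right corner wins ties, then cells from the bottom up),
    and the path stops when it reaches the first column (the free
    start); every column is therefore covered.
    """
    n, m = D.shape
    C = config.diagonal_regularizer
    if config.open_boundaries:
        order = np.concatenate(([n - 1], np.arange(n - 2, -1, -1)))
        end = (int(order[int(np.argmin(D[order, m - 1]))]), m - 1)
    else:
        end = (n - 1, m - 1)
    i, j = end
    path = [(i, j)]
    while True:
        if config.open_boundaries and j == 0:
            break
        if i == 0 and j == 0:
            break
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            i, j = _predecessor(D, i, j, C)
        path.append((i, j))
    return WarpingPath(np.array(path[::-1], dtype=int))


def register_longitudinal(
    pullback_a: Pullback,
    pullback_b: Pullback,
    config: DtwConfig = DtwConfig(),
) -> tuple[DtwResult, list[FramePairMatch]]:
    """Full longitudinal stage: cost matrix, accumulation, backtracking.

    With open boundaries both subsequence orientations (B within A and
    A within B) are aligned and the one with the lower per-step average
    cost is kept.  Returns the DTW result plus one
    :class:`FramePairMatch` per path element; a frame may appear in
    several matches (one-to-many).
    """
    costs = cost_matrix(pullback_a, pullback_b)
    D = dtw_accumulate(costs, config)
    path = backtrack(D, config)
    transposed = False
    if config.open_boundaries:
        D_t = dtw_accumulate(costs.T, config)
        path_t = backtrack(D_t, config)
        end = tuple(path.pairs[-1])
        end_t = tuple(path_t.pairs[-1])
        if D_t[end_t] / len(path_t) < D[end] / len(path):
            D, path, transposed = D_t, WarpingPath(path_t.pairs[:, ::-1]), True
    end = tuple(path.pairs[-1]) if not transposed else tuple(path.pairs[-1][::-1])
    result = DtwResult(
        cost_matrix=costs,
        accumulated=D,
        path=path,
        total_cost=float(D[end]),
        transposed=transposed,
    )
    matches = [
        FramePairMatch(index_a=int(i), index_b=int(j), dissimilarity=float(costs[i, j]))
        for i, j in path.pairs
    ]
    return result, matches
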