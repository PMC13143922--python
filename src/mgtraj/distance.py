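"""Dynamic Time Warping distance between patient trajectories.

DTW aligns two series by stretching/compressing the time axis, so two
patients showing the same dose "overshoot" pattern a visit or two apart are
recognised as similar. Local cost is |a_i - b_j| (L1) and the reported
distance is the unnormalised sum of local costs along the optimal monotone
warp path (symmetric step pattern, no window by default; trajectories here
are short, ~31 points). A path-length-normalised variant and a Sakoe-Chiba
window are available as options.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["WarpPath", "DistanceMatrix", "dtw_distance", "pairwise_matrix",
           "dtw_brute_force"]


@dataclass
class WarpPath:
    """Monotone alignment: (i, j) index pairs from (0,0) to (n-1, m-1)."""

    pairs: list[tuple[int, int]]

    def __post_init__(self):
        if not self.pairs:
            raise ValueError("empty warp path")

    def is_valid(self, n: int, m: int) -> bool:
        if self.pairs[0] != (0, 0) or self.pairs[-1] != (n - 1, m - 1):
            return False
        steps = {(1, 0), (0, 1), (1, 1)}
        return all(
            (b[0] - a[0], b[1] - a[1]) in steps
            for a, b in zip(self.pairs, self.pairs[1:])
        )


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative pairwise DTW distances with an id order."""

    values: np.ndarray
    ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape must match id count")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.values < 0):
            raise ValueError("distances must be nonnegative")

    def __len__(self) -> int:
        return len(self.ids)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def dtw_distance(
    a: np.ndarray,
    b: np.ndarray,
    window: int | None = None,
    normalize: bool = False,
) -> tuple[float, WarpPath]:
    """Optimal-warp L1 distance and an attaining path.

    ``window`` restricts |i - j| (Sakoe-Chiba band); ``normalize`` divides the
    path sum by the path length.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty input sequence")
    n, m = len(a), len(b)
    if window is not None and window < abs(n - m):
        raise ValueError("window too small to reach the end of both sequences")
    cost = np.abs(a[:, None] - b[None, :])
    if window is not None:
        ii, jj = np.indices((n, m))
        cost = np.where(np.abs(ii - jj) <= window, cost, np.inf)
    acc = np.full((n + 1, m + 1), np.inf)
    acc[0, 0] = 0.0
    for i in range(1, n + 1):
        # row-vectorised DP: predecessor minimum of insert/delete/match
        prev = np.minimum(acc[i - 1, 1:], acc[i - 1, :-1])
        row = acc[i]
        row[0] = np.inf
        c = cost[i - 1]
        for j in range(1, m + 1):
            row[j] = c[j - 1] + min(prev[j - 1], row[j - 1])
    # backtrack
    pairs = [(n - 1, m - 1)]
    i, j = n, m
    while (i, j) != (1, 1):
        moves = []
        if i > 1 and j > 1:
            moves.append((acc[i - 1, j - 1], (i - 1, j - 1)))
        if i > 1:
            moves.append((acc[i - 1, j], (i - 1, j)))
        if j > 1:
            moves.append((acc[i, j - 1], (i, j - 1)))
        _, (i, j) = min(moves, key=lambda t: t[0])
        pairs.append((i - 1, j - 1))
    pairs.reverse()
    d = float(acc[n, m])
    if normalize:
        d /= len(pairs)
    return d, WarpPath(pairs)


def dtw_brute_force(a: np.ndarray, b: np.ndarray) -> float:
    """Exhaustive enumeration of every monotone warp path (oracle, tiny n)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n, m = len(a), len(b)
    best = [np.inf]

    def walk(i: int, j: int, total: float) -> None:
        total += abs(a[i] - b[j])
        if total >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = total
            return
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, total)
        if i + 1 < n:
            walk(i + 1, j, total)
        if j + 1 < m:
            walk(i, j + 1, total)

    walk(0, 0, 0.0)
    return best[0]


def pairwise_matrix(trajs, window: int | None = None,
                    normalize: bool = False) -> DistanceMatrix:
    """DTW distance between every pair of trajectories on a common grid."""
    if len(trajs) < 2:
        raise ValueError("need at least 2 trajectories")
    g0 = trajs[0].grid
    if any(t.grid != g0 for t in trajs):
        raise ValueError("trajectories are on mixed grids")
    n = len(trajs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d, _ = dtw_distance(trajs[i].values, trajs[j].values,
                                window=window, normalize=normalize)
            D[i, j] = D[j, i] = d
    return DistanceMatrix(D, [t.patient_id for t in trajs])
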