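"""Independent brute-force oracles used to validate the dynamic programs."""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist


def _enumerate_paths(m: int, n: int):
    """All monotone step-{(1,0),(0,1),(1,1)} paths from (0,0) that end the
    moment row m-1 is consumed (at any column)."""
    stack = [((0, 0),)]
    while stack:
        path = stack.pop()
        i, j = path[-1]
        if i == m - 1:
            yield path
            # may still extend along the last row before terminating
            if j < n - 1:
                stack.append(path + ((i, j + 1),))
            continue
        if j < n - 1:
            stack.append(path + ((i, j + 1),))
        stack.append(path + ((i + 1, j),))
        if j < n - 1:
            stack.append(path + ((i + 1, j + 1),))


def oe_dtw_brute(a: np.ndarray, b: np.ndarray) -> float:
    """Exhaustive open-ended DTW dissimilarity.

    Enumerates every admissible open-ended path, finds the minimum
    accumulated cost, and normalises by that path's length (ties resolved
    toward the smaller normalised value). For equal lengths both
    orientations are taken, mirroring the symmetric convention.
    """

    def directed(short: np.ndarray, long_: np.ndarray) -> float:
        cost = cdist(short.T, long_.T)
        best_acc = np.inf
        best_d = np.inf
        for path in _enumerate_paths(cost.shape[0], cost.shape[1]):
            acc = float(sum(cost[i, j] for i, j in path))
            if acc < best_acc - 1e-12:
                best_acc = acc
                best_d = acc / len(path)
            elif abs(acc - best_acc) <= 1e-12:
                best_d = min(best_d, acc / len(path))
        return best_d

    la, lb = a.shape[1], b.shape[1]
    if la < lb:
        return directed(a, b)
    if lb < la:
        return directed(b, a)
    return min(directed(a, b), directed(b, a))
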