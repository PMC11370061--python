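"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: the DTW oracle
enumerates every monotone endpoint-matched warping path explicitly, and the
label-alignment oracle tries all k! permutations.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
from scipy.spatial.distance import cdist


def dtw_bruteforce(a: np.ndarray, b: np.ndarray, normalize: bool = True) -> float:
    """Minimum symmetric2 path cost by exhaustive path enumeration.

    A path starts at (0, 0) with cost d(0, 0) and moves by (1, 1) (adding
    2*d), (1, 0) or (0, 1) (adding d) until it reaches (N-1, M-1).
    Exponential — only for series of a handful of frames.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    local = cdist(a, b)
    n, m = local.shape
    best = [np.inf]

    def walk(i: int, j: int, cost: float) -> None:
        if cost >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = cost
            return
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, cost + 2.0 * local[i + 1, j + 1])
        if i + 1 < n:
            walk(i + 1, j, cost + local[i + 1, j])
        if j + 1 < m:
            walk(i, j + 1, cost + local[i, j + 1])

    walk(0, 0, float(local[0, 0]))
    return best[0] / (n + m) if normalize else best[0]


def align_bruteforce(reference: np.ndarray, candidate: np.ndarray, k: int) -> float:
    """Minimum disagreement fraction over all k! candidate relabelings."""
    reference = np.asarray(reference)
    candidate = np.asarray(candidate)
    best = np.inf
    for perm in permutations(range(k)):
        mapped = np.array([perm[c] for c in candidate])
        best = min(best, float(np.mean(mapped != reference)))
    return best
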