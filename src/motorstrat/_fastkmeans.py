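"""Compiled k-means (k-means++ init, Lloyd iterations, multiple restarts).

The stability analysis and the Gaussian-null simulation each run thousands
of small k-means fits (tens of points, 2-3 dimensions); this numba kernel
removes per-call overhead. It is algorithmically the standard k-means++
plus Lloyd procedure and is cross-checked against scikit-learn in the test
suite; the final reported clustering uses scikit-learn's estimator.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["kmeans_labels"]


@njit(cache=False)
def _pp_init(X, k):
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]))
    first = np.random.randint(0, n)
    centers[0] = X[first]
    d2 = np.empty(n)
    for i in range(n):
        d2[i] = np.sum((X[i] - centers[0]) ** 2)
    for c in range(1, k):
        total = d2.sum()
        if total <= 0.0:
            centers[c] = X[np.random.randint(0, n)]
            continue
        r = np.random.random() * total
        acc = 0.0
        idx = n - 1
        for i in range(n):
            acc += d2[i]
            if acc >= r:
                idx = i
                break
        centers[c] = X[idx]
        for i in range(n):
            nd = np.sum((X[i] - centers[c]) ** 2)
            if nd < d2[i]:
                d2[i] = nd
    return centers


@njit(cache=False)
def _lloyd(X, centers, max_iter, tol):
    n, p = X.shape
    k = centers.shape[0]
    labels = np.zeros(n, dtype=np.int64)
    inertia = np.inf
    for _ in range(max_iter):
        new_inertia = 0.0
        for i in range(n):
            best = np.inf
            bj = 0
            for j in range(k):
                d = 0.0
                for q in range(p):
                    diff = X[i, q] - centers[j, q]
                    d += diff * diff
                if d < best:
                    best = d
                    bj = j
            labels[i] = bj
            new_inertia += best
        counts = np.zeros(k)
        sums = np.zeros((k, p))
        for i in range(n):
            counts[labels[i]] += 1.0
            for q in range(p):
                sums[labels[i], q] += X[i, q]
        for j in range(k):
            if counts[j] > 0:
                for q in range(p):
                    centers[j, q] = sums[j, q] / counts[j]
            else:
                # empty cluster: seize the point farthest from its center
                worst = -1.0
                wi = 0
                for i in range(n):
                    d = 0.0
                    for q in range(p):
                        diff = X[i, q] - centers[labels[i], q]
                        d += diff * diff
                    if d > worst:
                        worst = d
                        wi = i
                for q in range(p):
                    centers[j, q] = X[wi, q]
        if abs(inertia - new_inertia) <= tol * abs(new_inertia):
            inertia = new_inertia
            break
        inertia = new_inertia
    return labels, inertia


@njit(cache=False)
def _kmeans(X, k, n_init, seed, max_iter, tol):
    np.random.seed(seed)
    best_inertia = np.inf
    best_labels = np.zeros(X.shape[0], dtype=np.int64)
    for _ in range(n_init):
        centers = _pp_init(X, k)
        labels, inertia = _lloyd(X, centers, max_iter, tol)
        if inertia < best_inertia:
            best_inertia = inertia
            best_labels = labels.copy()
    return best_labels, best_inertia


def kmeans_labels(
    X: np.ndarray,
    k: int,
    n_init: int = 10,
    seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> tuple[np.ndarray, float]:
    """Best-of-``n_init`` k-means labels and inertia."""
    X = np.ascontiguousarray(X, dtype=np.float64)
    labels, inertia = _kmeans(X, int(k), int(n_init), int(seed) % (2**31), int(max_iter), float(tol))
    return labels, float(inertia)
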