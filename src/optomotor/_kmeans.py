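"""Compiled k-means for the consensus subsampling loop.

The consensus stage runs k-means tens of thousands of times on small
subsampled matrices (a few hundred rows, a handful of columns), where
per-call overhead of a general-purpose implementation dominates.  This is a
standard k-means++ / Lloyd implementation with multiple restarts, JIT
compiled with numba, exiting each restart as soon as its assignment is
stable.  Partitions are tested against scikit-learn on fixtures.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["kmeans_labels"]


@njit(cache=False)
def _kmeans_best(X, k, restarts, max_iter, seed):  # pragma: no cover - compiled
    np.random.seed(seed)
    n, p = X.shape
    best_inertia = np.inf
    best_labels = np.zeros(n, dtype=np.int64)
    centers = np.empty((k, p))
    new_centers = np.empty((k, p))
    counts = np.empty(k, dtype=np.int64)
    d2 = np.empty(n)
    labels = np.empty(n, dtype=np.int64)
    for _r in range(restarts):
        # --- k-means++ seeding ---
        i0 = np.random.randint(0, n)
        for j in range(p):
            centers[0, j] = X[i0, j]
        for i in range(n):
            s = 0.0
            for j in range(p):
                d = X[i, j] - centers[0, j]
                s += d * d
            d2[i] = s
        for c in range(1, k):
            total = 0.0
            for i in range(n):
                total += d2[i]
            if total <= 0.0:
                idx = np.random.randint(0, n)
            else:
                u = np.random.random() * total
                acc = 0.0
                idx = n - 1
                for i in range(n):
                    acc += d2[i]
                    if acc >= u:
                        idx = i
                        break
            for j in range(p):
                centers[c, j] = X[idx, j]
            for i in range(n):
                s = 0.0
                for j in range(p):
                    d = X[i, j] - centers[c, j]
                    s += d * d
                if s < d2[i]:
                    d2[i] = s
        # --- Lloyd iterations, exit when the assignment is stable ---
        for i in range(n):
            labels[i] = -1
        for _it in range(max_iter):
            changed = False
            for i in range(n):
                best = np.inf
                arg = 0
                for c in range(k):
                    s = 0.0
                    for j in range(p):
                        d = X[i, j] - centers[c, j]
                        s += d * d
                    if s < best:
                        best = s
                        arg = c
                d2[i] = best
                if arg != labels[i]:
                    labels[i] = arg
                    changed = True
            if not changed:
                break
            new_centers[:] = 0.0
            counts[:] = 0
            for i in range(n):
                c = labels[i]
                counts[c] += 1
                for j in range(p):
                    new_centers[c, j] += X[i, j]
            for c in range(k):
                if counts[c] > 0:
                    for j in range(p):
                        centers[c, j] = new_centers[c, j] / counts[c]
                else:
                    # reseed an empty cluster at the farthest point
                    far = 0
                    fd = -1.0
                    for i in range(n):
                        if d2[i] > fd:
                            fd = d2[i]
                            far = i
                    for j in range(p):
                        centers[c, j] = X[far, j]
                    d2[far] = 0.0
        inertia = 0.0
        for i in range(n):
            inertia += d2[i]
        if inertia < best_inertia:
            best_inertia = inertia
            for i in range(n):
                best_labels[i] = labels[i]
    return best_labels


def kmeans_labels(
    X: np.ndarray,
    k: int,
    rng: np.random.Generator,
    restarts: int = 25,
    max_iter: int = 100,
) -> np.ndarray:
    """Labels of the best-inertia k-means partition over ``restarts``
    k-means++ initializations."""
    X = np.ascontiguousarray(X, dtype=float)
    n = X.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"k must lie in [2, n={n}], got {k}")
    seed = int(rng.integers(2**31))
    return _kmeans_best(X, k, restarts, max_iter, seed)
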