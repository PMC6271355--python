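"""Independent brute-force oracles used by the test suite.

These are deliberately naive re-implementations (explicit loops, O(n^3)
agglomeration, power iteration, normal equations) kept separate from the
package code paths they verify.
"""

from __future__ import annotations

import numpy as np


def ols_standardized(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Ordinary least squares on autoscaled data via the normal equations."""
    xs = (x - x.mean(0)) / x.std(0, ddof=1)
    ys = (y - y.mean()) / y.std(ddof=1)
    return np.linalg.solve(xs.T @ xs, xs.T @ ys)


def power_iteration_eigh(a: np.ndarray, n_iter: int = 20000) -> tuple[np.ndarray, np.ndarray]:
    """Dominant-eigenpair extraction with deflation on a symmetric matrix."""
    m = a.shape[0]
    residual = a.copy().astype(float)
    values = np.empty(m)
    vectors = np.empty((m, m))
    for k in range(m):
        v = np.ones(m) / np.sqrt(m)
        for _ in range(n_iter):
            v_new = residual @ v
            norm = np.linalg.norm(v_new)
            if norm == 0.0:
                break
            v_new /= norm
            if np.linalg.norm(v_new - v) < 1e-14 or np.linalg.norm(v_new + v) < 1e-14:
                v = v_new
                break
            v = v_new
        lam = v @ residual @ v
        values[k] = lam
        vectors[:, k] = v
        residual = residual - lam * np.outer(v, v)
    return values, vectors


_LANCE_WILLIAMS = {
    # method -> coefficients as functions of cluster sizes (na, nb, nc)
    "single": lambda na, nb, nc: (0.5, 0.5, 0.0, -0.5),
    "complete": lambda na, nb, nc: (0.5, 0.5, 0.0, 0.5),
    "average": lambda na, nb, nc: (na / (na + nb), nb / (na + nb), 0.0, 0.0),
}


def naive_agglomerate(d: np.ndarray, method: str) -> list[tuple[int, int, float, int]]:
    """O(n^3) agglomeration returning SciPy-style merge rows.

    Ward ("incremental") applies the Lance-Williams recurrence on squared
    distances and reports the square root, matching the distance-scale
    convention; the others update plain distances.  Ties break on the
    smallest merge criterion then lowest cluster indices.
    """
    n = d.shape[0]
    squared = method == "incremental"
    dist = {
        (i, j): (d[i, j] ** 2 if squared else d[i, j])
        for i in range(n)
        for j in range(i + 1, n)
    }
    sizes = {i: 1 for i in range(n)}
    active = list(range(n))
    merges = []
    for step in range(n - 1):
        best = min(
            ((dist[(min(a, b), max(a, b))], a, b) for i, a in enumerate(active)
             for b in active[i + 1:]),
            key=lambda t: (t[0], t[1], t[2]),
        )
        crit, a, b = best
        new = n + step
        na, nb = sizes[a], sizes[b]
        for c in active:
            if c in (a, b):
                continue
            nc = sizes[c]
            dac = dist[(min(a, c), max(a, c))]
            dbc = dist[(min(b, c), max(b, c))]
            if method == "incremental":
                dnew = (
                    (na + nc) * dac + (nb + nc) * dbc - nc * crit
                ) / (na + nb + nc)
            else:
                ca, cb, cg, cd = _LANCE_WILLIAMS[method](na, nb, nc)
                dnew = ca * dac + cb * dbc + cg * crit + cd * abs(dac - dbc)
            dist[(c, new)] = dnew
        active = [c for c in active if c not in (a, b)] + [new]
        sizes[new] = na + nb
        height = np.sqrt(crit) if squared else crit
        merges.append((a, b, float(height), na + nb))
    return merges


def partition_from_merges(
    merges: list[tuple[int, int, float, int]], n: int, k: int
) -> list[frozenset[int]]:
    """Leaf partition after undoing the last k-1 merges."""
    clusters: dict[int, set[int]] = {i: {i} for i in range(n)}
    for step, (a, b, _, _) in enumerate(merges[: n - k]):
        clusters[n + step] = clusters.pop(a) | clusters.pop(b)
    return sorted((frozenset(c) for c in clusters.values()), key=min)


def within_cluster_ess(points: np.ndarray, members: set[int]) -> float:
    """Explicit within-cluster error sum of squares about the centroid."""
    sub = points[sorted(members)]
    centroid = sub.mean(axis=0)
    return float(np.sum((sub - centroid) ** 2))
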