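"""Independent reference implementations used only to check the package.

Everything here is deliberately naive — explicit loops, textbook formulas —
and shares no code path with the implementations it validates.
"""

from __future__ import annotations

import numpy as np


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float) - np.mean(a)
    b = np.asarray(b, float) - np.mean(b)
    return float(np.sum(a * b) / np.sqrt(np.sum(a * a) * np.sum(b * b)))


def shift_and_correlate(x: np.ndarray, ref: np.ndarray, lag: int) -> float:
    """Explicit truncated-overlap lagged correlation (loop-free but literal)."""
    t = len(x)
    if lag > 0:
        return pearson(x[lag:], ref[: t - lag])
    if lag < 0:
        return pearson(x[: t + lag], ref[-lag:])
    return pearson(x, ref)


def icc_pairwise(series: np.ndarray) -> np.ndarray:
    """O(V^2) mean-of-squared-correlations, explicit pair loop on (T, V)."""
    t, v = series.shape
    c = series - series.mean(axis=0)
    norms = np.sqrt((c * c).sum(axis=0))
    out = np.zeros(v)
    for i in range(v):
        acc = 0.0
        for j in range(v):
            if j == i:
                continue
            r = float(c[:, i] @ c[:, j] / (norms[i] * norms[j]))
            acc += r * r
        out[i] = acc / (v - 1)
    return out


def partial_corr_precision(x, y, z) -> float:
    """Partial correlation via the inverse-correlation-matrix identity."""
    z = np.atleast_2d(np.asarray(z, float))
    if z.shape[0] != len(x):
        z = z.T
    m = np.column_stack([x, y, z])
    p = np.linalg.inv(np.corrcoef(m.T))
    return float(-p[0, 1] / np.sqrt(p[0, 0] * p[1, 1]))


def hat_matrix_residuals(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """(I - H) y with H the explicit hat matrix of [1 | x]."""
    x = np.atleast_2d(np.asarray(x, float))
    if x.shape[0] != len(y):
        x = x.T
    design = np.column_stack([np.ones(len(y)), x])
    h = design @ np.linalg.inv(design.T @ design) @ design.T
    return np.asarray(y, float) - h @ np.asarray(y, float)


# ---------------------------------------------------------------------------
# Graph metrics by exhaustive shortest-path computation
# ---------------------------------------------------------------------------

def _floyd_warshall_counts(dist_matrix: np.ndarray, tol: float = 1e-12):
    """All-pairs shortest distances and shortest-path counts.

    ``dist_matrix``: edge lengths, np.inf for absent edges, 0 diagonal.
    """
    n = dist_matrix.shape[0]
    d = dist_matrix.copy().astype(float)
    sigma = np.where(np.isfinite(dist_matrix) & (dist_matrix > 0), 1.0, 0.0)
    np.fill_diagonal(sigma, 1.0)
    for k in range(n):
        for i in range(n):
            if i == k:
                continue
            for j in range(n):
                if j == k or j == i:
                    continue
                via = d[i, k] + d[k, j]
                if via < d[i, j] - tol:
                    d[i, j] = via
                    sigma[i, j] = sigma[i, k] * sigma[k, j]
                elif np.isfinite(via) and np.isfinite(d[i, j]) \
                        and abs(via - d[i, j]) <= tol:
                    sigma[i, j] += sigma[i, k] * sigma[k, j]
    return d, sigma


def betweenness_exhaustive(dist_matrix: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Normalized betweenness by direct evaluation of the pair-dependency sum."""
    n = dist_matrix.shape[0]
    d, sigma = _floyd_warshall_counts(dist_matrix, tol)
    bc = np.zeros(n)
    for v in range(n):
        for s in range(n):
            for t in range(n):
                if len({s, t, v}) < 3 or not np.isfinite(d[s, t]) or sigma[s, t] == 0:
                    continue
                if abs(d[s, v] + d[v, t] - d[s, t]) <= tol:
                    bc[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    bc /= 2.0  # each unordered pair counted twice
    norm = (n - 1) * (n - 2) / 2.0
    return bc / norm if norm > 0 else bc


def local_efficiency_exhaustive(adj: np.ndarray, weights: np.ndarray | None = None
                                ) -> np.ndarray:
    """Binary (or weighted, d=1/w) local efficiency via pairwise distances."""
    n = adj.shape[0]
    out = np.zeros(n)
    for v in range(n):
        nbrs = np.flatnonzero(adj[v])
        if len(nbrs) < 2:
            continue
        if weights is None:
            sub = np.where(adj[np.ix_(nbrs, nbrs)] > 0, 1.0, np.inf)
        else:
            w = weights[np.ix_(nbrs, nbrs)]
            sub = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
        np.fill_diagonal(sub, 0.0)
        d, _ = _floyd_warshall_counts(sub)
        acc = 0.0
        k = len(nbrs)
        for a in range(k):
            for b in range(k):
                if a != b and np.isfinite(d[a, b]) and d[a, b] > 0:
                    acc += 1.0 / d[a, b]
        out[v] = acc / (k * (k - 1))
    return out


def flood_fill_clusters(mask: np.ndarray, connectivity: int) -> list[set]:
    """Connected components by explicit flood fill; returns voxel-index sets."""
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dx, dy, dz))
    seen = np.zeros(mask.shape, bool)
    comps = []
    for idx in np.argwhere(mask):
        idx = tuple(idx)
        if seen[idx]:
            continue
        comp = set()
        stack = [idx]
        seen[idx] = True
        while stack:
            cur = stack.pop()
            comp.add(cur)
            for off in offsets:
                nb = tuple(np.add(cur, off))
                if any(c < 0 or c >= s for c, s in zip(nb, mask.shape)):
                    continue
                if mask[nb] and not seen[nb]:
                    seen[nb] = True
                    stack.append(nb)
        comps.append(comp)
    return comps
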