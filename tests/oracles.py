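"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library code paths they check.
"""

from __future__ import annotations

import numpy as np


def dbscan_bruteforce(points: np.ndarray, eps: float, minpts: int) -> np.ndarray:
    """Textbook DBSCAN via all-pairs distances and breadth-first expansion.

    ``minpts`` counts the point itself. Returns labels with -1 for noise.
    """
    n = len(points)
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    neighbours = [np.nonzero(d[i] <= eps)[0] for i in range(n)]
    core = np.array([len(nb) >= minpts for nb in neighbours])
    labels = np.full(n, -2)  # -2 = unvisited
    cluster = -1
    for i in range(n):
        if labels[i] != -2:
            continue
        if not core[i]:
            labels[i] = -1
            continue
        cluster += 1
        labels[i] = cluster
        queue = list(neighbours[i])
        while queue:
            j = queue.pop(0)
            if labels[j] == -1:
                labels[j] = cluster  # border point
            if labels[j] != -2:
                continue
            labels[j] = cluster
            if core[j]:
                queue.extend(neighbours[j])
    labels[labels == -2] = -1
    return labels


def ks_statistic_bruteforce(a: np.ndarray, b: np.ndarray) -> float:
    """sup |ECDF_a - ECDF_b| evaluated exhaustively at every observed point."""
    pts = np.concatenate([a, b])
    best = 0.0
    for x in pts:
        fa = np.mean(a <= x)
        fb = np.mean(b <= x)
        best = max(best, abs(fa - fb))
    return float(best)


def weighted_origin_fit(tau: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Slope of a weighted zero-intercept fit by explicit normal equations."""
    return float(np.sum(w * tau * y) / np.sum(w * tau * tau))


def rank_sum_z(a: np.ndarray, b: np.ndarray) -> float:
    """Normal-approximation two-sample rank-sum z statistic (no ties)."""
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    order = np.argsort(pooled)
    ranks = np.empty(len(pooled))
    ranks[order] = np.arange(1, len(pooled) + 1)
    r1 = ranks[:n1].sum()
    mu = n1 * (n1 + n2 + 1) / 2.0
    sigma = np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
    return float((r1 - mu) / sigma)


def noisy_trimer_median(
    side_mean: float,
    side_sd: float,
    sigma_vertex: float,
    n_mc: int = 200_000,
    seed: int = 12345,
) -> float:
    """Monte-Carlo median of the mean pairwise distance of noisy triangles.

    Each triangle is equilateral with side ~ N(side_mean, side_sd) and each
    vertex is displaced by isotropic 3D Gaussian noise of s.d.
    ``sigma_vertex`` per axis (the positional error of an estimated
    fluorophore centre). Computed directly from ||(a + e1) - (b + e2)||.
    """
    rng = np.random.default_rng(seed)
    sides = rng.normal(side_mean, side_sd, n_mc)
    r = sides / np.sqrt(3.0)
    ang = np.array([np.pi / 2, np.pi / 2 + 2 * np.pi / 3, np.pi / 2 + 4 * np.pi / 3])
    verts = np.stack(
        [r[:, None] * np.cos(ang), r[:, None] * np.sin(ang), np.zeros((n_mc, 3))], axis=-1
    )  # (n_mc, 3, 3)
    verts = verts + rng.normal(0.0, sigma_vertex, verts.shape)
    d12 = np.linalg.norm(verts[:, 0] - verts[:, 1], axis=1)
    d13 = np.linalg.norm(verts[:, 0] - verts[:, 2], axis=1)
    d23 = np.linalg.norm(verts[:, 1] - verts[:, 2], axis=1)
    return float(np.median((d12 + d13 + d23) / 3.0))
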