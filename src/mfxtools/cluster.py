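"""Assignment of one 3D position per labelled protomer.

Localizations are clustered in 3D by a two-step DBSCAN — the first pass
removes noise, the second re-clusters the surviving points at a tighter
radius — and each second-pass cluster is refined by a spherical
Gaussian-mixture EM fit. The component means are the fluorophore
positions; the positional error of each is the s.d. of its member
localizations, and poorly localized positions are dropped by an error
threshold.

The ``minpts`` convention counts the point itself (a point is core if
its eps-neighbourhood, including itself, holds at least ``minpts``
points), matching scikit-learn's ``min_samples``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

logger = logging.getLogger(__name__)

_VAR_FLOOR_NM2 = 1.0  # spherical variance floor to avoid component collapse


@dataclass
class ClusterParams:
    eps1: float = 10.0           # nm, noise-removal pass
    minpts1: int = 5
    eps2: float = 7.0            # nm, re-clustering pass
    minpts2: int = 5
    gmm_init_sigma: float = 5.0  # nm
    max_position_error: float = 10.0  # nm
    em_tol: float = 1e-6         # relative log-likelihood change
    em_max_iter: int = 500

    def __post_init__(self) -> None:
        if not self.eps1 >= self.eps2 > 0:
            raise ValueError("need eps1 >= eps2 > 0")
        if self.minpts1 < 1 or self.minpts2 < 1:
            raise ValueError("minpts must be >= 1")
        if self.gmm_init_sigma <= 0:
            raise ValueError("gmm_init_sigma must be > 0")


@dataclass
class FluorophorePosition:
    """A GMM-assigned 3D protomer position."""

    position: np.ndarray   # (3,) nm
    error: float           # nm, rms per-axis s.d. of member localizations
    n_locs: int
    cluster_id: int
    converged: bool = True


def cluster_localizations(table: pd.DataFrame, params: ClusterParams) -> pd.DataFrame:
    """Two-step DBSCAN in 3D.

    Step 1 (``eps1``, ``minpts1``) labels noise, which is discarded;
    step 2 (``eps2``, ``minpts2``) re-clusters the survivors. Returns
    the surviving localizations with a ``cluster`` column holding the
    step-2 cluster id (-1 for points that are noise at step 2 only).

    Input order is made deterministic by a stable sort on
    ``(trace_id, t)`` before clustering.
    """
    if len(table) == 0:
        out = table.copy()
        out["cluster"] = pd.Series(dtype=np.int64)
        return out
    table = table.sort_values(["trace_id", "t"], kind="stable").reset_index(drop=True)
    xyz = table[["x", "y", "z"]].to_numpy(dtype=float)

    labels1 = DBSCAN(eps=params.eps1, min_samples=params.minpts1).fit_predict(xyz)
    keep = labels1 >= 0
    out = table[keep].reset_index(drop=True)
    if len(out) == 0:
        out["cluster"] = pd.Series(dtype=np.int64)
        return out
    labels2 = DBSCAN(eps=params.eps2, min_samples=params.minpts2).fit_predict(
        out[["x", "y", "z"]].to_numpy(dtype=float)
    )
    out["cluster"] = labels2.astype(np.int64)
    out.attrs = dict(table.attrs)
    return out


def _connected_components(centroids: np.ndarray, link_dist: float) -> list[np.ndarray]:
    """Single-linkage components of cluster centroids within ``link_dist``."""
    n = len(centroids)
    d = np.linalg.norm(centroids[:, None, :] - centroids[None, :, :], axis=-1)
    adj = d <= link_dist
    seen = np.zeros(n, dtype=bool)
    comps = []
    for i in range(n):
        if seen[i]:
            continue
        stack, comp = [i], []
        seen[i] = True
        while stack:
            j = stack.pop()
            comp.append(j)
            for k in np.nonzero(adj[j] & ~seen)[0]:
                seen[k] = True
                stack.append(k)
        comps.append(np.array(sorted(comp)))
    return comps


def _em_spherical(
    x: np.ndarray,
    means0: np.ndarray,
    sigma0: float,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool, list[float]]:
    """Fixed-K spherical-covariance Gaussian-mixture EM in 3D.

    Returns (means, variances, responsibilities, converged, log-likelihoods).
    The per-iteration log-likelihood trace lets callers assert EM
    monotonicity in debug mode.
    """
    n, d = x.shape
    k = len(means0)
    means = means0.astype(float).copy()
    var = np.full(k, max(sigma0**2, _VAR_FLOOR_NM2))
    weights = np.full(k, 1.0 / k)
    ll_trace: list[float] = []
    converged = False
    resp = np.full((n, k), 1.0 / k)
    prev_ll = -np.inf
    for _ in range(max_iter):
        # E step
        d2 = ((x[:, None, :] - means[None, :, :]) ** 2).sum(axis=-1)
        log_prob = (
            np.log(weights)[None, :]
            - 0.5 * d * np.log(2.0 * np.pi * var)[None, :]
            - 0.5 * d2 / var[None, :]
        )
        m = log_prob.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(log_prob - m).sum(axis=1))
        ll = float(lse.sum())
        ll_trace.append(ll)
        resp = np.exp(log_prob - lse[:, None])
        if np.isfinite(prev_ll) and abs(ll - prev_ll) <= tol * abs(prev_ll):
            converged = True
            break
        prev_ll = ll
        # M step
        nk = resp.sum(axis=0) + 1e-300
        weights = nk / n
        means = (resp.T @ x) / nk[:, None]
        d2 = ((x[:, None, :] - means[None, :, :]) ** 2).sum(axis=-1)
        var = np.maximum((resp * d2).sum(axis=0) / (d * nk), _VAR_FLOOR_NM2)
    return means, var, resp, converged, ll_trace


def fit_positions(
    labelled: pd.DataFrame,
    params: ClusterParams,
    collect_ll: list | None = None,
) -> tuple[list[FluorophorePosition], dict]:
    """Refine step-2 clusters into fluorophore positions by spherical EM.

    EM runs jointly over the points of each spatially connected
    neighbourhood (cluster centroids linked within ``2 * eps1``) with
    one component per cluster, means initialized at cluster centroids
    and s.d. at ``gmm_init_sigma``. Each position's error is the rms
    per-axis s.d. of the localizations assigned to it; positions with
    error above ``max_position_error`` are dropped and logged.

    If EM does not converge within ``em_max_iter`` the centroid-based
    positions are returned with ``converged=False``.
    """
    log: dict = {"n_clusters_in": 0, "n_dropped_error": 0, "n_not_converged": 0}
    clustered = labelled[labelled["cluster"] >= 0]
    if len(clustered) == 0:
        return [], log
    ids = np.sort(clustered["cluster"].unique())
    log["n_clusters_in"] = int(len(ids))
    xyz_all = clustered[["x", "y", "z"]].to_numpy(dtype=float)
    labels = clustered["cluster"].to_numpy()
    centroids = np.vstack([xyz_all[labels == cid].mean(axis=0) for cid in ids])

    positions: list[FluorophorePosition] = []
    for comp in _connected_components(centroids, 2.0 * params.eps1):
        comp_ids = ids[comp]
        mask = np.isin(labels, comp_ids)
        x = xyz_all[mask]
        means, _, resp, converged, ll_trace = _em_spherical(
            x, centroids[comp], params.gmm_init_sigma, params.em_tol, params.em_max_iter
        )
        if collect_ll is not None:
            collect_ll.append(ll_trace)
        assign = np.argmax(resp, axis=1)
        if not converged:
            log["n_not_converged"] += len(comp_ids)
            means = centroids[comp]
        for j, cid in enumerate(comp_ids):
            members = x[assign == j]
            if len(members) == 0:
                log["n_dropped_error"] += 1
                continue
            sds = members.std(axis=0, ddof=0)
            err = float(np.sqrt((sds**2).mean()))
            pos = FluorophorePosition(
                position=means[j],
                error=err,
                n_locs=int(len(members)),
                cluster_id=int(cid),
                converged=converged,
            )
            if err > params.max_position_error:
                log["n_dropped_error"] += 1
                logger.info(
                    "dropping cluster %d: position error %.2f nm > %.2f nm",
                    cid, err, params.max_position_error,
                )
                continue
            positions.append(pos)
    log["n_positions_out"] = len(positions)
    return positions, log


def positions_to_frame(positions: list[FluorophorePosition]) -> pd.DataFrame:
    """Tabulate fluorophore positions (``cluster_id, x, y, z, error, n_locs``)."""
    return pd.DataFrame(
        {
            "cluster_id": [p.cluster_id for p in positions],
            "x": [p.position[0] for p in positions],
            "y": [p.position[1] for p in positions],
            "z": [p.position[2] for p in positions],
            "error": [p.error for p in positions],
            "n_locs": [p.n_locs for p in positions],
        }
    )
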