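"""Trimer identification and 3D inter-position distances.

Fluorophore positions are grouped by DBSCAN at the isolation radius;
only clusters of exactly three positions whose pairwise 3D distances all
fall in the nearest-neighbour window survive. The per-molecule statistic
is the mean of the three pairwise distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

from mfxtools import stats as _stats


@dataclass
class TrimerParams:
    isolation_eps: float = 60.0   # nm
    isolation_minpts: int = 3
    nn_lo: float = 6.0            # nm, open interval
    nn_hi: float = 60.0           # nm, open interval
    required_neighbours: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.nn_lo < self.nn_hi:
            raise ValueError("need 0 < nn_lo < nn_hi")
        if self.isolation_eps < self.nn_hi:
            raise ValueError("isolation_eps must be >= nn_hi")


@dataclass
class TrimerMeasurement:
    molecule_id: int
    vertices: np.ndarray  # (3, 3) nm
    d12: float
    d13: float
    d23: float

    @property
    def d_mean(self) -> float:
        return (self.d12 + self.d13 + self.d23) / 3.0


def identify_trimers(
    positions: pd.DataFrame, params: TrimerParams
) -> tuple[list[TrimerMeasurement], dict]:
    """Select isolated triplets of positions and measure their geometry.

    ``positions`` needs columns ``x, y, z`` (one row per fluorophore
    position, already error-filtered). Returns the accepted
    measurements and a rejection log keyed by reason.
    """
    log = {"n_positions": int(len(positions)), "size_not_3": 0, "window_fail": 0, "accepted": 0}
    if len(positions) == 0:
        return [], log
    xyz = positions[["x", "y", "z"]].to_numpy(dtype=float)
    labels = DBSCAN(eps=params.isolation_eps, min_samples=params.isolation_minpts).fit_predict(xyz)

    out: list[TrimerMeasurement] = []
    mol_id = 0
    for cid in np.unique(labels[labels >= 0]):
        members = xyz[labels == cid]
        if len(members) != 3:
            log["size_not_3"] += 1
            continue
        d12 = float(np.linalg.norm(members[0] - members[1]))
        d13 = float(np.linalg.norm(members[0] - members[2]))
        d23 = float(np.linalg.norm(members[1] - members[2]))
        dists = (d12, d13, d23)
        # every point must have exactly `required_neighbours` co-members
        # inside the open window (nn_lo, nn_hi)
        per_point = [
            sum(params.nn_lo < d < params.nn_hi for d in (d12, d13)),
            sum(params.nn_lo < d < params.nn_hi for d in (d12, d23)),
            sum(params.nn_lo < d < params.nn_hi for d in (d13, d23)),
        ]
        if any(c != params.required_neighbours for c in per_point):
            log["window_fail"] += 1
            continue
        out.append(TrimerMeasurement(mol_id, members.copy(), *dists))
        mol_id += 1
    log["accepted"] = len(out)
    return out, log


def trimers_to_frame(trimers: list[TrimerMeasurement]) -> pd.DataFrame:
    """Distance table with columns ``molecule_id, d12, d13, d23, d_mean``."""
    return pd.DataFrame(
        {
            "molecule_id": [t.molecule_id for t in trimers],
            "d12": [t.d12 for t in trimers],
            "d13": [t.d13 for t in trimers],
            "d23": [t.d23 for t in trimers],
            "d_mean": [t.d_mean for t in trimers],
        }
    )


def interblade_distances(
    trimers: list[TrimerMeasurement],
    n_boot: int = 10_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Per-molecule mean distances plus summary statistics.

    The summary holds median with 95% bootstrap CI, mean, s.d.,
    variance and n. With no trimers an empty summary is returned with
    ``summary["empty"]`` set.
    """
    frame = trimers_to_frame(trimers)
    if len(frame) == 0:
        return frame, {"empty": True, "n": 0}
    d = frame["d_mean"].to_numpy()
    summary = {
        "empty": False,
        "n": int(len(d)),
        "median": float(np.median(d)),
        "mean": float(np.mean(d)),
        "sd": float(np.std(d, ddof=1)) if len(d) > 1 else 0.0,
        "variance": float(np.var(d, ddof=1)) if len(d) > 1 else 0.0,
    }
    if len(d) >= 3:
        ci = _stats.bootstrap_median_ci(d, n_boot=n_boot, seed=seed)
        summary["median_ci95"] = [ci.ci_lo, ci.ci_hi]
    return frame, summary
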