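"""Single-molecule trajectories and MSD-based diffusion estimation.

Trajectories are traces that survive gap truncation and quality
filters. The mean squared displacement uses all ordered localization
pairs, binned by actual time difference (MINFLUX timestamps are
irregular), and diffusion coefficients come from weighted least-squares
fits of the zero-intercept law MSD(tau) = 6 * D * tau over a stated lag
window, with displacement-pair counts as weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

NM2_PER_MS_TO_UM2_PER_S = 1e-3  # (nm^2/ms) -> (um^2/s)


@dataclass
class TrackFilterParams:
    efo_max: float = 130_000.0     # Hz, on the per-trajectory mean
    max_gap: float = 18.0          # ms
    min_locs: int = 200            # strict: n_locs must exceed this
    micro_window: tuple[float, float] = (5.0, 50.0)    # ms
    macro_window: tuple[float, float] = (50.0, 350.0)  # ms
    ensemble_bins: int = 50
    ensemble_tmax: float = 350.0   # ms
    lag_bin_width: float = 7.0     # ms (= ensemble_tmax / ensemble_bins)
    keep_post_gap: bool = False    # sensitivity switch: re-use the post-gap remainder

    def __post_init__(self) -> None:
        if self.ensemble_bins < 2:
            raise ValueError("ensemble_bins must be >= 2")
        lo1, hi1 = self.micro_window
        lo2, hi2 = self.macro_window
        if not (lo1 < hi1 <= lo2 < hi2):
            raise ValueError("windows must be ordered and non-overlapping except at the joint")


@dataclass
class Trajectory:
    track_id: int
    t: np.ndarray          # s, strictly increasing
    xyz: np.ndarray        # (n, 3) nm
    mean_efo: float
    source_trace: int
    truncated_at: int | None = None  # index of the first over-gap step, if any

    @property
    def n_locs(self) -> int:
        return len(self.t)


@dataclass
class MSDCurve:
    lag_centers: np.ndarray   # ms, geometric bin centres
    lag_means: np.ndarray     # ms, pair-weighted mean lag per bin (fit abscissa)
    msd: np.ndarray           # nm^2
    weights: np.ndarray       # displacement-pair count per bin
    sem: np.ndarray | None = None  # nm^2, ensemble curves only

    @property
    def n_pairs_total(self) -> int:
        return int(self.weights.sum())

    @property
    def empty(self) -> bool:
        return len(self.msd) == 0


@dataclass
class DiffusionFit:
    d: float                  # um^2 s^-1
    window: tuple[float, float]
    n_lags: int
    residual_rms: float
    refused: bool = False
    reason: str = ""


def build_trajectories(
    table: pd.DataFrame, params: TrackFilterParams
) -> tuple[list[Trajectory], dict]:
    """Group localizations into quality-filtered, gap-truncated trajectories.

    Per trace: sort by time, truncate at the first time gap exceeding
    ``max_gap`` (the remainder is discarded unless ``keep_post_gap``),
    then drop trajectories whose mean EFO exceeds ``efo_max`` or with
    ``n_locs <= min_locs``.
    """
    log = {"traces_in": 0, "removed_efo": 0, "removed_short": 0, "accepted": 0}
    out: list[Trajectory] = []
    next_id = 0
    for trace_id, g in table.groupby("trace_id", sort=True):
        log["traces_in"] += 1
        g = g.sort_values("t", kind="stable")
        t = g["t"].to_numpy(dtype=float)
        xyz = g[["x", "y", "z"]].to_numpy(dtype=float)
        efo = g["efo"].to_numpy(dtype=float)

        gaps = np.nonzero(np.diff(t) * 1e3 > params.max_gap)[0]
        if params.keep_post_gap:
            bounds = [0, *list(gaps + 1), len(t)]
            segments = [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]
        else:
            end = gaps[0] + 1 if len(gaps) else len(t)
            segments = [(0, end)]

        for k, (a, b) in enumerate(segments):
            if b - a < 2:
                continue
            mean_efo = float(efo[a:b].mean())
            if mean_efo > params.efo_max:
                log["removed_efo"] += 1
                continue
            if b - a <= params.min_locs:
                log["removed_short"] += 1
                continue
            out.append(
                Trajectory(
                    track_id=next_id,
                    t=t[a:b],
                    xyz=xyz[a:b],
                    mean_efo=mean_efo,
                    source_trace=int(trace_id),
                    truncated_at=int(gaps[0]) if (len(gaps) and k == 0 and b < len(t)) else None,
                )
            )
            next_id += 1
    log["accepted"] = len(out)
    return out, log


def _bin_edges(params: TrackFilterParams) -> np.ndarray:
    n_bins = int(np.ceil(params.ensemble_tmax / params.lag_bin_width))
    return params.lag_bin_width * np.arange(n_bins + 1)


def _pair_sums(traj: Trajectory, params: TrackFilterParams):
    """Accumulate squared 3D displacements of all ordered pairs into lag bins.

    Returns per-bin (pair count, sum of squared displacements, sum of lags).
    """
    edges = _bin_edges(params)
    n_bins = len(edges) - 1
    counts = np.zeros(n_bins, dtype=np.int64)
    sq_sums = np.zeros(n_bins)
    lag_sums = np.zeros(n_bins)
    t_ms = traj.t * 1e3
    xyz = traj.xyz
    n = len(t_ms)
    for k in range(1, n):
        lags = t_ms[k:] - t_ms[:-k]
        if lags.min() > params.ensemble_tmax:
            break
        ok = lags <= params.ensemble_tmax
        if not ok.any():
            continue
        disp2 = ((xyz[k:] - xyz[:-k]) ** 2).sum(axis=1)[ok]
        lags = lags[ok]
        which = np.minimum((lags / params.lag_bin_width).astype(np.int64), n_bins - 1)
        counts += np.bincount(which, minlength=n_bins)
        sq_sums += np.bincount(which, weights=disp2, minlength=n_bins)
        lag_sums += np.bincount(which, weights=lags, minlength=n_bins)
    return counts, sq_sums, lag_sums


def compute_msd(traj: Trajectory, params: TrackFilterParams) -> MSDCurve:
    """Lag-binned MSD of one trajectory with pair-count weights.

    Bins with no pairs are omitted; an entirely empty curve is
    signalled by :attr:`MSDCurve.empty`.
    """
    if traj.n_locs < 2:
        return MSDCurve(np.array([]), np.array([]), np.array([]), np.array([], dtype=np.int64))
    counts, sq_sums, lag_sums = _pair_sums(traj, params)
    edges = _bin_edges(params)
    centers = 0.5 * (edges[:-1] + edges[1:])
    pop = counts > 0
    return MSDCurve(
        lag_centers=centers[pop],
        lag_means=lag_sums[pop] / counts[pop],
        msd=sq_sums[pop] / counts[pop],
        weights=counts[pop],
    )


def fit_diffusion(curve: MSDCurve, window: tuple[float, float]) -> DiffusionFit:
    """Weighted zero-intercept fit MSD(tau) = 6 D tau over bins in ``window``.

    Weights are displacement-pair counts and the abscissa is the
    pair-weighted mean lag of each bin. Refuses to fit with fewer than
    two populated bins inside the window.
    """
    lo, hi = window
    sel = (curve.lag_means >= lo) & (curve.lag_means <= hi) if not curve.empty else np.array([], bool)
    if sel.sum() < 2:
        return DiffusionFit(np.nan, window, int(sel.sum()), np.nan, refused=True,
                            reason="fewer than 2 populated lag bins in window")
    tau = curve.lag_means[sel]          # ms
    msd = curve.msd[sel]                # nm^2
    w = curve.weights[sel].astype(float)
    slope = float((w * tau * msd).sum() / (w * tau * tau).sum())  # nm^2/ms
    resid = msd - slope * tau
    rms = float(np.sqrt((w * resid**2).sum() / w.sum()))
    d = slope / 6.0 * NM2_PER_MS_TO_UM2_PER_S
    return DiffusionFit(d, window, int(sel.sum()), rms)


def ensemble_msd(
    trajectories: list[Trajectory], params: TrackFilterParams
) -> tuple[MSDCurve, DiffusionFit, DiffusionFit]:
    """Pool trajectories into the ensemble MSD curve and fit both windows.

    Per-trajectory per-bin MSD values are combined as a pair-count-
    weighted mean, with a weighted s.e.m. per bin; the pooled curve is
    then fit over the micro and macro lag windows.
    """
    if not trajectories:
        raise ValueError("need at least one trajectory")
    edges = _bin_edges(params)
    n_bins = len(edges) - 1
    w_sum = np.zeros(n_bins)
    wm_sum = np.zeros(n_bins)
    lag_sum = np.zeros(n_bins)
    per_bin_vals: list[list[tuple[float, float]]] = [[] for _ in range(n_bins)]
    for traj in trajectories:
        counts, sq_sums, lag_sums = _pair_sums(traj, params)
        pop = counts > 0
        w_sum[pop] += counts[pop]
        wm_sum[pop] += sq_sums[pop]
        lag_sum[pop] += lag_sums[pop]
        for b in np.nonzero(pop)[0]:
            per_bin_vals[b].append((sq_sums[b] / counts[b], counts[b]))

    pop = w_sum > 0
    msd = wm_sum[pop] / w_sum[pop]
    lag_means = lag_sum[pop] / w_sum[pop]
    centers = 0.5 * (edges[:-1] + edges[1:])[pop]

    sem = np.zeros(pop.sum())
    for out_i, b in enumerate(np.nonzero(pop)[0]):
        vals = np.array([v for v, _ in per_bin_vals[b]])
        ws = np.array([c for _, c in per_bin_vals[b]], dtype=float)
        if len(vals) > 1:
            mean = (ws * vals).sum() / ws.sum()
            var = (ws * (vals - mean) ** 2).sum() / ws.sum()
            sem[out_i] = np.sqrt(var / (len(vals) - 1))
        else:
            sem[out_i] = np.nan

    curve = MSDCurve(centers, lag_means, msd, w_sum[pop].astype(np.int64), sem=sem)
    micro = fit_diffusion(curve, params.micro_window)
    macro = fit_diffusion(curve, params.macro_window)
    return curve, micro, macro


def per_trajectory_fits(
    trajectories: list[Trajectory], params: TrackFilterParams
) -> pd.DataFrame:
    """Table of per-trajectory micro and macro diffusion coefficients."""
    rows = []
    for traj in trajectories:
        curve = compute_msd(traj, params)
        micro = fit_diffusion(curve, params.micro_window)
        macro = fit_diffusion(curve, params.macro_window)
        rows.append(
            dict(
                track_id=traj.track_id,
                n_locs=traj.n_locs,
                d_micro=micro.d if not micro.refused else np.nan,
                d_macro=macro.d if not macro.refused else np.nan,
            )
        )
    return pd.DataFrame(rows, columns=["track_id", "n_locs", "d_micro", "d_macro"])


def center_of_mass_overlay(
    trajectories: list[Trajectory], duration_s: float = 1.0
) -> list[np.ndarray]:
    """Centre trajectories on their centre of mass, first ``duration_s`` only
    (visualization helper)."""
    out = []
    for traj in trajectories:
        sel = traj.t - traj.t[0] <= duration_s
        xyz = traj.xyz[sel]
        out.append(xyz - xyz.mean(axis=0))
    return out
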