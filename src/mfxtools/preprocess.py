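"""Localization-level corrections and trace-level quality filters.

The fixed filter order is: per-localization EFO cut, then trace size and
per-dimension spread filters, then a z window on the trace mean
position. Row counts removed at each stage are recorded in a filter
log so that downstream sample sizes are auditable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: flag set on a table once the axial correction has been applied
Z_CORRECTED_ATTR = "z_correction_applied"

EFO_CLAMP_LO = 120_000.0
EFO_CLAMP_HI = 150_000.0


@dataclass
class PreprocessParams:
    """Quality-filter parameters.

    Defaults sit at the stringent end of the documented 10-20 ranges
    (min 10 localizations per trace, per-dimension s.d. < 10 nm).
    ``z_window`` is either an explicit ``(lo, hi)`` in nm or ``"auto"``
    (mode of the z histogram +/- 100 nm).
    """

    z_correction: float = 0.7
    min_locs_per_trace: int = 10
    max_trace_sd: float = 10.0
    z_window: tuple[float, float] | str = "auto"
    efo_max: float = 130_000.0

    def __post_init__(self) -> None:
        if not 0.0 < self.z_correction <= 1.0:
            raise ValueError("z_correction must be in (0, 1]")
        if self.min_locs_per_trace < 1:
            raise ValueError("min_locs_per_trace must be >= 1")
        if self.max_trace_sd <= 0:
            raise ValueError("max_trace_sd must be > 0")
        if self.efo_max <= 0:
            raise ValueError("efo_max must be > 0")
        if self.z_window != "auto":
            lo, hi = self.z_window
            if not lo < hi:
                raise ValueError("z_window must satisfy lo < hi")


class ZCorrectionError(RuntimeError):
    """The axial correction was already applied to this table."""


def correct_z(table: pd.DataFrame, factor: float = 0.7) -> pd.DataFrame:
    """Scale z coordinates by ``factor`` (refractive-index mismatch correction).

    The correction must be applied exactly once; a table attribute
    guards against re-application.
    """
    if not 0.0 < factor <= 1.0:
        raise ValueError("factor must be in (0, 1]")
    if table.attrs.get(Z_CORRECTED_ATTR):
        raise ZCorrectionError(
            f"z correction already applied (attrs[{Z_CORRECTED_ATTR!r}] is set)"
        )
    out = table.copy()
    out["z"] = out["z"] * factor
    out.attrs = dict(table.attrs)
    out.attrs[Z_CORRECTED_ATTR] = factor
    return out


def summarize_traces(table: pd.DataFrame) -> pd.DataFrame:
    """Per-trace summary: size, per-dimension s.d., mean position, mean EFO."""
    g = table.groupby("trace_id", sort=True)
    out = pd.DataFrame(
        {
            "n_locs": g.size(),
            "sd_x": g["x"].std(ddof=0),
            "sd_y": g["y"].std(ddof=0),
            "sd_z": g["z"].std(ddof=0),
            "mean_x": g["x"].mean(),
            "mean_y": g["y"].mean(),
            "mean_z": g["z"].mean(),
            "mean_efo": g["efo"].mean(),
        }
    )
    return out.reset_index()


def auto_z_window(z: np.ndarray, half_width: float = 100.0, bin_width: float = 10.0) -> tuple[float, float]:
    """Mode of the z histogram +/- ``half_width`` nm."""
    z = np.asarray(z, dtype=float)
    if z.size == 0:
        return (-half_width, half_width)
    lo, hi = z.min(), z.max()
    if hi - lo < bin_width:
        mode = float(np.median(z))
    else:
        counts, edges = np.histogram(z, bins=np.arange(lo, hi + bin_width, bin_width))
        i = int(np.argmax(counts))
        mode = 0.5 * (edges[i] + edges[i + 1])
    return (mode - half_width, mode + half_width)


def filter_traces(
    table: pd.DataFrame, params: PreprocessParams
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Apply the quality filters in their fixed order.

    Returns the filtered table, the post-EFO-cut trace summaries and a
    log of row counts removed at each stage. An empty result is a valid
    outcome signalled by ``log["no_traces_survive"]``.
    """
    log: dict = {"rows_in": int(len(table))}

    # 1. per-localization EFO cut (before trace statistics)
    keep = table["efo"] <= params.efo_max
    log["efo_rows_removed"] = int((~keep).sum())
    table = table[keep]

    summaries = summarize_traces(table)

    # 2. trace size and per-dimension spread ("any dimension >= threshold fails")
    ok_size = summaries["n_locs"] >= params.min_locs_per_trace
    sds = summaries[["sd_x", "sd_y", "sd_z"]].to_numpy()
    ok_sd = (sds < params.max_trace_sd).all(axis=1)
    log["traces_removed_size"] = int((~ok_size).sum())
    log["traces_removed_sd"] = int((ok_size & ~ok_sd).sum())
    kept = summaries[ok_size & ok_sd]

    # 3. z window on the trace mean
    if params.z_window == "auto":
        window = auto_z_window(kept["mean_z"].to_numpy())
    else:
        window = tuple(params.z_window)
    log["z_window"] = [float(window[0]), float(window[1])]
    in_window = (kept["mean_z"] >= window[0]) & (kept["mean_z"] <= window[1])
    log["traces_removed_z"] = int((~in_window).sum())
    kept = kept[in_window]

    out = table[table["trace_id"].isin(set(kept["trace_id"]))].reset_index(drop=True)
    out.attrs = dict(table.attrs)
    log["rows_out"] = int(len(out))
    log["traces_out"] = int(len(kept))
    log["no_traces_survive"] = len(kept) == 0
    return out, summaries, log


def estimate_efo_threshold(
    table: pd.DataFrame,
    structural: bool = True,
    grid_points: int = 2048,
) -> float:
    """Estimate the multi-emitter EFO cutoff from the emission-frequency histogram.

    The single-emitter population forms the first (dominant low-frequency)
    mode and a two-emitter population appears at about twice that
    frequency; the cutoff is placed at the antimode between them on a
    kernel-smoothed density. In structural mode the result is clamped to
    the documented legal range [120, 150] kHz.
    """
    from scipy.stats import gaussian_kde

    efo = table["efo"].to_numpy(dtype=float)
    if efo.size < 100:
        raise ValueError("need at least 100 localizations to estimate an EFO threshold")
    midpoint = 0.5 * (EFO_CLAMP_LO + EFO_CLAMP_HI)
    if np.ptp(efo) == 0:
        warnings.warn("degenerate EFO distribution; returning clamp midpoint", stacklevel=2)
        return midpoint

    kde = gaussian_kde(efo)
    grid = np.linspace(efo.min(), efo.max(), grid_points)
    dens = kde(grid)

    # first mode: leftmost local maximum that carries appreciable density
    from scipy.signal import argrelextrema

    maxima = argrelextrema(dens, np.greater)[0]
    maxima = [i for i in maxima if dens[i] > 0.05 * dens.max()]
    if not maxima:
        maxima = [int(np.argmax(dens))]
    m1 = grid[maxima[0]]

    lo, hi = m1, 2.0 * m1
    band = (grid > lo) & (grid < hi)
    if not band.any() or len(maxima) < 2:
        warnings.warn("EFO histogram appears unimodal; returning clamp midpoint", stacklevel=2)
        return midpoint
    cutoff = float(grid[band][np.argmin(dens[band])])
    if structural:
        cutoff = float(np.clip(cutoff, EFO_CLAMP_LO, EFO_CLAMP_HI))
    return cutoff
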