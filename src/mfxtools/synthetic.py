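"""Synthetic localization data with the statistical structure the analysis assumes.

Three generators are provided:

* :func:`simulate_scene` — clusters of repeated localizations around the
  three vertices of labelled trimers in a flat membrane, with per-trace
  blinking statistics, a bimodal EFO distribution (single-emitter mode
  plus a two-emitter mode at twice the frequency), uniform background
  localizations and labelling dropout.
* :func:`simulate_tracks` — 3D Brownian trajectories at fixed diffusion
  coefficient with irregular sampling, dark gaps, static localization
  error and optional confinement.
* :func:`simulate_two_channel_image` — two-channel 2D images of Gaussian
  spots for the colocalization branch.

All generators are deterministic given their ``rng_seed``.

Notes
-----
Blinking kinetics are not modelled mechanistically (no on/off rates);
traces are drawn directly as localization bursts, which is sufficient to
exercise the clustering stages. Axial confinement of tracks is modelled
as independent Gaussian z around the membrane plane (an
Ornstein-Uhlenbeck process was rejected for simplicity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Sequence

import numpy as np
import pandas as pd

from mfxtools import io

UM_TO_NM = 1e3
#: default EFO mode of a single emitter, Hz
SINGLE_EMITTER_EFO_HZ = 75_000.0


def _check_nonneg(cfg, names: Sequence[str]) -> None:
    for n in names:
        v = getattr(cfg, n)
        if not np.isfinite(v) or v < 0:
            raise ValueError(f"{n} must be finite and >= 0, got {v}")


def _check_prob(cfg, names: Sequence[str]) -> None:
    for n in names:
        v = getattr(cfg, n)
        if not np.isfinite(v) or not 0.0 <= v <= 1.0:
            raise ValueError(f"{n} must be a probability in [0, 1], got {v}")


def _lognormal_mode(rng: np.random.Generator, mode: float, shape: float, size) -> np.ndarray:
    # lognormal(mu, s) has mode exp(mu - s^2); solve mu for the requested mode
    mu = math.log(mode) + shape**2
    return rng.lognormal(mu, shape, size)


@dataclass
class SceneConfig:
    """Parameters of a fixed-cell structural imaging scene."""

    n_trimers: int = 100
    side_mean: float = 20.0           # nm, triangle side
    side_sd: float = 1.5              # nm
    vertex_sigma_xy: float = 3.0      # nm, per-localization noise (placeholder default)
    vertex_sigma_z: float = 4.0       # nm (placeholder default)
    locs_per_vertex_mean: float = 30.0   # Poisson mean localizations per trace
    traces_per_vertex_mean: float = 5.0  # Poisson mean traces per labelled vertex
    # floors applied to the Poisson draws: over a long acquisition every intact
    # docking site is revisited, so a guaranteed minimum burst count/length is a
    # legitimate operating point; 0 keeps the draws purely Poisson
    min_traces_per_vertex: int = 0
    min_locs_per_trace: int = 0
    label_efficiency: float = 1.0
    background_density: float = 0.0   # localizations per um^2
    multi_emitter_fraction: float = 0.0
    efo_mode_hz: float = SINGLE_EMITTER_EFO_HZ
    efo_shape: float = 0.25           # lognormal shape parameter
    membrane_z: float = 0.0           # nm
    field_size: float = 5.0           # um, square field side
    min_separation: float = 150.0     # nm, between trimer centres
    random_rotation: bool = True      # uniform in-plane rotation of each trimer
    tilt_sd_deg: float = 0.0          # out-of-plane tilt (off by default: flat membrane)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        _check_nonneg(
            self,
            [
                "n_trimers", "side_mean", "side_sd", "vertex_sigma_xy",
                "vertex_sigma_z", "locs_per_vertex_mean", "traces_per_vertex_mean",
                "background_density", "efo_mode_hz", "efo_shape", "field_size",
                "min_separation", "tilt_sd_deg", "min_traces_per_vertex",
                "min_locs_per_trace",
            ],
        )
        _check_prob(self, ["label_efficiency", "multi_emitter_fraction"])
        if self.side_mean <= 0:
            raise ValueError("side_mean must be > 0")
        if not np.isfinite(self.membrane_z):
            raise ValueError("membrane_z must be finite")


@dataclass
class TrackConfig:
    """Parameters of a live-cell tracking simulation."""

    n_tracks: int = 100
    d_true: float = 0.01              # um^2 s^-1
    dt_ms: float = 2.0                # nominal sampling interval
    dt_jitter_ms: float = 0.0         # sd of sampling jitter
    n_locs: int = 500                 # localizations per track (before gaps)
    loc_sigma: float = 0.0            # nm, static isotropic localization error
    gap_prob: float = 0.0             # per-step probability of a dark gap
    gap_len_ms: float = 25.0
    z_confinement_sd: float = 0.0     # nm; 0 disables z confinement
    corral_radius_nm: float = 0.0     # xy corral (reflecting); 0 disables
    efo_mode_hz: float = SINGLE_EMITTER_EFO_HZ
    efo_shape: float = 0.25
    rng_seed: int = 0

    def __post_init__(self) -> None:
        _check_nonneg(
            self,
            [
                "n_tracks", "d_true", "dt_ms", "dt_jitter_ms", "loc_sigma",
                "gap_len_ms", "z_confinement_sd", "corral_radius_nm",
                "efo_mode_hz", "efo_shape",
            ],
        )
        _check_prob(self, ["gap_prob"])
        if self.dt_ms <= 0:
            raise ValueError("dt_ms must be > 0")
        if self.n_locs < 2:
            raise ValueError("n_locs must be >= 2")


@dataclass
class ImageConfig:
    """Parameters of a two-channel spot image (colocalization fixture)."""

    shape: tuple[int, int] = (256, 256)   # pixels
    pixel_nm: float = 20.0
    spots_ch1: list = field(default_factory=list)  # (x_px, y_px, amplitude, sigma_nm)
    spots_ch2: list = field(default_factory=list)
    coloc_fraction: float = 0.0
    noise_sd: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_nm <= 0:
            raise ValueError("pixel_nm must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        _check_prob(self, ["coloc_fraction"])
        ny, nx = self.shape
        for name in ("spots_ch1", "spots_ch2"):
            for x, y, amp, sigma_nm in getattr(self, name):
                if sigma_nm <= 0:
                    raise ValueError("sigma_nm must be > 0")
                if not (0 <= x < nx and 0 <= y < ny):
                    raise ValueError(f"spot ({x}, {y}) outside field {self.shape}")


def _triangle_vertices(side: float) -> np.ndarray:
    """Equilateral triangle of given side, centred at the origin, in the xy plane."""
    r = side / math.sqrt(3.0)
    ang = np.array([math.pi / 2, math.pi / 2 + 2 * math.pi / 3, math.pi / 2 + 4 * math.pi / 3])
    return np.column_stack([r * np.cos(ang), r * np.sin(ang), np.zeros(3)])


def _rotation_z(theta: float) -> np.ndarray:
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rotation_x(theta: float) -> np.ndarray:
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def simulate_scene(config: SceneConfig) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Simulate a structural imaging scene.

    Returns
    -------
    table
        Canonical localization table. An extra ``origin`` column links
        each localization to its ground-truth vertex (``trimer_id * 3 +
        vertex_index``) or to background (-1); the column is preserved
        by :func:`mfxtools.io.write_table` but is not part of the
        canonical schema.
    truth
        ``{"trimers": ..., "vertices": ...}`` ground-truth tables.
        ``vertices`` contains one row per trimer vertex with its true
        position and whether it carries a label.
    """
    rng = np.random.default_rng(config.rng_seed)
    field_nm = config.field_size * UM_TO_NM

    # trimer centres: uniform with rejection to enforce min_separation
    centres = np.empty((config.n_trimers, 2))
    n_placed = 0
    attempts = 0
    while n_placed < config.n_trimers:
        cand = rng.uniform(0.0, field_nm, size=2)
        if n_placed == 0 or (
            np.min(np.linalg.norm(centres[:n_placed] - cand, axis=1)) >= config.min_separation
        ):
            centres[n_placed] = cand
            n_placed += 1
        attempts += 1
        if attempts > 1000 * max(config.n_trimers, 1):
            raise RuntimeError(
                "could not place trimers with the requested min_separation; "
                "increase field_size or decrease n_trimers"
            )

    sides = rng.normal(config.side_mean, config.side_sd, config.n_trimers)
    sides = np.clip(sides, 1e-6, None)

    trimer_rows = []
    vertex_rows = []
    loc_chunks = []
    trace_id = 0
    t_cursor = 0.0
    loc_dt = 1e-3  # s between localizations of a trace

    for i in range(config.n_trimers):
        verts = _triangle_vertices(sides[i])
        rot = _rotation_z(rng.uniform(0.0, 2.0 * math.pi) if config.random_rotation else 0.0)
        if config.tilt_sd_deg > 0:
            rot = rot @ _rotation_x(math.radians(rng.normal(0.0, config.tilt_sd_deg)))
        verts = verts @ rot.T
        verts += np.array([centres[i, 0], centres[i, 1], config.membrane_z])
        trimer_rows.append(
            dict(trimer_id=i, cx=centres[i, 0], cy=centres[i, 1],
                 cz=config.membrane_z, side=sides[i])
        )
        labelled = rng.random(3) < config.label_efficiency
        for v in range(3):
            vertex_rows.append(
                dict(trimer_id=i, vertex_id=v, x=verts[v, 0], y=verts[v, 1],
                     z=verts[v, 2], labelled=bool(labelled[v]))
            )
            if not labelled[v]:
                continue
            n_traces = max(
                rng.poisson(config.traces_per_vertex_mean), config.min_traces_per_vertex
            )
            for _ in range(n_traces):
                n_locs = max(
                    rng.poisson(config.locs_per_vertex_mean), config.min_locs_per_trace
                )
                if n_locs == 0:
                    continue
                noise = np.column_stack(
                    [
                        rng.normal(0.0, config.vertex_sigma_xy, (n_locs, 2)),
                        rng.normal(0.0, config.vertex_sigma_z, n_locs),
                    ]
                )
                mode = config.efo_mode_hz
                if rng.random() < config.multi_emitter_fraction:
                    mode = 2.0 * config.efo_mode_hz
                efo = _lognormal_mode(rng, mode, config.efo_shape, n_locs)
                ts = t_cursor + loc_dt * np.arange(n_locs)
                t_cursor = ts[-1] + 0.1
                loc_chunks.append(
                    pd.DataFrame(
                        {
                            "trace_id": trace_id,
                            "t": ts,
                            "x": verts[v, 0] + noise[:, 0],
                            "y": verts[v, 1] + noise[:, 1],
                            "z": verts[v, 2] + noise[:, 2],
                            "efo": efo,
                            "valid": True,
                            "origin": i * 3 + v,
                        }
                    )
                )
                trace_id += 1

    # uniform background, one localization per spurious trace, broad EFO
    area_um2 = config.field_size**2
    n_bg = rng.poisson(config.background_density * area_um2)
    if n_bg:
        xy = rng.uniform(0.0, field_nm, (n_bg, 2))
        z = rng.uniform(config.membrane_z - 300.0, config.membrane_z + 300.0, n_bg)
        efo = _lognormal_mode(rng, config.efo_mode_hz, 0.8, n_bg)
        ts = t_cursor + 0.1 * np.arange(n_bg)
        loc_chunks.append(
            pd.DataFrame(
                {
                    "trace_id": trace_id + np.arange(n_bg),
                    "t": ts,
                    "x": xy[:, 0],
                    "y": xy[:, 1],
                    "z": z,
                    "efo": efo,
                    "valid": True,
                    "origin": -1,
                }
            )
        )

    if loc_chunks:
        table = pd.concat(loc_chunks, ignore_index=True)
    else:
        table = io.empty_table()
        table["origin"] = pd.Series(dtype=np.int64)
    table = table.astype({"trace_id": np.int64, "valid": np.bool_, "origin": np.int64})
    truth = {
        "trimers": pd.DataFrame(trimer_rows),
        "vertices": pd.DataFrame(vertex_rows),
    }
    return table, truth


def simulate_tracks(config: TrackConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate Brownian single-molecule trajectories.

    Per-axis increments are Gaussian with variance ``2 * d_true * dt``
    using the actual elapsed time of each step, so dark gaps displace
    the molecule. With ``z_confinement_sd > 0`` the z coordinate is
    resampled i.i.d. around z = 0; with ``corral_radius_nm > 0`` xy
    excursions are reflected back into a circular corral.

    Returns the localization table and a per-track ground-truth table
    (``track_id, d_true``).
    """
    rng = np.random.default_rng(config.rng_seed)
    d_nm2_per_ms = config.d_true * 1e6 / 1e3  # um^2/s -> nm^2/ms
    chunks = []
    t_cursor = 0.0
    for tid in range(config.n_tracks):
        n = config.n_locs
        dt = np.full(n - 1, config.dt_ms)
        if config.dt_jitter_ms > 0:
            dt = np.clip(rng.normal(config.dt_ms, config.dt_jitter_ms, n - 1), 0.1, None)
        if config.gap_prob > 0:
            gaps = rng.random(n - 1) < config.gap_prob
            dt = dt + gaps * config.gap_len_ms
        t_ms = np.concatenate([[0.0], np.cumsum(dt)])

        sd = np.sqrt(2.0 * d_nm2_per_ms * dt)
        steps = rng.normal(0.0, 1.0, (n - 1, 3)) * sd[:, None]
        pos = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
        if config.corral_radius_nm > 0:
            pos[:, :2] = _reflect_into_disc(pos[:, :2], config.corral_radius_nm)
        if config.z_confinement_sd > 0:
            pos[:, 2] = rng.normal(0.0, config.z_confinement_sd, n)
        if config.loc_sigma > 0:
            pos = pos + rng.normal(0.0, config.loc_sigma, (n, 3))
        efo = _lognormal_mode(rng, config.efo_mode_hz, config.efo_shape, n)
        chunks.append(
            pd.DataFrame(
                {
                    "trace_id": tid,
                    "t": t_cursor + t_ms / 1e3,
                    "x": pos[:, 0],
                    "y": pos[:, 1],
                    "z": pos[:, 2],
                    "efo": efo,
                    "valid": True,
                }
            )
        )
        t_cursor += t_ms[-1] / 1e3 + 1.0
    table = pd.concat(chunks, ignore_index=True) if chunks else io.empty_table()
    table = table.astype({"trace_id": np.int64, "valid": np.bool_})
    truth = pd.DataFrame(
        {"track_id": np.arange(config.n_tracks), "d_true": config.d_true}
    )
    return table, truth


def _reflect_into_disc(xy: np.ndarray, radius: float) -> np.ndarray:
    """Radially reflect points into a disc of given radius (sequentially exact
    reflection is unnecessary for the qualitative confinement it models)."""
    out = xy.copy()
    r = np.linalg.norm(out, axis=1)
    outside = r > radius
    # reflect r -> 2*radius - r, capped at the origin
    new_r = np.clip(2.0 * radius - r[outside], 0.0, radius)
    scale = np.where(r[outside] > 0, new_r / r[outside], 0.0)
    out[outside] *= scale[:, None]
    return out


def simulate_two_channel_image(
    config: ImageConfig,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Render two channels of Gaussian spots with optional read noise.

    With ``coloc_fraction > 0`` each channel-2 spot is co-placed at a
    randomly chosen channel-1 spot centre with that probability.
    Returns ``(image_ch1, image_ch2, spots)`` where ``spots`` lists the
    realized ground-truth spot parameters per channel.
    """
    rng = np.random.default_rng(config.rng_seed)
    ny, nx = config.shape
    yy, xx = np.mgrid[0:ny, 0:nx]

    spots2 = [list(s) for s in config.spots_ch2]
    if config.coloc_fraction > 0 and config.spots_ch1:
        for s in spots2:
            if rng.random() < config.coloc_fraction:
                ref = config.spots_ch1[rng.integers(len(config.spots_ch1))]
                s[0], s[1] = ref[0], ref[1]

    rows = []

    def render(spots, channel):
        img = np.zeros((ny, nx), dtype=float)
        for x, y, amp, sigma_nm in spots:
            sigma_px = sigma_nm / config.pixel_nm
            img += amp * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2.0 * sigma_px**2))
            rows.append(dict(channel=channel, x=x, y=y, amplitude=amp, sigma_nm=sigma_nm))
        if config.noise_sd > 0:
            img += rng.normal(0.0, config.noise_sd, img.shape)
        return img

    img1 = render(config.spots_ch1, 1)
    img2 = render(spots2, 2)
    spots = pd.DataFrame(rows, columns=["channel", "x", "y", "amplitude", "sigma_nm"])
    return img1, img2, spots


def config_to_dict(cfg) -> dict:
    return {f.name: getattr(cfg, f.name) for f in fields(cfg)}
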