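import numpy as np
import pytest

import oracles
from conftest import make_table
from mfxtools import tracking
from mfxtools.synthetic import TrackConfig, simulate_tracks
from mfxtools.tracking import (
    MSDCurve,
    TrackFilterParams,
    Trajectory,
    build_trajectories,
    compute_msd,
    ensemble_msd,
    fit_diffusion,
)


def brownian_table(n_tracks, d, dt_ms, n_locs, seed, **kw):
    cfg = TrackConfig(n_tracks=n_tracks, d_true=d, dt_ms=dt_ms, n_locs=n_locs,
                      loc_sigma=0.0, rng_seed=seed, **kw)
    table, _ = simulate_tracks(cfg)
    return table


def make_trajectory(t_ms, xyz, track_id=0):
    return Trajectory(track_id=track_id, t=np.asarray(t_ms) / 1e3,
                      xyz=np.asarray(xyz, dtype=float), mean_efo=75e3, source_trace=0)


class TestBuildTrajectories:
    def _table(self, n, gap_at=None, gap_ms=25.0, efo=75_000.0):
        t = np.arange(n) * 2e-3
        if gap_at is not None:
            t[gap_at:] += gap_ms * 1e-3
        rng = np.random.default_rng(0)
        return make_table(np.zeros(n), t, rng.normal(0, 10, n),
                          rng.normal(0, 10, n), rng.normal(0, 10, n),
                          efos=np.full(n, efo))

    def test_gap_truncation(self):
        table = self._table(500, gap_at=300)
        trajs, _ = build_trajectories(table, TrackFilterParams())
        assert len(trajs) == 1
        assert trajs[0].n_locs == 300

    def test_short_trajectory_dropped(self):
        table = self._table(150)
        trajs, log = build_trajectories(table, TrackFilterParams(min_locs=200))
        assert trajs == []
        assert log["removed_short"] == 1

    def test_exactly_min_locs_dropped(self):
        # "greater than" is strict
        table = self._table(200)
        trajs, _ = build_trajectories(table, TrackFilterParams(min_locs=200))
        assert trajs == []

    def test_high_efo_dropped(self):
        table = self._table(500, efo=150_000.0)
        trajs, log = build_trajectories(table, TrackFilterParams())
        assert trajs == []
        assert log["removed_efo"] == 1

    def test_post_gap_remainder_discarded_by_default(self):
        table = self._table(600, gap_at=300)
        trajs, _ = build_trajectories(table, TrackFilterParams())
        assert len(trajs) == 1 and trajs[0].n_locs == 300

    def test_keep_post_gap_switch(self):
        table = self._table(600, gap_at=300)
        trajs, _ = build_trajectories(table, TrackFilterParams(keep_post_gap=True))
        assert len(trajs) == 2
        assert {t.n_locs for t in trajs} == {300}

    def test_strictly_increasing_time(self):
        table = self._table(300)
        trajs, _ = build_trajectories(table, TrackFilterParams())
        assert (np.diff(trajs[0].t) > 0).all()


class TestComputeMsd:
    def test_stationary_msd_zero(self):
        t_ms = np.arange(300) * 2.0
        xyz = np.tile([[5.0, -3.0, 2.0]], (300, 1))
        curve = compute_msd(make_trajectory(t_ms, xyz), TrackFilterParams())
        assert not curve.empty
        np.testing.assert_allclose(curve.msd, 0.0)

    def test_ballistic_closed_form(self):
        # v = 1 nm/ms: with one lag value per bin, MSD(tau) = tau^2 exactly
        t_ms = np.arange(200) * 2.0
        xyz = np.column_stack([t_ms, np.zeros(200), np.zeros(200)])
        params = TrackFilterParams(lag_bin_width=2.0)
        curve = compute_msd(make_trajectory(t_ms, xyz), params)
        # the final bin absorbs the boundary lag tau = t_max as well, so it
        # holds two lag values; all others hold exactly one
        np.testing.assert_allclose(curve.msd[:-1], curve.lag_means[:-1] ** 2, rtol=1e-12)

    def test_brownian_pooled_msd(self):
        # pooled MSD per bin within 3 s.e. of 6 D tau
        d = 0.01
        table = brownian_table(300, d, 2.0, 300, seed=4)
        trajs, _ = build_trajectories(table, TrackFilterParams())
        curve, _, _ = ensemble_msd(trajs, TrackFilterParams())
        expected = 6.0 * d * 1e3 * curve.lag_means  # nm^2 (D in um^2/s -> nm^2/ms)
        sel = curve.sem > 0
        resid = np.abs(curve.msd[sel] - expected[sel]) / curve.sem[sel]
        assert np.median(resid) < 3.0

    def test_weights_are_pair_counts(self):
        t_ms = np.arange(10) * 2.0
        xyz = np.zeros((10, 3))
        params = TrackFilterParams(lag_bin_width=2.0)
        curve = compute_msd(make_trajectory(t_ms, xyz), params)
        # lag k*2 ms has 10-k ordered pairs
        np.testing.assert_array_equal(curve.weights, 10 - np.arange(1, 10))

    def test_too_short(self):
        curve = compute_msd(make_trajectory([0.0], [[0, 0, 0]]), TrackFilterParams())
        assert curve.empty

    def test_translation_invariance(self, rng):
        t_ms = np.cumsum(rng.uniform(1, 3, 100))
        xyz = rng.normal(0, 30, (100, 3))
        c0 = compute_msd(make_trajectory(t_ms, xyz), TrackFilterParams())
        c1 = compute_msd(make_trajectory(t_ms, xyz + [100.0, -50.0, 10.0]),
                         TrackFilterParams())
        np.testing.assert_allclose(c0.msd, c1.msd, rtol=1e-12)

    def test_scaling_quadratic(self, rng):
        t_ms = np.cumsum(rng.uniform(1, 3, 100))
        xyz = rng.normal(0, 30, (100, 3))
        c0 = compute_msd(make_trajectory(t_ms, xyz), TrackFilterParams())
        c2 = compute_msd(make_trajectory(t_ms, 3.0 * xyz), TrackFilterParams())
        np.testing.assert_allclose(c2.msd, 9.0 * c0.msd, rtol=1e-12)


class TestFitDiffusion:
    def _curve(self, tau, msd, w=None):
        tau = np.asarray(tau, dtype=float)
        return MSDCurve(tau, tau, np.asarray(msd, dtype=float),
                        np.ones_like(tau, dtype=np.int64) if w is None else np.asarray(w))

    def test_exact_linear(self):
        tau = np.array([7.0, 14.0, 21.0, 28.0])
        msd = 6.0 * 0.01 * 1e3 * tau  # nm^2 for D = 0.01 um^2/s
        fit = fit_diffusion(self._curve(tau, msd), (5.0, 50.0))
        assert fit.d == pytest.approx(0.01, rel=1e-12)

    def test_weight_invariance_on_noiseless_data(self):
        tau = np.array([7.0, 14.0, 21.0, 28.0])
        msd = 6.0 * 0.02 * 1e3 * tau
        f1 = fit_diffusion(self._curve(tau, msd), (5.0, 50.0))
        f2 = fit_diffusion(self._curve(tau, msd, w=[5, 50, 500, 1]), (5.0, 50.0))
        assert f1.d == pytest.approx(f2.d, rel=1e-12)

    def test_refusal_with_too_few_bins(self):
        fit = fit_diffusion(self._curve([10.0], [100.0]), (5.0, 50.0))
        assert fit.refused and "bins" in fit.reason

    def test_matches_normal_equations_oracle(self, rng):
        tau = np.sort(rng.uniform(5, 50, 8))
        msd = 6.0 * 15.0 * tau + rng.normal(0, 40, 8)
        w = rng.integers(1, 100, 8).astype(float)
        fit = fit_diffusion(self._curve(tau, msd, w=w), (0.0, 60.0))
        slope = oracles.weighted_origin_fit(tau, msd, w)
        assert fit.d == pytest.approx(slope / 6.0 * 1e-3, rel=1e-12)

    def test_static_noise_inflates_zero_intercept_micro_d(self, rng):
        # with intercept 6 sigma^2 forced through origin, the fitted slope
        # exceeds 6D by 6 sigma^2 * sum(w tau)/sum(w tau^2)
        d_nm2_ms = 10.0
        sigma = 15.0
        tau = np.array([7.0, 14.0, 21.0, 28.0, 35.0, 42.0, 49.0])
        w = np.array([100, 90, 80, 70, 60, 50, 40], dtype=float)
        msd = 6.0 * d_nm2_ms * tau + 6.0 * sigma**2
        fit = fit_diffusion(self._curve(tau, msd, w=w), (5.0, 50.0))
        excess = 6.0 * sigma**2 * np.sum(w * tau) / np.sum(w * tau**2)
        expected = (6.0 * d_nm2_ms + excess) / 6.0 * 1e-3
        assert fit.d == pytest.approx(expected, rel=1e-9)


class TestEnsemble:
    def test_identical_trajectories_match_single(self, rng):
        t_ms = np.arange(250) * 2.0
        xyz = np.cumsum(rng.normal(0, 5, (250, 3)), axis=0)
        traj = make_trajectory(t_ms, xyz)
        single = compute_msd(traj, TrackFilterParams())
        curve, _, _ = ensemble_msd([traj, make_trajectory(t_ms, xyz, track_id=1)],
                                   TrackFilterParams())
        np.testing.assert_allclose(curve.msd, single.msd, rtol=1e-12)
        np.testing.assert_allclose(curve.sem, 0.0, atol=1e-9)

    def test_micro_d_recovery_within_5pct(self):
        d = 0.02
        table = brownian_table(200, d, 2.0, 500, seed=5)
        trajs, _ = build_trajectories(table, TrackFilterParams())
        _, micro, _ = ensemble_msd(trajs, TrackFilterParams())
        assert micro.d == pytest.approx(d, rel=0.05)

    def test_bimodal_mixture_separates(self):
        params = TrackFilterParams()
        t_lo = brownian_table(60, 0.004, 2.0, 400, seed=6)
        t_hi = brownian_table(60, 0.02, 2.0, 400, seed=7)
        lo_fits = tracking.per_trajectory_fits(build_trajectories(t_lo, params)[0], params)
        hi_fits = tracking.per_trajectory_fits(build_trajectories(t_hi, params)[0], params)
        med_lo = lo_fits["d_micro"].median()
        med_hi = hi_fits["d_micro"].median()
        assert med_lo == pytest.approx(0.004, rel=0.25)
        assert med_hi == pytest.approx(0.02, rel=0.25)
        # the pooled per-trajectory histogram has a clear dip between the modes
        pooled = np.concatenate([lo_fits["d_micro"], hi_fits["d_micro"]])
        mid = (pooled > 0.008) & (pooled < 0.012)
        assert mid.mean() < 0.2

    def test_median_micro_d_unbiased(self):
        for d, seed in [(0.004, 8), (0.01, 9), (0.02, 10)]:
            table = brownian_table(80, d, 2.0, 300, seed=seed)
            trajs, _ = build_trajectories(table, TrackFilterParams())
            fits = tracking.per_trajectory_fits(trajs, TrackFilterParams())
            assert fits["d_micro"].median() == pytest.approx(d, rel=0.10)

    def test_confined_macro_below_micro(self):
        table = brownian_table(80, 0.02, 2.0, 400, seed=11,
                               z_confinement_sd=50.0, corral_radius_nm=150.0)
        trajs, _ = build_trajectories(table, TrackFilterParams())
        _, micro, macro = ensemble_msd(trajs, TrackFilterParams())
        assert macro.d < micro.d


class TestParamValidation:
    def test_window_ordering(self):
        with pytest.raises(ValueError):
            TrackFilterParams(micro_window=(5.0, 60.0), macro_window=(50.0, 350.0))

    def test_center_of_mass_overlay(self, rng):
        t_ms = np.arange(100) * 20.0
        xyz = np.cumsum(rng.normal(0, 5, (100, 3)), axis=0)
        out = tracking.center_of_mass_overlay([make_trajectory(t_ms, xyz)], duration_s=1.0)
        assert len(out) == 1
        assert len(out[0]) == 51  # first second at 20 ms spacing
        np.testing.assert_allclose(out[0].mean(axis=0), 0.0, atol=1e-9)
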