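"""The four stochastic engines: exactness, determinism, limits, statistics."""

import math

import numpy as np
import pytest

import camnoise as cn
from camnoise.simulate import JumpPath


def _se_of_mean(system, t_end):
    """Standard error of a time-averaged mean over t_end (OU theory)."""
    p = cn.noise_params(system)
    n_eff = t_end / (2 * p.tau)
    return math.sqrt(p.variance / n_eff)


class TestSSA:
    def test_same_seed_same_path(self, cam_small):
        a = cn.ssa_simulate(cam_small, 50.0, seed=11)
        b = cn.ssa_simulate(cam_small, 50.0, seed=11)
        assert np.array_equal(a.times, b.times)
        assert np.array_equal(a.states, b.states)
        c = cn.ssa_simulate(cam_small, 50.0, seed=12)
        assert not np.array_equal(a.times, c.times)

    def test_conservation_laws(self, cam_small):
        path = cn.ssa_simulate(cam_small, 100.0, seed=1)
        X = path.states[:, 0]
        Y = path.states[:, 1]
        Z = path.states[:, 2]
        assert len(set(X + Z)) == 1  # total calcium
        assert len(set(Y + Z)) == 1  # total buffer
        assert path.states.min() >= 0

    def test_single_reaction_per_event(self, cam_small):
        path = cn.ssa_simulate(cam_small, 20.0, seed=3)
        steps = np.diff(path.states, axis=0)
        assert set(np.abs(steps).sum(axis=1)) == {3}  # X, Y, Z all move by 1
        assert np.all(np.diff(path.times) > 0)

    def test_stationary_mean_matches_equilibrium(self, cam_small):
        path = cn.ssa_simulate(cam_small, 5000.0, seed=5)
        x = cn.resample_path(path, 0.01).component("X")
        eq = cn.equilibrium_state(cam_small)
        assert np.mean(x.values) == pytest.approx(
            eq.X, abs=3 * _se_of_mean(cam_small, 5000.0)
        )

    def test_diffusion_exchanges_calcium_only(self, cam):
        system = cn.make_system(cam, 0.125, 0.1, D_Ca=0.2)
        path = cn.ssa_simulate(system, 50.0, seed=2)
        Y, Z = path.states[:, 1], path.states[:, 2]
        assert len(set(Y + Z)) == 1  # buffer still conserved
        assert len(set(path.states[:, 0] + Z)) > 1  # calcium exchanged

    def test_rejects_bad_horizon(self, cam_small):
        with pytest.raises(ValueError):
            cn.ssa_simulate(cam_small, 0.0, seed=1)


class TestResample:
    def _path(self, times, xs):
        return JumpPath(
            times=np.asarray(times, dtype=float),
            states=np.asarray(xs, dtype=np.int64)[:, None],
            columns=("X",),
            meta={"t_end": float(times[-1])},
        )

    def test_linear_midpoint(self):
        traj = cn.resample_path(self._path([0.0, 1.0], [0, 2]), dt=0.5)
        assert np.allclose(traj.values, [0.0, 1.0, 2.0])

    def test_constant_path(self):
        traj = cn.resample_path(self._path([0.0, 0.3, 2.0], [5, 5, 5]), dt=0.25)
        assert np.all(traj.values == 5.0)

    def test_grid_length_contract(self):
        traj = cn.resample_path(self._path([0.0, 1.0, 3.14], [0, 1, 2]), dt=0.01)
        assert len(traj) == math.floor(3.14 / 0.01) + 1

    def test_hold_mode_keeps_pre_event_state(self):
        traj = cn.resample_path(self._path([0.0, 1.0], [0, 2]), dt=0.5, kind="hold")
        assert np.allclose(traj.values, [0.0, 0.0, 2.0])


class TestCLE:
    def test_noiseless_is_euler_ode(self, cam_small):
        traj = cn.cle_simulate(cam_small, 5.0, dt=0.01, seed=1, noise=False,
                               x0=1.0)
        # independent forward-Euler integration of the mass-action ODE
        rates = cn.stochastic_rates(cam_small)
        cp, cm = float(rates.c_plus[0]), float(rates.c_minus[0])
        eq = cn.equilibrium_state(cam_small)
        X = float(np.rint(cn.concentration_to_count(1.0, 0.125)))
        Z = float(np.rint(eq.Z[0]))
        BT = float(np.rint(eq.Y[0])) + Z
        expected = [X]
        for _ in range(len(traj) - 1):
            inc = (cm * Z - cp * X * (BT - Z)) * 0.01
            X += inc
            Z -= inc
            expected.append(X)
        assert np.allclose(traj.component("X").values, expected, rtol=0,
                           atol=1e-9)

    def test_same_seed_same_trajectory(self, cam_small):
        a = cn.cle_simulate(cam_small, 20.0, seed=4)
        b = cn.cle_simulate(cam_small, 20.0, seed=4)
        assert np.array_equal(a.values, b.values)

    def test_stationary_variance_near_ou_prediction(self, cam_small):
        traj = cn.cle_simulate(cam_small, 4000.0, seed=6)
        var = np.var(traj.component("X").values, ddof=1)
        predicted = cn.noise_params(cam_small).variance
        assert var == pytest.approx(predicted, rel=0.20)

    def test_no_nan_and_clamps_logged_in_tiny_volume(self, cam):
        # ~0.6 free ions on average: negative excursions are certain
        system = cn.make_system(cam, 0.01, 0.1)
        traj = cn.cle_simulate(system, 200.0, seed=7)
        assert np.all(np.isfinite(traj.values))
        assert traj.values.min() >= 0
        assert traj.meta["n_clamped"] > 0

    def test_multibuffer_channels(self, cam):
        system = cn.make_system(
            [cam, cn.buffer_from_table("EGTA")], 0.125, 0.1
        )
        traj = cn.cle_simulate(system, 100.0, seed=8)
        assert traj.values.shape[1] == 5
        assert np.all(np.isfinite(traj.values))


class TestCLEEBA:
    def test_noiseless_relaxation_follows_linear_ode(self, cam_small):
        dt = 0.01
        traj = cn.cle_eba_simulate(cam_small, 4.0, dt=dt, seed=1, noise=False,
                                   x0=1.0)
        lk = cn.linear_kinetics(cam_small)
        eq = cn.equilibrium_state(cam_small)
        x0c = float(np.rint(cn.concentration_to_count(1.0, 0.125)))
        k = np.arange(len(traj))
        # closed form of the Euler recursion itself
        expected = eq.X + (x0c - eq.X) * (1 - lk.K1 * dt) ** k
        assert np.allclose(traj.values, expected, rtol=1e-9)

    def test_frozen_volatility_is_euler_ou(self, cam_1fl):
        # 1 fl voxel (~60 ions): no zero-clamping, so the frozen-volatility
        # reduced engine and the Euler OU integrator follow the same recursion
        frozen = cn.cle_eba_simulate(
            cam_1fl, 50.0, seed=9, freeze_sigma=True
        )
        assert frozen.meta["n_clamped"] == 0
        ou = cn.oup_simulate(
            cn.noise_params(cam_1fl),
            x0=float(np.rint(cn.equilibrium_state(cam_1fl).X)),
            t_end=50.0,
            seed=9,
        )
        assert np.allclose(frozen.values, ou.values, rtol=1e-7)

    def test_stationary_mean(self, cam_small):
        traj = cn.cle_eba_simulate(cam_small, 4000.0, seed=10)
        eq = cn.equilibrium_state(cam_small)
        assert np.mean(traj.values) == pytest.approx(
            eq.X, abs=3 * _se_of_mean(cam_small, 4000.0)
        )

    def test_multibuffer_reduction_runs(self, cam):
        system = cn.make_system(
            [cam, cn.buffer_from_table("Fluo-4")], 0.125, 0.1
        )
        traj = cn.cle_eba_simulate(system, 100.0, seed=2)
        assert np.all(np.isfinite(traj.values))
        mean = np.mean(traj.component("X").values[1000:])
        assert mean == pytest.approx(cn.equilibrium_state(system).X, rel=0.2)


class TestOUP:
    def test_noiseless_exact_decay(self):
        params = cn.NoiseParams(mu=10.0, tau=0.5, sigma=0.0)
        traj = cn.oup_simulate(params, x0=20.0, t_end=5.0, dt=0.01, seed=1,
                               exact=True)
        expected = 10.0 + 10.0 * np.exp(-traj.times / 0.5)
        assert np.allclose(traj.values, expected, rtol=1e-10)

    def test_stationary_variance_and_acf(self):
        params = cn.NoiseParams(mu=7.53, tau=0.516, sigma=5.348)
        traj = cn.oup_simulate(params, x0=7.53, t_end=10_000.0, dt=0.01,
                               seed=2, exact=True)
        assert np.var(traj.values, ddof=1) == pytest.approx(
            params.variance, rel=0.10
        )
        acf = cn.autocorrelation(traj, max_lag=1.0)
        lag_idx = int(round(params.tau / 0.01))
        assert acf.values[lag_idx] == pytest.approx(math.exp(-1), abs=0.05)

    def test_rejects_invalid_steps(self):
        params = cn.NoiseParams(mu=0.0, tau=1.0, sigma=1.0)
        with pytest.raises(ValueError):
            cn.oup_simulate(params, x0=0.0, t_end=1.0, dt=0.0, seed=1)
        with pytest.raises(ValueError):
            cn.NoiseParams(mu=0.0, tau=-1.0, sigma=1.0)


class TestEngineConsistency:
    """Cross-engine invariants on the calcium-calmodulin microdomain."""

    def test_all_engines_recover_theoretical_tau(self, cam_small):
        tau = cn.tau_theory(cam_small)
        t_end = 5000.0  # single-run tau-hat spread scales as sqrt(tau/T)
        for engine in ("ssa", "cle", "cle-eba", "oup"):
            hats = []
            for seed in (21, 22, 23, 24):
                if engine == "ssa":
                    traj = cn.resample_path(
                        cn.ssa_simulate(cam_small, t_end, seed=seed), 0.01
                    ).component("X")
                elif engine == "cle":
                    traj = cn.cle_simulate(
                        cam_small, t_end, seed=seed
                    ).component("X")
                elif engine == "cle-eba":
                    traj = cn.cle_eba_simulate(cam_small, t_end, seed=seed)
                else:
                    p = cn.noise_params(cam_small)
                    traj = cn.oup_simulate(p, x0=p.mu, t_end=t_end, seed=seed)
                hats.append(cn.summary_stats(traj).tau_hat)
            assert np.mean(hats) == pytest.approx(tau, rel=0.15), engine

    def test_mean_ssa_relaxation_tracks_linear_theory(self, cam_small):
        """Averaged perturbation decay follows the mono-exponential solution."""
        dt, t_end = 0.01, 4.0
        runs = [
            cn.resample_path(
                cn.ssa_simulate(cam_small, t_end, seed=s, x0=1.0), dt
            ).component("X")
            for s in range(31, 41)
        ]
        n = min(len(r) for r in runs)
        stack = np.stack([r.values[:n] for r in runs])
        mean_path = stack.mean(axis=0)
        pooled_sd = stack.std(axis=0, ddof=1)
        t = dt * np.arange(n)
        theory = cn.deterministic_relaxation(1.0, cam_small, t) * 0.125 * \
            cn.COUNTS_PER_UM_FL
        # stochastic relaxations fluctuate around the deterministic curve
        resid = np.abs(mean_path - theory)[1:]
        assert np.all(resid < 3 * np.maximum(pooled_sd[1:], 1.0))
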