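import numpy as np
import pytest
from scipy import stats

from spad.model_core import ModelDomainError, NeutralParams, stationary_beta, neutral_to_ratespec
from spad.simulator import (
    DiscreteBDConfig,
    TrajectoryEnsemble,
    discrete_rate_tables,
    ensemble_summary,
    read_ensemble,
    simulate_discrete,
    simulate_sde,
    terminal_sample,
    write_ensemble,
)


@pytest.fixture()
def small_ensemble(ref_params):
    return simulate_sde(ref_params, 0.2, 10.0, 0.01, 25, seed=7)


class TestDiscreteRates:
    def test_boundary_rates(self, ref_params):
        cfg = DiscreteBDConfig(J=100, params=ref_params, n0=0, t_end=1.0, seed=0)
        B, D = discrete_rate_tables(cfg)
        # at n=0 the only possible event is a birth
        assert D[0] == 0.0
        assert B[0] == pytest.approx(ref_params.m * ref_params.p)
        # at n=J both birth terms vanish: the chain never exceeds J
        assert B[100] == 0.0
        assert D[100] > 0.0

    def test_lam_j_default_scaling(self, ref_params):
        cfg = DiscreteBDConfig(J=500, params=ref_params, n0=10, t_end=1.0, seed=0)
        assert cfg.effective_lam_J == pytest.approx(ref_params.lam * 500)
        cfg2 = DiscreteBDConfig(J=500, params=ref_params, n0=10, t_end=1.0, seed=0, lam_J=3.0)
        assert cfg2.effective_lam_J == 3.0

    def test_invalid_configs(self, ref_params):
        with pytest.raises(ModelDomainError):
            DiscreteBDConfig(J=1, params=ref_params, n0=0, t_end=1.0, seed=0)
        with pytest.raises(ModelDomainError):
            DiscreteBDConfig(J=10, params=ref_params, n0=11, t_end=1.0, seed=0)
        with pytest.raises(ModelDomainError):
            DiscreteBDConfig(J=10, params=ref_params, n0=0, t_end=0.0, seed=0)


class TestSimulateDiscrete:
    def test_first_event_from_zero_is_birth(self, ref_params):
        # D(0) = 0, so from n0=0 the state can only ever have moved up
        cfg = DiscreteBDConfig(J=50, params=ref_params, n0=0, t_end=200.0, seed=11, n_traj=40)
        ens = simulate_discrete(cfg, np.linspace(1.0, 200.0, 20))
        assert np.all(ens.paths >= 0.0)
        assert ens.paths.max() > 0.0  # some birth happened somewhere

    def test_values_stay_in_unit_interval(self, ref_params):
        cfg = DiscreteBDConfig(J=30, params=ref_params, n0=29, t_end=300.0, seed=5, n_traj=50)
        ens = simulate_discrete(cfg, np.linspace(0.0, 300.0, 31))
        assert np.all(ens.paths >= 0.0) and np.all(ens.paths <= 1.0)

    def test_seed_determinism(self, ref_params):
        cfg = DiscreteBDConfig(J=200, params=ref_params, n0=40, t_end=20.0, seed=123, n_traj=10)
        grid = np.linspace(0.0, 20.0, 11)
        a = simulate_discrete(cfg, grid)
        b = simulate_discrete(cfg, grid)
        np.testing.assert_array_equal(a.paths, b.paths)

    def test_record_grid_validation(self, ref_params):
        cfg = DiscreteBDConfig(J=20, params=ref_params, n0=5, t_end=1.0, seed=0)
        with pytest.raises(ModelDomainError):
            simulate_discrete(cfg, [0.5, 0.25])
        with pytest.raises(ModelDomainError):
            simulate_discrete(cfg, [0.5, 2.0])

    def test_initial_grid_point_records_n0(self, ref_params):
        cfg = DiscreteBDConfig(J=40, params=ref_params, n0=17, t_end=1.0, seed=3, n_traj=4)
        ens = simulate_discrete(cfg, [0.0, 1.0])
        np.testing.assert_array_equal(ens.paths[:, 0], 17 / 40)

    def test_numba_and_python_kernels_agree(self, ref_params):
        import spad.simulator as sim

        if not sim._HAVE_NUMBA:
            pytest.skip("numba unavailable; python kernel is the only path")
        cfg = DiscreteBDConfig(J=80, params=ref_params, n0=16, t_end=30.0, seed=99, n_traj=6)
        B, D = discrete_rate_tables(cfg)
        seeds = np.random.SeedSequence(99).generate_state(6, dtype=np.uint32).astype(np.int64)
        grid_nat = np.linspace(1.0, 30.0, 7) * 80
        out_nb = np.empty((6, 7), dtype=np.int64)
        out_py = np.empty((6, 7), dtype=np.int64)
        sim._gillespie_kernel(B, D, 16, seeds, grid_nat, out_nb)
        sim._gillespie_kernel_py(B, D, 16, seeds, grid_nat, out_py)
        np.testing.assert_array_equal(out_nb, out_py)

    def test_terminal_distribution_approaches_beta(self, ref_params, ref_stationary):
        """KS distance to the stationary Beta decreases in J (module-scale
        version of the weak-convergence property)."""
        t_end = 10.0 / ref_params.m
        ks_stats = []
        for J, seed in [(100, 1), (1000, 2)]:
            cfg = DiscreteBDConfig(
                J=J, params=ref_params, n0=round(0.2 * J), t_end=t_end, seed=seed, n_traj=400
            )
            vals = simulate_discrete(cfg, [t_end]).paths[:, -1]
            ks = stats.kstest(
                vals, lambda x: stats.beta.cdf(x, ref_stationary.alpha, ref_stationary.beta)
            )
            ks_stats.append(ks.statistic)
        assert ks_stats[1] < ks_stats[0]


class TestSimulateSde:
    def test_validation(self, ref_params):
        with pytest.raises(ModelDomainError):
            simulate_sde(ref_params, -0.1, 1.0, 0.01, 2, seed=0)
        with pytest.raises(ModelDomainError):
            simulate_sde(ref_params, 0.5, 1.0, 0.0, 2, seed=0)
        with pytest.raises(ModelDomainError):
            simulate_sde(ref_params, 0.5, 1.0, 0.01, 2, seed=0, method="heun")
        with pytest.raises(ModelDomainError):
            simulate_sde(NeutralParams(m=0.9, p=0.5, lam=1.0), 0.5, 10.0, 2.0, 2, seed=0)

    def test_boundedness(self, ref_params):
        ens = simulate_sde(ref_params, 0.99, 50.0, 0.01, 50, seed=21)
        assert np.all(ens.paths >= 0.0) and np.all(ens.paths <= 1.0)

    def test_seed_determinism(self, small_ensemble, ref_params):
        again = simulate_sde(ref_params, 0.2, 10.0, 0.01, 25, seed=7)
        np.testing.assert_array_equal(small_ensemble.paths, again.paths)

    def test_lam_zero_matches_exponential_relaxation(self):
        """Drift-only case: Z(t) = p + (z0 - p) exp(-m t), 4-decimal match
        at dt = 1e-3 (both methods coincide when lam = 0)."""
        params = NeutralParams(m=0.2, p=0.1, lam=0.0)
        for method in ("milstein", "euler"):
            ens = simulate_sde(
                params, 0.8, 5.0, 1e-3, 1, seed=0, record_times=[1.0, 5.0], method=method
            )
            expected = 0.1 + 0.7 * np.exp(-0.2 * ens.times)
            np.testing.assert_allclose(ens.paths[0], expected, atol=5e-5)

    def test_terminal_mean_and_variance_match_beta(self):
        """Stationary moments: MC mean within 3 SE of p, variance within
        10% of the closed-form Beta variance (1e4 trajectories)."""
        params = NeutralParams(m=0.3, p=0.02, lam=0.01)
        bp = stationary_beta(neutral_to_ratespec(params))
        t_end = 40.0  # m*t = 12
        ens = simulate_sde(params, 0.2, t_end, 0.01, 10_000, seed=17, record_times=[0.0, t_end])
        vals = terminal_sample(ens, t_end)
        se = vals.std(ddof=1) / np.sqrt(vals.size)
        assert abs(vals.mean() - bp.mean) < 3 * se
        assert vals.var(ddof=1) == pytest.approx(bp.var, rel=0.10)

    def test_record_times_must_align(self, ref_params):
        with pytest.raises(ModelDomainError):
            simulate_sde(ref_params, 0.2, 1.0, 0.01, 2, seed=0, record_times=[0.005])


class TestEnsembleSummary:
    def test_constant_paths_zero_width_band(self):
        params = NeutralParams(m=0.2, p=0.3, lam=0.0)
        ens = simulate_sde(params, 0.3, 2.0, 0.01, 5, seed=0)
        summary = ensemble_summary(ens, level=0.95)
        np.testing.assert_allclose(summary["mean"], 0.3, atol=1e-12)
        np.testing.assert_allclose(summary["upper"] - summary["lower"], 0.0, atol=1e-12)

    def test_band_ordering(self, small_ensemble):
        summary = ensemble_summary(small_ensemble, level=0.9)
        assert np.all(summary["lower"] <= summary["mean"] + 1e-12)
        assert np.all(summary["mean"] <= summary["upper"] + 1e-12)

    def test_relaxation_toward_long_run_mean(self, ref_params):
        """The ensemble mean decays from z0 toward p on the 1/m time scale."""
        ens = simulate_sde(ref_params, 0.2, 60.0, 0.01, 200, seed=3)
        summary = ensemble_summary(ens)
        m = ref_params.m
        at = lambda t: summary["mean"].iloc[int(np.argmin(np.abs(summary["time"] - t)))]
        expected = lambda t: ref_params.p + (0.2 - ref_params.p) * np.exp(-m * t)
        for t in (10.0, 30.0, 60.0):
            assert at(t) == pytest.approx(expected(t), abs=0.02)

    def test_requires_two_trajectories(self, ref_params):
        ens = simulate_sde(ref_params, 0.2, 1.0, 0.01, 1, seed=0)
        with pytest.raises(ModelDomainError):
            ensemble_summary(ens)


class TestTerminalSample:
    def test_single_trajectory(self, ref_params):
        ens = simulate_sde(ref_params, 0.2, 1.0, 0.01, 1, seed=0)
        assert terminal_sample(ens, 1.0).shape == (1,)

    def test_out_of_range_errors(self, small_ensemble):
        with pytest.raises(ModelDomainError):
            terminal_sample(small_ensemble, 11.0)
        with pytest.raises(ModelDomainError):
            terminal_sample(small_ensemble, -1.0)

    def test_nearest_grid_time(self, small_ensemble):
        np.testing.assert_array_equal(
            terminal_sample(small_ensemble, 10.0), small_ensemble.paths[:, -1]
        )

    def test_stationary_sample_passes_ks_in_most_seeds(self, ref_params, ref_stationary):
        """Module-scale KS calibration: t >= 10/m, 5 seeds, all should pass
        at the 1% level."""
        t_end = 120.0
        passed = 0
        for seed in range(5):
            ens = simulate_sde(
                ref_params, 0.2, t_end, 0.01, 225, seed=1000 + seed, record_times=[0.0, t_end]
            )
            vals = terminal_sample(ens, t_end)
            ks = stats.kstest(
                vals, lambda x: stats.beta.cdf(x, ref_stationary.alpha, ref_stationary.beta)
            )
            passed += ks.pvalue >= 0.01
        assert passed >= 4


class TestEnsembleIO:
    def test_round_trip_exact(self, small_ensemble, tmp_path):
        tsv = tmp_path / "ens.tsv"
        write_ensemble(small_ensemble, tsv)
        back = read_ensemble(tsv)
        np.testing.assert_array_equal(back.paths, small_ensemble.paths)
        np.testing.assert_array_equal(back.times, small_ensemble.times)
        assert back.params == small_ensemble.params
        assert back.seed == small_ensemble.seed
        assert back.scheme == small_ensemble.scheme

    def test_discrete_round_trip(self, ref_params, tmp_path):
        cfg = DiscreteBDConfig(J=60, params=ref_params, n0=12, t_end=5.0, seed=2, n_traj=3)
        ens = simulate_discrete(cfg, [0.0, 2.5, 5.0])
        write_ensemble(ens, tmp_path / "d.tsv", tmp_path / "d.json")
        back = read_ensemble(tmp_path / "d.tsv", tmp_path / "d.json")
        np.testing.assert_array_equal(back.paths, ens.paths)
        assert back.meta["J"] == 60


class TestTrajectoryEnsembleInvariants:
    def test_rejects_out_of_bounds_values(self, ref_params):
        with pytest.raises(ModelDomainError):
            TrajectoryEnsemble(
                times=[0.0, 1.0],
                paths=[[0.5, 1.2]],
                params=ref_params,
                seed=0,
                scheme="diffusion",
            )

    def test_rejects_non_increasing_times(self, ref_params):
        with pytest.raises(ModelDomainError):
            TrajectoryEnsemble(
                times=[1.0, 0.5],
                paths=[[0.5, 0.5]],
                params=ref_params,
                seed=0,
                scheme="diffusion",
            )
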