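import math
import warnings

import numpy as np
import pytest
from scipy.stats import ks_2samp

from persistext.environment import EnvironmentSpec
from persistext.gillespie import (
    propensities,
    run_ensemble,
    ssa_constant,
    ssa_dmn,
    ssa_next_reaction,
    ssa_time_dependent,
)
from persistext.model_core import ModelParams


class TestPropensities:
    def test_absorbing_state(self, small_params):
        assert propensities((0, 0), 1.5, small_params) == (0.0, 0.0, 0.0, 0.0)

    def test_logistic_ceiling(self, small_params):
        birth, *_ = propensities((small_params.K, 5), 2.0, small_params)
        assert birth == 0.0

    def test_overshoot_clipped(self, small_params):
        birth, *_ = propensities((small_params.K + 3, 0), 2.0, small_params)
        assert birth == 0.0

    def test_printed_rates(self):
        p = ModelParams(B_ref=1.1, K=500, alpha=0.02, beta=0.02)
        assert propensities((45, 45), 1.1, p) == pytest.approx(
            (1.1 * 45 * (1 - 45 / 500), 45.0, 0.9, 0.9)
        )


class TestTrajectoryInvariants:
    def test_counts_and_stoichiometry(self, small_params):
        traj = ssa_constant(small_params, 1.3, init=(8, 3), seed=5, t_max=1e5)
        assert traj.extinct
        assert np.all(traj.n >= 0) and np.all(traj.m >= 0)
        assert np.all(np.diff(traj.times) > 0)
        # each event changes (n, m) by one reaction's stoichiometry
        dn = np.diff(np.concatenate([[8], traj.n]))
        dm = np.diff(np.concatenate([[3], traj.m]))
        steps = set(zip(dn.tolist(), dm.tolist()))
        assert steps <= {(1, 0), (-1, 0), (-1, 1), (1, -1)}
        assert (traj.n[-1], traj.m[-1]) == (0, 0)

    def test_absorbing_start(self, small_params):
        traj = ssa_constant(small_params, 1.3, init=(0, 0), seed=1)
        assert traj.extinct and traj.final_time == 0.0

    def test_persisters_alone_not_absorbing(self, small_params):
        traj = ssa_constant(small_params, 1.3, init=(0, 5), seed=2, t_max=1e5)
        assert traj.extinct and traj.final_time > 0.0


class TestUnitRateExponential:
    def test_pure_death_mean_extinction(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            p = ModelParams(B_ref=0.0, K=10, alpha=0.0, beta=0.0)
            ens = run_ensemble(
                p, EnvironmentSpec.constant(0.0), 10000, seed=3,
                init=(1, 0), t_max=200.0,
            )
        se = ens.escape_times.std(ddof=1) / math.sqrt(ens.escape_times.size)
        assert abs(ens.escape_times.mean() - 1.0) < 3 * se


class TestSharedVariateProtocol:
    def test_constant_B_bitwise_equivalence(self, small_params):
        """The time-inhomogeneous sampler degenerates to the plain Gillespie
        sampler draw-for-draw when B(t) is constant."""
        a = ssa_constant(small_params, 1.3, init=(8, 3), seed=42, t_max=1e5)
        b = ssa_time_dependent(
            small_params, EnvironmentSpec.constant(1.3),
            init=(8, 3), seed=42, t_max=1e5,
        )
        assert np.array_equal(a.times, b.times)
        assert np.array_equal(a.n, b.n)
        assert np.array_equal(a.m, b.m)


def _escape_times(runner, params, env, n, seed, **kw):
    ens = run_ensemble(params, env, n, seed=seed, t_max=1e6, method=runner, **kw)
    assert ens.n_censored == 0
    return ens.escape_times


class TestEqualityInLaw:
    """Degenerate environments must reproduce the constant-B law."""

    def test_dmn_with_equal_levels(self, small_params):
        env = EnvironmentSpec.sdmn(1.3, 1.3, nu=0.05)
        t_dmn = _escape_times("dmn", small_params, env, 2000, 10, init=(8, 3))
        t_const = _escape_times(
            "constant", small_params, EnvironmentSpec.constant(1.3), 2000, 11,
            init=(8, 3),
        )
        assert ks_2samp(t_dmn, t_const).pvalue > 0.01

    def test_sinusoid_with_zero_amplitude(self, small_params):
        env = EnvironmentSpec.sinusoidal(B0=1.3, epsilon=0.0, omega=0.1)
        t_sin = _escape_times("time_dependent", small_params, env, 2000, 12, init=(8, 3))
        t_const = _escape_times(
            "constant", small_params, EnvironmentSpec.constant(1.3), 2000, 13,
            init=(8, 3),
        )
        assert ks_2samp(t_sin, t_const).pvalue > 0.01

    def test_square_wave_with_equal_levels(self, small_params):
        env = EnvironmentSpec.square(1.3, 1.3, nu=0.05)
        t_sq = _escape_times("next_reaction", small_params, env, 2000, 14, init=(8, 3))
        t_const = _escape_times(
            "constant", small_params, EnvironmentSpec.constant(1.3), 2000, 15,
            init=(8, 3),
        )
        assert ks_2samp(t_sq, t_const).pvalue > 0.01

    def test_next_reaction_matches_hazard_inversion(self, small_params):
        """Cross-implementation check: Anderson clocks vs cumulative-hazard
        inversion on the same square wave."""
        env = EnvironmentSpec.square(1.5, 1.1, nu=0.02, phase=0.0)
        t_nr = _escape_times("next_reaction", small_params, env, 2000, 16, init=(8, 3))
        t_td = _escape_times("time_dependent", small_params, env, 2000, 17, init=(8, 3))
        assert ks_2samp(t_nr, t_td).pvalue > 0.01


class TestDMNOccupancy:
    def test_environment_occupancy_matches_duty_cycle(self):
        """Fraction of environment-flip events consistent with gamma."""
        # long-lived population (K=100, B- well above 1) so the trajectory
        # spans many environment cycles before extinction
        p = ModelParams(B_ref=1.4, K=100, alpha=0.05, beta=0.05)
        env = EnvironmentSpec.admn(1.5, 1.3, nu_plus=0.3, nu_minus=0.1)
        traj = ssa_dmn(p, env, init=(35, 15), seed=21, t_max=2e4, zeta0=1)
        times = np.concatenate([[0.0], traj.times])
        z = np.concatenate([[1], traj.zeta])
        dt = np.diff(np.concatenate([times, [traj.final_time]]))
        frac = float(dt[z > 0].sum() / dt.sum())
        n_switches = int(np.sum(np.diff(z) != 0))
        assert n_switches > 500
        se = math.sqrt(env.gamma * (1 - env.gamma) / n_switches) * 2
        assert abs(frac - env.gamma) < 3 * se


class TestRunEnsemble:
    def test_bitwise_reproducibility(self, small_params):
        a = run_ensemble(small_params, EnvironmentSpec.constant(1.3), 3, seed=9)
        b = run_ensemble(small_params, EnvironmentSpec.constant(1.3), 3, seed=9)
        assert np.array_equal(a.escape_times, b.escape_times)
        assert np.array_equal(a.seeds, b.seeds)

    def test_censoring_reported(self, small_params):
        with pytest.warns(UserWarning, match="censored"):
            ens = run_ensemble(
                small_params, EnvironmentSpec.constant(1.3), 10, seed=30,
                t_max=1.0,
            )
        assert ens.n_censored + ens.escape_times.size == 10

    def test_mock_exponential_ensemble_mean(self, rng):
        """Ensemble-mean machinery against the analytic exponential mean."""
        lam = 0.25
        times = rng.exponential(1 / lam, size=4000)
        se = times.std(ddof=1) / math.sqrt(times.size)
        assert abs(times.mean() - 1 / lam) < 3 * se


class TestSwitchingRateTrends:
    def test_mte_increases_with_alpha_and_decreases_with_beta(self):
        """More switching into the protected persister state delays
        extinction exponentially; faster reversion accelerates it."""
        base = dict(B_ref=1.3, K=30)
        mtes_a = []
        for alpha in (0.05, 0.1, 0.2):
            p = ModelParams(alpha=alpha, beta=0.1, **base)
            ens = run_ensemble(p, EnvironmentSpec.constant(1.3), 1200, seed=31,
                               init=(10, 5), t_max=1e7)
            mtes_a.append(ens.escape_times.mean())
        assert mtes_a[0] < mtes_a[1] < mtes_a[2]
        mtes_b = []
        for beta in (0.05, 0.1, 0.2):
            p = ModelParams(alpha=0.1, beta=beta, **base)
            ens = run_ensemble(p, EnvironmentSpec.constant(1.3), 1200, seed=32,
                               init=(10, 5), t_max=1e7)
            mtes_b.append(ens.escape_times.mean())
        assert mtes_b[0] > mtes_b[1] > mtes_b[2]


class TestRunnerValidation:
    def test_next_reaction_rejects_wrong_kind(self, small_params):
        with pytest.raises(ValueError):
            ssa_next_reaction(small_params, EnvironmentSpec.constant(1.3))

    def test_dmn_rejects_wrong_kind(self, small_params):
        with pytest.raises(ValueError):
            ssa_dmn(small_params, EnvironmentSpec.constant(1.3))

    def test_sinusoid_rejects_negative_swing(self, small_params):
        with pytest.warns(UserWarning):
            env = EnvironmentSpec.sinusoidal(B0=0.5, epsilon=0.8, omega=1.0)
        with pytest.raises(ValueError, match="epsilon <= B0"):
            ssa_time_dependent(small_params, env)
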