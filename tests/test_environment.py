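import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from persistext.environment import (
    EnvironmentSpec,
    average_birth_rate,
    birth_rate_at,
    dmn_to_sinusoid_params,
    sample_dmn_path,
    zeta_rect,
)


class TestSpecValidation:
    def test_duty_cycle_statistics(self):
        env = EnvironmentSpec.admn(1.5, 1.1, nu_plus=0.25, nu_minus=0.75)
        assert env.gamma == pytest.approx(0.75)
        assert env.Delta == pytest.approx(0.5)
        assert env.nu == pytest.approx(0.5)
        assert env.period == pytest.approx(4 + 4 / 3)

    def test_from_duty_cycle_inverts_gamma(self):
        env = EnvironmentSpec.from_duty_cycle(1.3, 0.0, nu=0.01, gamma=0.3)
        assert env.gamma == pytest.approx(0.3)
        assert env.nu == pytest.approx(0.01)

    def test_ordering_enforced(self):
        with pytest.raises(ValueError, match="B_minus <= B_plus"):
            EnvironmentSpec.sdmn(1.0, 1.5, nu=0.1)

    def test_negative_swing_warns(self):
        with pytest.warns(UserWarning, match="epsilon > B0"):
            EnvironmentSpec.sinusoidal(B0=0.1, epsilon=0.5, omega=1.0)

    def test_round_trip_dict(self):
        env = EnvironmentSpec.sinusoidal(B0=1.1, epsilon=0.05, omega=0.01, phase=0.3)
        assert EnvironmentSpec.from_dict(env.to_dict()) == env


class TestZetaRect:
    def test_square_wave_matches_sign_of_sine(self):
        env = EnvironmentSpec.square(1.5, 1.1, nu=1.0, phase=0.0)
        assert zeta_rect(0.5, env) == 1  # sign(sin(pi/2))
        assert zeta_rect(1.5, env) == -1  # sign(sin(3pi/2))
        for t in np.linspace(0.01, 7.99, 211):
            s = math.sin(math.pi * t)
            if abs(s) > 1e-9:
                assert zeta_rect(t, env) == (1 if s > 0 else -1)

    def test_edges_evaluate_to_zero(self):
        env = EnvironmentSpec.square(1.5, 1.1, nu=1.0, phase=0.0)
        assert zeta_rect(0.0, env) == 0
        assert zeta_rect(1.0, env) == 0

    def test_duty_cycle_fraction(self):
        env = EnvironmentSpec.rectangular(1.5, 1.1, nu_plus=0.25, nu_minus=0.75, phase=0.0)
        t = np.linspace(0, env.period, 40001)[:-1]
        frac = np.mean([zeta_rect(ti, env) > 0 for ti in t])
        assert frac == pytest.approx(env.gamma, abs=2e-3)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        nu_p=st.floats(0.05, 2.0),
        nu_m=st.floats(0.05, 2.0),
        # keep t away from representability extremes: adding one period to a
        # subnormal t rounds onto the interval edge, a measure-zero artifact
        t=st.floats(-30.0, 30.0).map(lambda x: round(x, 6)),
    )
    def test_periodicity_and_mean(self, nu_p, nu_m, t):
        env = EnvironmentSpec.rectangular(1.5, 1.1, nu_plus=nu_p, nu_minus=nu_m, phase=0.0)
        T = env.period
        assert zeta_rect(t, env) == zeta_rect(t + T, env)
        # time average over one period equals 2*gamma - 1
        ts = np.linspace(0, T, 2000, endpoint=False) + T / 4000
        avg = np.mean([zeta_rect(x, env) for x in ts])
        assert avg == pytest.approx(2 * env.gamma - 1, abs=5e-3)

    def test_wrong_kind_signalled(self):
        with pytest.raises(ValueError):
            zeta_rect(0.0, EnvironmentSpec.constant(1.1))


class TestBirthRateAt:
    def test_dmn_levels(self):
        env = EnvironmentSpec.sdmn(1.5, 1.1, nu=0.003)
        assert birth_rate_at(0.0, env, zeta=1) == pytest.approx(1.5)
        assert birth_rate_at(0.0, env, zeta=-1) == pytest.approx(1.1)

    def test_sinusoid_values(self):
        env = EnvironmentSpec.sinusoidal(B0=1.3, epsilon=0.2, omega=1.0, phase=0.0)
        assert birth_rate_at(0.0, env) == pytest.approx(1.3)
        assert birth_rate_at(math.pi / 2, env) == pytest.approx(1.5)

    def test_never_negative(self):
        with pytest.warns(UserWarning):
            env = EnvironmentSpec.sinusoidal(B0=0.1, epsilon=1.0, omega=1.0, phase=0.0)
        with pytest.warns(UserWarning, match="clipped"):
            val = birth_rate_at(3 * math.pi / 2, env)
        assert val == 0.0


class TestDMNPathStatistics:
    def test_stationary_mean_is_asymmetry(self):
        env = EnvironmentSpec.admn(1.5, 1.1, nu_plus=0.003, nu_minus=0.005)
        path = sample_dmn_path(env, 1e6, rng=1)
        mean = 2 * path.occupancy_plus() - 1
        # s.e. of the time average of an exponentially correlated +-1 signal
        se = math.sqrt((1 - env.Delta**2) / (env.nu * 1e6))
        assert abs(mean - env.Delta) < 3 * se

    def test_autocovariance_decay_rate(self):
        env = EnvironmentSpec.sdmn(1.5, 1.1, nu=0.01)
        path = sample_dmn_path(env, 1e6, rng=2)
        dt = 5.0
        grid = np.arange(0.0, 1e6, dt)
        idx = np.searchsorted(path.switch_times, grid, side="right") - 1
        z = path.zeta[idx].astype(float)
        z -= z.mean()
        lags = np.arange(1, 21)
        acf = np.array([np.mean(z[:-k] * z[k:]) for k in lags]) / np.mean(z * z)
        mask = acf > 0.05
        slope = np.polyfit(lags[mask] * dt, np.log(acf[mask]), 1)[0]
        assert -slope == pytest.approx(2 * env.nu, rel=0.1)

    def test_symmetric_holding_times(self):
        env = EnvironmentSpec.sdmn(1.5, 1.1, nu=0.02)
        path = sample_dmn_path(env, 5e5, rng=3)
        holds = np.diff(path.switch_times)
        se = holds.std(ddof=1) / math.sqrt(holds.size)
        assert abs(holds.mean() - 50.0) < 3 * se

    def test_reproducible_under_seed(self):
        env = EnvironmentSpec.sdmn(1.5, 1.1, nu=0.01)
        a = sample_dmn_path(env, 1e4, rng=11)
        b = sample_dmn_path(env, 1e4, rng=11)
        assert np.array_equal(a.switch_times, b.switch_times)
        assert np.array_equal(a.zeta, b.zeta)

    def test_invalid_horizon(self):
        with pytest.raises(ValueError):
            sample_dmn_path(EnvironmentSpec.sdmn(1.5, 1.1, 0.01), -1.0)


class TestParameterMappings:
    def test_dmn_to_sinusoid(self):
        env = EnvironmentSpec.sdmn(1.15, 1.05, nu=0.003)
        omega, B0, eps = dmn_to_sinusoid_params(env)
        assert omega == pytest.approx(0.003 * math.pi)
        assert B0 == pytest.approx(1.1)
        assert eps == pytest.approx(0.05)

    def test_degenerate_amplitude(self):
        env = EnvironmentSpec.sdmn(1.2, 1.2, nu=0.01)
        assert dmn_to_sinusoid_params(env)[2] == 0.0

    @pytest.mark.parametrize(
        "gamma,Bp,Bm,expected",
        [(0.1, 2.0, 0.95, 1.055), (0.5, 1.15, 1.05, 1.1)],
    )
    def test_average_birth_rate(self, gamma, Bp, Bm, expected):
        env = EnvironmentSpec.from_duty_cycle(Bp, Bm, nu=0.01, gamma=gamma)
        assert average_birth_rate(env) == pytest.approx(expected)

    def test_full_duty_cycle_limit(self):
        env = EnvironmentSpec.from_duty_cycle(1.3, 0.9, nu=0.01, gamma=0.999)
        assert average_birth_rate(env) == pytest.approx(1.3, abs=5e-4)
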