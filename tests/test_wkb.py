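import math

import numpy as np
import pytest

from persistext.model_core import ModelParams, mean_field_rhs
from persistext.wkb import (
    InstantonPath,
    PhasePointMomentum,
    PhasePointReal,
    action_along_path,
    alpha_zero_action,
    eom_momentum,
    eom_real,
    hamiltonian_momentum,
    hamiltonian_real,
    momentum_fixed_points,
    momentum_to_real,
    real_to_momentum,
    solve_instanton,
)

B = 1.1


def _params(alpha=0.02, beta=0.02, B_ref=B, K=500):
    return ModelParams(B_ref=B_ref, K=K, alpha=alpha, beta=beta)


def _random_points(n=60, scale=0.3, seed=7):
    rng = np.random.default_rng(seed)
    pts = rng.uniform(-scale, scale, size=(n, 4))
    pts[:, 0] = np.abs(pts[:, 0])  # x >= 0
    pts[:, 1] = np.abs(pts[:, 1])
    return pts


class TestHamiltonianReal:
    def test_zero_on_empty_population(self):
        assert hamiltonian_real((0, 0, 0.7, -0.3), B, _params()) == 0.0

    def test_zero_at_viable_fixed_point(self):
        p = _params()
        x = 1 - 1 / B
        assert hamiltonian_real((x, p.Gamma * x, 0, 0), B, p) == pytest.approx(0.0)

    def test_zero_at_fluctuational_extinction_point(self):
        val = hamiltonian_real((0, 0, -math.log(B), -math.log(B)), B, _params())
        assert val == pytest.approx(0.0, abs=1e-15)

    def test_momentum_guard(self):
        with pytest.raises(OverflowError):
            hamiltonian_real((0.1, 0.1, 60.0, 0.0), B, _params())


class TestEOMReal:
    def test_vanishes_at_saddles(self):
        p = _params()
        x = 1 - 1 / B
        for pt in [(0, 0, 0, 0), (x, p.Gamma * x, 0, 0),
                   (0, 0, -math.log(B), -math.log(B))]:
            assert np.allclose(eom_real(pt, B, p), 0.0, atol=1e-12)

    def test_zero_momentum_reduces_to_mean_field(self):
        p = _params()
        x, y = 0.07, 0.04
        xdot, ydot, _, _ = eom_real((x, y, 0.0, 0.0), B, p)
        dn, dm = mean_field_rhs((x * p.K, y * p.K), B, p)
        assert xdot == pytest.approx(dn / p.K, rel=1e-12)
        assert ydot == pytest.approx(dm / p.K, rel=1e-12)

    def test_matches_finite_difference_gradients(self):
        p = _params()
        h = 1e-6
        for pt in _random_points(20):
            x, y, px, py = pt
            flow = eom_real(pt, B, p)
            grads = []
            for i in range(4):
                e = np.zeros(4)
                e[i] = h
                grads.append(
                    (hamiltonian_real(pt + e, B, p) - hamiltonian_real(pt - e, B, p))
                    / (2 * h)
                )
            expected = (grads[2], grads[3], -grads[0], -grads[1])
            assert np.allclose(flow, expected, atol=1e-6)


class TestHamiltonianMomentum:
    def test_deterministic_manifold_is_zero_energy(self):
        assert hamiltonian_momentum((0.3, 0.2, 0.0, 0.0), B, _params()) == 0.0

    def test_zero_at_extinction_saddle(self):
        pE = (1 - B) / B
        assert hamiltonian_momentum((0, 0, pE, pE), B, _params()) == pytest.approx(0.0)

    def test_agrees_with_real_space_under_map(self):
        p = _params()
        for pt in _random_points(100, scale=0.25, seed=13):
            real = PhasePointReal(*pt)
            mom = real_to_momentum(real)
            assert hamiltonian_momentum(tuple(mom), B, p) == pytest.approx(
                hamiltonian_real(tuple(real), B, p), abs=1e-12
            )

    def test_map_round_trip(self):
        pt = PhasePointReal(0.12, 0.08, -0.05, 0.03)
        back = momentum_to_real(real_to_momentum(pt))
        assert np.allclose(list(back), list(pt), atol=1e-14)


class TestEOMMomentum:
    def test_vanishes_at_fixed_points(self):
        p = _params()
        for fp in momentum_fixed_points(B, p):
            assert np.allclose(eom_momentum(tuple(fp), B, p), 0.0, atol=1e-14)

    def test_matches_finite_difference_gradients(self):
        p = _params()
        h = 1e-6
        for pt in _random_points(20, seed=17):
            flow = eom_momentum(pt, B, p)
            grads = []
            for i in range(4):
                e = np.zeros(4)
                e[i] = h
                grads.append(
                    (hamiltonian_momentum(pt + e, B, p)
                     - hamiltonian_momentum(pt - e, B, p)) / (2 * h)
                )
            expected = (grads[2], grads[3], -grads[0], -grads[1])
            assert np.allclose(flow, expected, atol=1e-6)

    def test_pushforward_of_real_flow(self):
        """Chain rule: d/dt of the variable map applied to the real-space
        flow reproduces the momentum-space flow."""
        p = _params()
        for pt in _random_points(20, scale=0.2, seed=23):
            x, y, px, py = pt
            xd, yd, pxd, pyd = eom_real(pt, B, p)
            q1d = (xd - x * pxd) * math.exp(-px)
            q2d = (yd - y * pyd) * math.exp(-py)
            p1d = math.exp(px) * pxd
            p2d = math.exp(py) * pyd
            mom = real_to_momentum(PhasePointReal(*pt))
            flow = eom_momentum(tuple(mom), B, p)
            assert np.allclose(flow, (q1d, q2d, p1d, p2d), rtol=1e-9, atol=1e-12)


class TestInstanton:
    def test_alpha_zero_matches_quadrature_oracle(self):
        p = _params(alpha=0.0)
        path = solve_instanton(p, B=B)
        oracle = alpha_zero_action(B)
        assert path.action == pytest.approx(oracle, rel=0.01)
        # closed form of the same integral
        assert oracle == pytest.approx(math.log(B) - 1 + 1 / B, rel=1e-6)

    def test_heteroclinic_boundary_conditions(self, std_instanton):
        res_start, res_end = std_instanton.boundary_residuals()
        assert res_start < 1e-4
        assert res_end < 1e-4

    def test_energy_conservation(self, std_instanton):
        assert std_instanton.energy_max < 1e-6

    def test_action_grid_convergence(self, std_params, std_instanton):
        """Doubling the resolution changes the action by < 0.1%."""
        fine = solve_instanton(std_params, B=B, n_nodes=16001)
        assert fine.action == pytest.approx(std_instanton.action, rel=1e-3)

    def test_action_positive_and_vanishing_at_bifurcation(self):
        actions = []
        for Bi in (1.02, 1.05, 1.1):
            p = _params(B_ref=Bi)
            actions.append(solve_instanton(p, B=Bi).action)
        assert all(S > 0 for S in actions)
        assert actions[0] < actions[1] < actions[2]
        assert actions[0] < 5e-4

    def test_approach_to_near_bifurcation_closed_form(self):
        """S -> delta^2 (1/2 + Gamma) as the switching slows (beta << delta)."""
        target = 0.05**2 * 1.5
        ratios = []
        for ab in (0.02, 0.005, 0.001):
            p = _params(alpha=ab, beta=ab, B_ref=1.05)
            ratios.append(solve_instanton(p, B=1.05).action / target)
        assert ratios[0] < ratios[1] < ratios[2] < 1.0

    def test_requires_supercritical_B(self):
        with pytest.raises(ValueError):
            solve_instanton(_params(), B=0.9)

    def test_action_of_stationary_path_is_zero(self, std_params):
        _, FM, _ = momentum_fixed_points(B, std_params)
        t = np.linspace(-10, 10, 101)
        q = np.tile(np.array([[FM.q1], [FM.q2]]), (1, t.size))
        p = np.zeros((2, t.size))
        path = InstantonPath(
            t=t, q=q, p=p, action=math.nan, iterations=0, residual=0.0,
            converged=True, B=B, params=std_params,
        )
        assert action_along_path(path) == pytest.approx(0.0, abs=1e-14)
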