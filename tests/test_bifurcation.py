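"""Steady states, stability classification, continuation and fold location.

Independent oracles used here:

* the islet Z level solves z^2 (1 - z) = 1/s, a scalar root found by brentq;
* the homogeneous acinar existence boundary solves q = b y^5 (1 - y) (with
  n = 3 and negligible A, X, Z corrections), whose fold is the closed form
  b = q / max_y[y^5 (1 - y)] = q * 6^6 / 5^5;
* a 4-dimensional homogeneous-reduction Newton solver with finite-difference
  Jacobian, independent of the package's analytic coupled Jacobian.
"""

import numpy as np
import pytest
from scipy.optimize import brentq

from pancfate.bifurcation import (
    acinar_guess,
    continue_branch,
    coupled_jacobian,
    coupled_rhs,
    critical_inhibition,
    critical_stabilization,
    directional_stability,
    find_fixed_point,
    find_fold,
    islet_guess,
    mixed_guess,
    probe_directional_stability,
    progenitor_guess,
)
from pancfate.integrate import IntegrationConfig, simulate
from pancfate.model import ModelParams, classify_fate, rhs
from pancfate.tissue import from_edge_list, make_triangle3

# closed-form fold of q = b y^5 (1-y): maximum of y^5(1-y) is at y=5/6
B_FOLD_HOMOGENEOUS = 1e-4 * 6**6 / 5**5  # = 1.49299e-3
# an acinar cell stabilized by a single acinar neighbour sees Ybar = Y/2,
# which rescales the fold by 2^n = 8
B_FOLD_SINGLE_NEIGHBOR = 8 * B_FOLD_HOMOGENEOUS  # = 1.19439e-2


def homogeneous_fixed_point(guess, p, kx=1.0, ky=1.0, tol=1e-12):
    """Independent 4-D reduction oracle (finite-difference Newton)."""
    v = np.asarray(guess, float).copy()
    for _ in range(200):
        f = rhs(v, (kx * v[1], ky * v[2]), p)
        if np.max(np.abs(f)) < tol:
            return v
        J = np.empty((4, 4))
        for j in range(4):
            vp = v.copy()
            vp[j] += 1e-8
            J[:, j] = (rhs(vp, (kx * vp[1], ky * vp[2]), p) - f) / 1e-8
        v = v + np.linalg.solve(J, -f)
    return None


class TestFixedPoints:
    def test_three_coexisting_fate_configurations(self, p, triangle):
        for guess, target in [(acinar_guess(3), 3.0), (islet_guess(3), 0.0), (mixed_guess(), 2.0)]:
            fp = find_fixed_point(guess, triangle, p)
            assert fp.converged and fp.residual_norm < 1e-10
            assert fp.sum_y == pytest.approx(target, abs=0.05)
            assert fp.stable

    def test_islet_level_matches_scalar_root_oracle(self, p, triangle):
        fp = find_fixed_point(islet_guess(3), triangle, p)
        z_oracle = brentq(lambda z: z**2 * (1 - z) - 1.0 / p.s, 0.9, 0.999, xtol=1e-14)
        np.testing.assert_allclose(fp.states[:, 3], z_oracle, atol=1e-6)

    def test_newton_failure_is_a_result_not_an_exception(self, p, triangle):
        fp = find_fixed_point(np.full((3, 4), 0.4), triangle, p, max_iter=1)
        assert not fp.converged
        assert fp.eigenvalues is None

    def test_analytic_jacobian_matches_finite_differences(self, p, rng, triangle):
        graph = from_edge_list([(0, 1), (1, 2), (2, 3), (3, 0)], coordination=2)
        for tissue in (triangle, graph):
            x0 = rng.random(4 * tissue.n_cells)
            J = coupled_jacobian(x0, tissue, p)
            f0 = coupled_rhs(x0, tissue, p)
            Jfd = np.empty_like(J)
            eps = 1e-7
            for j in range(x0.size):
                xp = x0.copy()
                xp[j] += eps
                Jfd[:, j] = (coupled_rhs(xp, tissue, p) - f0) / eps
            np.testing.assert_allclose(J, Jfd, atol=5e-5)

    def test_homogeneous_branch_reduction(self, p, triangle):
        # homogeneous triangle fixed points coincide with the single-cell
        # system closed with Xbar=X, Ybar=Y
        fp = find_fixed_point(acinar_guess(3), triangle, p)
        reduced = homogeneous_fixed_point(acinar_guess(1)[0], p)
        for cell in fp.states:
            np.testing.assert_allclose(cell, reduced, atol=1e-8)


class TestDirectionalStability:
    def test_progenitor_saddle_is_y_stable_x_unstable(self, p, triangle):
        # below the critical stabilization the multipotent state resists Y
        # perturbations but noise on X can tip it
        fp = find_fixed_point(progenitor_guess(3), triangle, p.replace(b=0.0))
        assert not fp.stable
        d = directional_stability(fp)
        assert d["Y"] is True and d["X"] is False

    def test_stable_point_is_stable_in_every_direction(self, p, triangle):
        fp = find_fixed_point(acinar_guess(3), triangle, p)
        assert fp.stable
        assert all(directional_stability(fp).values())
        assert all(probe_directional_stability(fp, triangle, p).values())

    def test_probe_flags_the_unstable_x_direction(self, p, triangle):
        params = p.replace(b=0.0)
        fp = find_fixed_point(progenitor_guess(3), triangle, params)
        probe = probe_directional_stability(fp, triangle, params)
        assert probe["X"] is False

    def test_stable_points_reproduced_by_relaxation(self, p, triangle, rng):
        # simulation oracle: a small perturbation of a stable fixed point
        # relaxes back onto it
        cfg = IntegrationConfig(t_end=100.0, noise_on=False, record_every=10**6)
        for guess in (acinar_guess(3), islet_guess(3), mixed_guess()):
            fp = find_fixed_point(guess, triangle, p)
            init = np.clip(fp.states + 1e-3 * rng.standard_normal((3, 4)), 0, None)
            traj = simulate(triangle, init, p, cfg)
            assert np.max(np.abs(traj.final_states() - fp.states)) < 1e-5


class TestContinuationAndFolds:
    def test_acinar_branch_folds_at_homogeneous_boundary(self, p, triangle):
        start = find_fixed_point(acinar_guess(3), triangle, p)
        branch = continue_branch(start, triangle, p, "b", direction=-1, stop_value=1e-5)
        assert branch.terminus == "fold"
        assert np.all(np.abs(branch.sum_y - 3.0) < 0.6)  # Y*=5/6 each at the fold
        fold = find_fold(start, triangle, p, "b", (1e-4, 1.0), tol=1e-5)
        assert fold == pytest.approx(B_FOLD_HOMOGENEOUS, abs=5e-5)

    def test_single_neighbor_acinar_fold(self, p, triangle):
        start = find_fixed_point(mixed_guess(), triangle, p)
        fold = find_fold(start, triangle, p, "b", (1e-4, 1.0), tol=1e-5)
        assert fold == pytest.approx(B_FOLD_SINGLE_NEIGHBOR, rel=2e-3)

    def test_islet_branch_has_no_fold_in_b(self, p, triangle):
        start = find_fixed_point(islet_guess(3), triangle, p)
        branch = continue_branch(start, triangle, p, "b", direction=-1, stop_value=1e-4)
        assert branch.terminus == "boundary"
        assert np.all(branch.sum_y < 0.05)
        with pytest.raises(ValueError, match="no existence boundary"):
            find_fold(start, triangle, p, "b", (0.0, 2000.0))

    def test_progenitor_fold_matches_reduction_oracle(self, p, triangle):
        a_c = critical_inhibition(p, tol=1e-6)
        # independent oracle: bisection on existence of the homogeneous
        # 4-D reduction at b=0
        params = ModelParams(b=0.0)
        seed = homogeneous_fixed_point(progenitor_guess(1)[0], params)

        def exists(a):
            nonlocal seed
            sol = homogeneous_fixed_point(seed, params.replace(a=a))
            if sol is None or np.any(sol < -1e-9) or np.max(np.abs(sol - seed)) > 0.3:
                return False
            seed = sol
            return True

        hi, lo = 1e-2, 1e-4
        for a in np.geomspace(1000.0, hi, 30):  # walk the branch down to hi
            assert exists(a)
        for _ in range(40):
            mid = 0.5 * (hi + lo)
            if exists(mid):
                hi = mid
            else:
                lo = mid
        assert a_c == pytest.approx(0.5 * (hi + lo), abs=5e-5)

    def test_fold_consistency_just_above_and_below(self, p, triangle):
        # just above the homogeneous fold the all-acinar state exists and is
        # stable; just below, deterministic relaxation abandons the acinar fate
        above = p.replace(b=B_FOLD_HOMOGENEOUS * 1.05)
        fp = find_fixed_point(acinar_guess(3), triangle, above)
        assert fp.converged and fp.stable and classify_fate(fp.states[0]) == "acinar"
        below = p.replace(b=B_FOLD_HOMOGENEOUS * 0.95)
        cfg = IntegrationConfig(t_end=100.0, noise_on=False, record_every=10**6)
        traj = simulate(triangle, fp.states, below, cfg)
        assert all(f != "acinar" for f in classify_fate(traj.final_states()))

    def test_recovery_hysteresis_islet_branch_persists(self, p, triangle):
        # raising b back from 0 to 2000 never loses the islet state:
        # restored stabilization cannot reverse a completed conversion
        start = find_fixed_point(islet_guess(3), triangle, p.replace(b=1e-3))
        branch = continue_branch(start, triangle, p.replace(b=1e-3), "b",
                                 direction=+1, stop_value=2000.0)
        assert branch.terminus == "boundary"
        assert branch.parameter_values[-1] == 2000.0
        assert np.all(branch.sum_y < 0.05)
        assert all(fp.stable for _, fp in branch.points)
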