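"""Steady states, stability and fold detection of the deterministic system.

The coupled deterministic system on a small tissue (dimension 4 x n_cells)
is solved by Newton iteration with an analytic Jacobian, including the
coupling blocks through the neighbour averages Xbar and Ybar.  Stability is
read from the Jacobian spectrum at the converged point; a *directional*
stability notion assigns each eigenvalue to the state variable that
dominates its eigenvector, so a saddle can be reported as, say, stable
against perturbations in Y but unstable against perturbations in X.

Branches are traced by natural-parameter continuation with adaptive step
halving, and saddle-node (fold) locations are refined by bisection on the
*existence* of a branch-continuous solution: at a trial parameter value
Newton is seeded from the nearest accepted branch point and the solution
counts as present only if it converges, stays non-negative, and does not
jump away from the seed.

Two critical coupling strengths of the 3-cell minimal tissue are exposed
directly:

* ``critical_stabilization`` -- the lateral-stabilization strength below
  which the acinar fate can no longer be maintained.  The operative branch
  is the mixed configuration (two acinar cells, one islet cell), i.e. the
  fold of an acinar cell stabilized by a *single* acinar neighbour; the
  fully surrounded homogeneous branch persists to eightfold smaller values
  (``branch="acinar"``).
* ``critical_inhibition`` -- the lateral-inhibition strength at which the
  multipotent progenitor-like branch (with stabilization lost, b = 0)
  vanishes in a saddle-node bifurcation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .model import A, X, Y, Z, VAR_NAMES, ModelParams, rhs
from .tissue import Tissue, make_triangle3, neighbor_signals

__all__ = [
    "FixedPoint",
    "Branch",
    "coupled_rhs",
    "coupled_jacobian",
    "find_fixed_point",
    "directional_stability",
    "probe_directional_stability",
    "continue_branch",
    "find_fold",
    "critical_stabilization",
    "critical_inhibition",
    "acinar_guess",
    "islet_guess",
    "progenitor_guess",
    "mixed_guess",
]

_EIG_TOL = 1e-8  # real-part tolerance for stability calls (symmetry forces
# eigenvalue multiplicity at homogeneous points; never rely on ordering)


@dataclass
class FixedPoint:
    """A steady state of the coupled system with stability classification."""

    states: np.ndarray  # (n_cells, 4)
    residual_norm: float
    converged: bool
    jacobian: np.ndarray | None = None
    eigenvalues: np.ndarray | None = None
    eigenvectors: np.ndarray | None = None
    left_eigenvectors: np.ndarray | None = None
    n_iterations: int = 0

    @property
    def stable(self) -> bool:
        if self.eigenvalues is None:
            raise ValueError("fixed point has no spectrum (Newton did not converge)")
        return bool(np.max(self.eigenvalues.real) < _EIG_TOL)

    @property
    def sum_y(self) -> float:
        return float(self.states[:, Y].sum())

    @property
    def directional(self) -> dict:
        return directional_stability(self)


@dataclass
class Branch:
    """An ordered run of fixed points along one parameter.

    ``terminus`` is ``fold`` (continuation step fell below its minimum),
    ``boundary`` (parameter range exhausted) or ``max_steps``.
    """

    parameter_name: str
    points: list = field(default_factory=list)  # (param value, FixedPoint)
    terminus: str = "max_steps"

    @property
    def parameter_values(self) -> np.ndarray:
        return np.array([v for v, _ in self.points])

    @property
    def sum_y(self) -> np.ndarray:
        return np.array([fp.sum_y for _, fp in self.points])

    def to_frame(self):
        import pandas as pd

        rows = []
        for value, fp in self.points:
            row = {
                self.parameter_name: value,
                "sum_Y": fp.sum_y,
                "stable": fp.stable,
                "max_re_eig": float(np.max(fp.eigenvalues.real)),
            }
            for var, ok in directional_stability(fp).items():
                row[f"stable_{var}"] = ok
            rows.append(row)
        return pd.DataFrame(rows)


def coupled_rhs(flat: np.ndarray, tissue: Tissue, p: ModelParams) -> np.ndarray:
    """Drift of the full coupled system on a flat (4 n_cells,) vector."""
    states = np.asarray(flat, dtype=float).reshape(tissue.n_cells, 4)
    return rhs(states, neighbor_signals(tissue, states), p).ravel()


def coupled_jacobian(flat: np.ndarray, tissue: Tissue, p: ModelParams) -> np.ndarray:
    """Closed-form Jacobian of :func:`coupled_rhs`, coupling blocks included.

    The only inter-cell entries are d(dX_i/dt)/dX_j and d(dY_i/dt)/dY_j,
    weighted by the coupling matrix entry 1/coordination for each occupied
    neighbour j of i.
    """
    n_cells = tissue.n_cells
    st = np.asarray(flat, dtype=float).reshape(n_cells, 4)
    sig = neighbor_signals(tissue, st)
    n = p.n
    av, xv, yv, zv = st[:, A], st[:, X], st[:, Y], st[:, Z]
    xb, yb = sig[:, 0], sig[:, 1]

    def pw(v, k):  # v**k with integer k >= 0
        return v**k

    an = pw(av, n)
    xn = pw(xv, n)
    yn = pw(yv, n)
    zn = pw(zv, n)
    d_an = n * pw(av, n - 1)
    d_xn = n * pw(xv, n - 1)
    d_yn = n * pw(yv, n - 1)
    d_zn = n * pw(zv, n - 1)

    J = np.zeros((4 * n_cells, 4 * n_cells))
    W = tissue.coupling  # csr, entries 1/coordination

    DA = 1.0 + p.r * yn + p.r * zn
    DX = p.q + p.a * pw(xb, n)
    u = pw(yv * yb, n)
    du_dy = n * pw(yv * yb, n - 1) * yb
    du_dyb = n * pw(yv * yb, n - 1) * yv
    NY = p.q * an + p.b * u
    DY = p.q + p.b * u + p.c * xn + p.c * zn
    DZ = 1.0 + p.s * zn

    for i in range(n_cells):
        o = 4 * i
        # f_A = 1/DA - A
        J[o + A, o + A] = -1.0
        J[o + A, o + Y] = -p.r * d_yn[i] / DA[i] ** 2
        J[o + A, o + Z] = -p.r * d_zn[i] / DA[i] ** 2
        # f_X = q A^n / DX - X
        J[o + X, o + A] = p.q * d_an[i] / DX[i]
        J[o + X, o + X] = -1.0
        dfx_dxb = -p.q * an[i] * p.a * n * pw(xb[i], n - 1) / DX[i] ** 2
        # f_Y = NY/DY - Y
        J[o + Y, o + A] = p.q * d_an[i] / DY[i]
        J[o + Y, o + X] = -NY[i] * p.c * d_xn[i] / DY[i] ** 2
        J[o + Y, o + Z] = -NY[i] * p.c * d_zn[i] / DY[i] ** 2
        J[o + Y, o + Y] = p.b * du_dy[i] * (DY[i] - NY[i]) / DY[i] ** 2 - 1.0
        dfy_dyb = p.b * du_dyb[i] * (DY[i] - NY[i]) / DY[i] ** 2
        # f_Z = (X^n + s Z^n)/DZ - Z
        J[o + Z, o + X] = d_xn[i] / DZ[i]
        J[o + Z, o + Z] = p.s * d_zn[i] * (1.0 - xn[i]) / DZ[i] ** 2 - 1.0
        # coupling blocks through Xbar_i and Ybar_i
        row = W.getrow(i)
        for j, w in zip(row.indices, row.data):
            J[o + X, 4 * j + X] += dfx_dxb * w
            J[o + Y, 4 * j + Y] += dfy_dyb * w
    return J


def find_fixed_point(
    guess: np.ndarray,
    tissue: Tissue,
    p: ModelParams,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> FixedPoint:
    """Newton iteration on the coupled drift from ``guess``.

    Returns a :class:`FixedPoint` whose ``converged`` flag is False when the
    iteration cap is hit or the linear solve fails -- an explicit failure
    result, usable by the fold bisection, rather than an exception.
    """
    x = np.asarray(guess, dtype=float).reshape(tissue.n_cells, 4).ravel().copy()
    if not np.isfinite(x).all():
        raise ValueError("non-finite initial guess")
    res = coupled_rhs(x, tissue, p)
    for it in range(1, max_iter + 1):
        if np.max(np.abs(res)) < tol:
            break
        J = coupled_jacobian(x, tissue, p)
        try:
            step = np.linalg.solve(J, -res)
        except np.linalg.LinAlgError:
            return FixedPoint(x.reshape(-1, 4), float(np.max(np.abs(res))), False, n_iterations=it)
        x = x + step
        if not np.isfinite(x).all():
            return FixedPoint(x.reshape(-1, 4), np.inf, False, n_iterations=it)
        res = coupled_rhs(x, tissue, p)
    else:
        it = max_iter
    resid = float(np.max(np.abs(res)))
    if resid >= tol:
        return FixedPoint(x.reshape(-1, 4), resid, False, n_iterations=it)
    J = coupled_jacobian(x, tissue, p)
    eigvals, left, right = scipy.linalg.eig(J, left=True, right=True)
    return FixedPoint(
        states=x.reshape(-1, 4),
        residual_norm=resid,
        converged=True,
        jacobian=J,
        eigenvalues=eigvals,
        eigenvectors=right,
        left_eigenvectors=left,
        n_iterations=it,
    )


def directional_stability(fp: FixedPoint, tol: float = _EIG_TOL) -> dict:
    """Map each variable name to True (stable) / False (unstable).

    "Unstable with respect to perturbations in V" means that a perturbation
    applied to V projects onto a growing mode, so each eigenvalue is
    assigned to the variable carrying the largest absolute *left*
    eigenvector loading (summed over cells) -- the left eigenvector is the
    functional that measures how strongly a perturbation excites the mode.
    A variable is unstable iff any of its assigned eigenvalues has real
    part above ``tol``; at a stable fixed point every variable is stable.
    """
    if fp.eigenvalues is None or fp.left_eigenvectors is None:
        raise ValueError("fixed point has no eigen-decomposition")
    n_cells = fp.states.shape[0]
    result = {name: True for name in VAR_NAMES}
    for lam, vec in zip(fp.eigenvalues, fp.left_eigenvectors.T):
        loading = np.abs(vec.reshape(n_cells, 4)).sum(axis=0)
        var = VAR_NAMES[int(np.argmax(loading))]
        if lam.real > tol:
            result[var] = False
    return result


def probe_directional_stability(
    fp: FixedPoint,
    tissue: Tissue,
    p: ModelParams,
    delta: float = 1e-3,
    t_probe: float = 20.0,
    dt: float = 0.02,
) -> dict:
    """Fallback stability probe by deterministic integration.

    Perturbs one cell of the fixed point by ``+delta`` in one variable
    (a single-cell kick also excites symmetry-breaking modes) and
    integrates without noise: the variable counts as stable when the state
    stays within ``10 * delta`` of the fixed point over the probe window.
    Independent of the eigen-decomposition, this guards against
    misassignment when eigenvectors mix variables or the eigenbasis is
    ill-conditioned; for a saddle whose unstable mode has a tiny but
    nonzero projection on a variable, long probe windows will eventually
    report departure, so the window is kept short.
    """
    from .integrate import IntegrationConfig, simulate

    cfg = IntegrationConfig(dt=dt, t_end=t_probe, noise_on=False, record_every=10**9)
    result = {}
    for k, name in enumerate(VAR_NAMES):
        init = fp.states.copy()
        init[0, k] += delta
        traj = simulate(tissue, init, p, cfg)
        err = np.max(np.abs(traj.final_states() - fp.states))
        result[name] = bool(err < 10 * delta)
    return result


def _accepts(seed_states, tissue, p, tol, max_jump):
    fp = find_fixed_point(seed_states, tissue, p, tol=tol)
    if not fp.converged:
        return None
    if np.any(fp.states < -1e-9):
        return None
    if np.max(np.abs(fp.states - seed_states)) > max_jump:
        return None
    return fp


def continue_branch(
    start: FixedPoint,
    tissue: Tissue,
    p: ModelParams,
    parameter_name: str,
    start_value: float | None = None,
    direction: int = -1,
    stop_value: float | None = None,
    rel_step: float = 0.2,
    min_rel_step: float = 1e-6,
    max_jump: float = 0.3,
    max_steps: int = 500,
    tol: float = 1e-10,
) -> Branch:
    """Natural-parameter continuation of ``start`` in one parameter.

    Steps are geometric (the couplings span decades); on Newton failure or
    a solution jump the step is halved, and the branch terminates with
    ``terminus='fold'`` once the relative step falls below ``min_rel_step``.
    ``stop_value`` bounds the sweep (``terminus='boundary'``).
    """
    if not start.converged:
        raise ValueError("continuation must start from a converged fixed point")
    value = float(getattr(p, parameter_name) if start_value is None else start_value)
    if value <= 0:
        raise ValueError("continuation requires a positive starting parameter value")
    if stop_value is None:
        stop_value = value * 1e-6 if direction < 0 else value * 1e6
    branch = Branch(parameter_name=parameter_name)
    fp = _accepts(start.states, tissue, p.replace(**{parameter_name: value}), tol, max_jump)
    if fp is None:
        raise ValueError("starting fixed point does not exist at the starting parameter value")
    branch.points.append((value, fp))
    step = rel_step
    for _ in range(max_steps):
        factor = (1.0 - step) if direction < 0 else 1.0 / (1.0 - step)
        new_value = value * factor
        bounded = (new_value <= stop_value) if direction < 0 else (new_value >= stop_value)
        if bounded:
            new_value = stop_value
        cand = _accepts(fp.states, tissue, p.replace(**{parameter_name: new_value}), tol, max_jump)
        if cand is not None:
            value, fp = new_value, cand
            branch.points.append((value, fp))
            if bounded:
                branch.terminus = "boundary"
                return branch
            step = min(rel_step, step * 2)
        else:
            step /= 2
            if step < min_rel_step:
                branch.terminus = "fold"
                return branch
    branch.terminus = "max_steps"
    return branch


def find_fold(
    branch_seed: FixedPoint,
    tissue: Tissue,
    p: ModelParams,
    parameter_name: str,
    bracket: tuple,
    tol: float = 1e-4,
    newton_tol: float = 1e-10,
    max_jump: float = 0.3,
) -> float:
    """Critical parameter value where the branch ceases to exist.

    The branch must exist at the high end of ``bracket`` and not at the low
    end.  An initial geometric scan walks the solution down from the high
    end; once a failing value is found, plain bisection on "does Newton,
    seeded from the nearest accepted branch point, converge to a
    branch-continuous solution" refines the boundary to width ``tol``.
    Returns the midpoint of the final bracket.
    """
    lo, hi = (float(b) for b in bracket)
    if not 0 <= lo < hi:
        raise ValueError("bracket must satisfy 0 <= lo < hi")
    # walk the seed to the high end in gentle geometric steps
    seed = branch_seed.states
    start_val = float(getattr(p, parameter_name))
    if start_val <= 0:
        start_val = hi
    for val in np.geomspace(start_val, hi, 8)[1:] if start_val != hi else [hi]:
        fp = _accepts(seed, tissue, p.replace(**{parameter_name: val}), newton_tol, max_jump)
        if fp is None:
            raise ValueError(f"branch does not exist at the high end {hi}")
        seed = fp.states
    # geometric scan downward to find a failing value
    value = hi
    fail = None
    floor = max(lo, tol * 0.25)
    while value > floor * 1.0000001:
        trial = max(value / 2.0, floor)
        fp = _accepts(seed, tissue, p.replace(**{parameter_name: trial}), newton_tol, max_jump)
        if fp is None:
            fail = trial
            break
        seed, value = fp.states, trial
    if fail is None:
        # scan reached the floor with the branch intact; test the low end itself
        fp = _accepts(seed, tissue, p.replace(**{parameter_name: lo}), newton_tol, max_jump)
        if fp is not None:
            raise ValueError("no existence boundary inside the bracket: branch persists at the low end")
        fail = lo
    good, bad = value, fail
    while good - bad > tol:
        mid = 0.5 * (good + bad)
        fp = _accepts(seed, tissue, p.replace(**{parameter_name: mid}), newton_tol, max_jump)
        if fp is None:
            bad = mid
        else:
            good, seed = mid, fp.states
    return 0.5 * (good + bad)


# -- canned initial guesses on small tissues --------------------------------

_ISLET_Z = 0.97880  # root of z^2 (1 - z) = 1/s near 1 for s = 50


def acinar_guess(n_cells: int) -> np.ndarray:
    """All cells acinar-like (Y near 1)."""
    g = np.zeros((n_cells, 4))
    g[:, A] = 0.01
    g[:, Y] = 1.0
    return g


def islet_guess(n_cells: int) -> np.ndarray:
    """All cells islet-like (Z near 1)."""
    g = np.zeros((n_cells, 4))
    g[:, A] = 0.01
    g[:, Z] = _ISLET_Z
    return g


def progenitor_guess(n_cells: int) -> np.ndarray:
    """Multipotent-like: high A, low promiscuous X and Y."""
    g = np.zeros((n_cells, 4))
    g[:, A] = 1.0
    g[:, X] = 0.02
    g[:, Y] = 0.03
    return g


def mixed_guess() -> np.ndarray:
    """Triangle configuration with two acinar cells and one islet cell."""
    g = acinar_guess(3)
    g[2] = islet_guess(1)[0]
    return g


def critical_stabilization(
    p: ModelParams | None = None,
    branch: str = "mixed",
    bracket: tuple = (1e-4, 1.0),
    tol: float = 1e-4,
) -> float:
    """Critical lateral-stabilization strength b_c of the 3-cell tissue.

    ``branch="mixed"`` (default) locates the fold of the configuration in
    which an acinar cell keeps only one acinar neighbour -- the point below
    which the acinar fate can no longer be maintained anywhere in the
    minimal tissue.  ``branch="acinar"`` instead follows the homogeneous
    all-acinar state, which is stabilized by both neighbours and persists
    to values smaller by a factor 2**n.
    """
    p = default_if_none(p)
    tissue = make_triangle3()
    guess = mixed_guess() if branch == "mixed" else acinar_guess(3)
    start = find_fixed_point(guess, tissue, p)
    if not start.converged:
        raise RuntimeError("could not converge the seeding fixed point")
    return find_fold(start, tissue, p, "b", bracket, tol=tol)


def critical_inhibition(
    p: ModelParams | None = None,
    bracket: tuple = (1e-4, 1.0),
    tol: float = 1e-5,
) -> float:
    """Critical lateral-inhibition strength a_c of the 3-cell tissue.

    Computed with stabilization lost (b = 0): the homogeneous multipotent
    progenitor-like state is converged at strong inhibition and continued
    downward in a until it vanishes in a saddle-node bifurcation (the
    colliding partner branch carries higher Z activity).
    """
    p = default_if_none(p).replace(b=0.0)
    tissue = make_triangle3()
    start = find_fixed_point(progenitor_guess(3), tissue, p)
    if not start.converged:
        raise RuntimeError("could not converge the progenitor fixed point")
    return find_fold(start, tissue, p, "a", bracket, tol=tol)


def default_if_none(p: ModelParams | None) -> ModelParams:
    return ModelParams() if p is None else p
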