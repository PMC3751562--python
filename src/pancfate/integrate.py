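"""Stochastic time stepping of the coupled cell system.

The coupled stochastic equations carry additive Gaussian white noise on the
X and Y components only, with amplitudes ``eta_x`` and ``eta_y``.  They are
integrated with the second-order Heun-Maruyama scheme at a fixed step
(default ``dt = 0.02``):

    predictor   s* = s + f(s) dt + g dW
    corrector   s' = s + (f(s) + f(s*)) dt / 2 + g dW

with the *same* Wiener increment ``dW = sqrt(dt) N(0, 1)`` in both stages
(fresh draws would break the convergence order) and neighbour signals
recomputed from the predictor state for the corrector drift.  The noise is
additive, so the Ito and Stratonovich readings coincide and the corrector
is unambiguous.

States are clamped at zero after every update: expression levels are
non-negative, and with noise amplitudes of 1e-3 the clamp is a guard
against tiny negative excursions, not a driver of the dynamics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import VAR_NAMES, X, Y, ModelParams, classify_fate, rhs
from .tissue import Tissue, neighbor_signals

__all__ = [
    "IntegrationConfig",
    "Trajectory",
    "heun_update",
    "heun_maruyama_step",
    "simulate",
    "population_average",
    "islet_fraction",
    "time_to_fraction",
]


@dataclass(frozen=True)
class IntegrationConfig:
    """Time-stepping settings.

    ``record_every`` is the sampling stride in steps (the initial and final
    states are always recorded).  ``seed`` feeds one generator per run; with
    ``noise_on=False`` no random numbers are drawn at all and the scheme
    reduces bitwise to the deterministic Heun method.
    """

    dt: float = 0.02
    t_end: float = 100.0
    record_every: int = 25
    seed: int | None = 0
    noise_on: bool = True

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")


@dataclass
class Trajectory:
    """Time-indexed record of all cell states for one run.

    ``states`` has shape (n_samples, n_cells, 4) in (A, X, Y, Z) order;
    ``events`` lists applied parameter changes as (time, name, old, new).
    """

    times: np.ndarray
    states: np.ndarray
    events: list = field(default_factory=list)
    tissue: Tissue | None = None

    @property
    def n_cells(self) -> int:
        return self.states.shape[1]

    def final_states(self) -> np.ndarray:
        return self.states[-1]

    def final_fates(self) -> np.ndarray:
        return classify_fate(self.states[-1])

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format frame: t, cell_id, (row, col), A, X, Y, Z, fate."""
        n_t, n_c, _ = self.states.shape
        data = {
            "t": np.repeat(self.times, n_c),
            "cell_id": np.tile(np.arange(n_c), n_t),
        }
        if self.tissue is not None and self.tissue.positions is not None:
            data["row"] = np.tile(self.tissue.positions[:, 0], n_t)
            data["col"] = np.tile(self.tissue.positions[:, 1], n_t)
        flat = self.states.reshape(n_t * n_c, 4)
        for k, name in enumerate(VAR_NAMES):
            data[name] = flat[:, k]
        data["fate"] = classify_fate(flat) if flat.size else np.array([], dtype=object)
        return pd.DataFrame(data)

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


def heun_update(drift, state: np.ndarray, dt: float, noise_incr: np.ndarray | None):
    """One Heun-Maruyama update for an arbitrary drift and additive noise.

    ``noise_incr`` is the already-scaled additive increment ``g dW`` (same
    shape as ``state``) shared by predictor and corrector; ``None`` means
    no noise.  Returns the un-clamped updated state.
    """
    f0 = drift(state)
    if noise_incr is None:
        predictor = state + f0 * dt
        return state + 0.5 * (f0 + drift(predictor)) * dt
    predictor = state + f0 * dt + noise_incr
    return state + 0.5 * (f0 + drift(predictor)) * dt + noise_incr


def _coupled_drift(tissue: Tissue, p: ModelParams):
    def drift(states: np.ndarray) -> np.ndarray:
        return rhs(states, neighbor_signals(tissue, states), p)

    return drift


def heun_maruyama_step(
    states: np.ndarray,
    tissue: Tissue,
    p: ModelParams,
    dt: float,
    noise_draw: np.ndarray | None = None,
) -> np.ndarray:
    """Advance all cells by one step and clamp components at zero.

    ``noise_draw`` holds i.i.d. standard-normal draws of shape
    (n_cells, 2), one pair per cell for the X and Y channels; they are
    scaled internally by ``eta * sqrt(dt)``.  ``None`` integrates the
    deterministic drift only.
    """
    states = np.asarray(states, dtype=float)
    incr = None
    if noise_draw is not None:
        noise_draw = np.asarray(noise_draw, dtype=float)
        if noise_draw.shape != (states.shape[0], 2):
            raise ValueError("noise_draw must have shape (n_cells, 2)")
        incr = np.zeros_like(states)
        root_dt = np.sqrt(dt)
        incr[:, X] = p.eta_x * root_dt * noise_draw[:, 0]
        incr[:, Y] = p.eta_y * root_dt * noise_draw[:, 1]
    out = heun_update(_coupled_drift(tissue, p), states, dt, incr)
    return np.maximum(out, 0.0)


def simulate(
    tissue: Tissue,
    init: np.ndarray,
    p: ModelParams,
    cfg: IntegrationConfig,
    schedule=(),
    t0: float = 0.0,
) -> Trajectory:
    """Integrate from ``t0`` to ``cfg.t_end``, applying scheduled overrides.

    ``schedule`` is a sorted sequence of ``(time, {param: value})`` pairs;
    each override replaces fields of ``p`` from the first step boundary at
    or after its time (a negative ``t0`` provides pre-equilibration before
    a switch that marks t = 0).  Entries beyond ``t_end`` are ignored with
    a warning.  One seeded generator drives all noise; per-cell draws are
    made in a single (n_cells, 2) block per step, so runs are reproducible.
    """
    n = tissue.n_cells
    init = np.asarray(init, dtype=float).reshape(n, 4).copy()
    if cfg.t_end < t0:
        raise ValueError("t_end must be >= t0")
    sched = sorted(schedule, key=lambda item: item[0])
    for t_ev, _ in sched:
        if t_ev > cfg.t_end:
            warnings.warn(f"schedule entry at t={t_ev} is beyond t_end={cfg.t_end}; ignored")
    sched = [(t_ev, dict(ov)) for t_ev, ov in sched if t_ev <= cfg.t_end]

    n_steps = int(round((cfg.t_end - t0) / cfg.dt))
    rng = np.random.default_rng(cfg.seed) if cfg.noise_on else None

    times = [t0]
    samples = [init.copy()]
    events: list = []
    states = init
    next_ev = 0
    for k in range(n_steps):
        t = t0 + k * cfg.dt
        while next_ev < len(sched) and sched[next_ev][0] <= t + cfg.dt / 2:
            t_ev, overrides = sched[next_ev]
            for name, value in overrides.items():
                events.append((t_ev, name, getattr(p, name), value))
            p = p.replace(**overrides)
            next_ev += 1
        draws = rng.standard_normal((n, 2)) if rng is not None else None
        states = heun_maruyama_step(states, tissue, p, cfg.dt, draws)
        if not np.isfinite(states).all():
            bad = int(np.argwhere(~np.isfinite(states))[0, 0])
            raise FloatingPointError(
                f"non-finite state in cell {bad} at t={t + cfg.dt:.6g}"
            )
        if (k + 1) % cfg.record_every == 0 or k + 1 == n_steps:
            times.append(t0 + (k + 1) * cfg.dt)
            samples.append(states.copy())

    return Trajectory(
        times=np.asarray(times),
        states=np.asarray(samples) if samples else np.zeros((1, n, 4)),
        events=events,
        tissue=tissue,
    )


def population_average(traj: Trajectory) -> pd.DataFrame:
    """Mean A, X, Y, Z over cells at each sample time."""
    if traj.n_cells == 0:
        raise ValueError("population average of an empty tissue is undefined")
    means = traj.states.mean(axis=1)
    frame = pd.DataFrame(means, columns=list(VAR_NAMES))
    frame.insert(0, "t", traj.times)
    return frame


def islet_fraction(traj: Trajectory, z_threshold: float = 0.5) -> np.ndarray:
    """Fraction of cells classified islet at each sample time."""
    if traj.n_cells == 0:
        raise ValueError("islet fraction of an empty tissue is undefined")
    return (traj.states[:, :, 3] > z_threshold).mean(axis=1)


def time_to_fraction(traj: Trajectory, fraction: float = 0.5) -> float:
    """First sampled time at which the islet fraction exceeds ``fraction``.

    Returns NaN when the level is never reached.
    """
    frac = islet_fraction(traj)
    idx = np.nonzero(frac > fraction)[0]
    return float(traj.times[idx[0]]) if idx.size else float("nan")
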