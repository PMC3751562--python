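"""Canned experimental protocols and their summary statistics.

Protocols (each a :class:`ScenarioSpec` built by a factory):

* ``development`` -- progenitor ("embryo") initial state A=1, X=Y=Z=0 on a
  fully occupied lattice; noise breaks the symmetry and the tissue
  patterns itself into scattered islet cells inside acinar fields.
* ``conversion_stab`` -- differentiated ("adult") initial state Y=1,
  A=X=Z=0; after a burn-in confirming stability, lateral stabilization is
  lost (b=0) at t=0 and cells sequentially convert to the islet fate.
* ``conversion_both`` -- both couplings lost (a=b=0) at t=0: direct,
  faster conversion without a multipotent intermediate.
* ``inhibition_only`` -- a=0 with b intact: acinar identity is retained.
* ``recovery`` -- b=0 at t=0, restored at ``t_rec``; depending on timing
  the outcome is a mixed re-decision, an arrested conversion, or a
  completed conversion.
* ``density_sweep`` / ``shape_sweep`` -- adult tissue at reduced site
  occupancy or prescribed aggregate shapes, with b held fixed; conversion
  is driven by missing neighbours rather than by a parameter switch.

Replicates are advanced as one disjoint-union system (block-diagonal
coupling), which keeps the vectorized step cost low; per-replicate
occupancy masks are drawn from seeds derived deterministically from the
scenario seed, and the noise stream for a given spec is reproducible, so
equal specs (including seeds) give identical results and two scenarios
sharing a seed and tissue layout see identical noise (paired comparisons).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace as dc_replace
from typing import Sequence

import numpy as np
import pandas as pd

from .model import A, X, Y, Z, ModelParams, classify_fate
from .integrate import IntegrationConfig, Trajectory, heun_maruyama_step, simulate
from .tissue import Tissue, aggregate_stats, disjoint_union, from_occupancy, make_hex_lattice

__all__ = [
    "EMBRYO_STATE",
    "ADULT_STATE",
    "ScenarioSpec",
    "ScenarioResult",
    "development_spec",
    "conversion_spec",
    "recovery_spec",
    "run_scenario",
    "run_development",
    "run_conversion",
    "run_recovery",
    "run_density_sweep",
    "run_shape_sweep",
    "neighbor_pair_fraction",
    "shuffled_pair_fraction",
    "commitment_times",
]

# initial-condition presets (A, X, Y, Z)
EMBRYO_STATE = np.array([1.0, 0.0, 0.0, 0.0])
ADULT_STATE = np.array([0.0, 0.0, 1.0, 0.0])

_PRESETS = {"embryo": EMBRYO_STATE, "adult": ADULT_STATE}


@dataclass(frozen=True)
class ScenarioSpec:
    """Complete description of one protocol run (tissue, schedule, seeds).

    Scenario clocks are in the model's dimensionless time.  The defaults
    (t_end 100 for development, 200 for conversion/recovery, 300 for
    sweeps, set by the factories) let every protocol reach a steady fate
    classification at the reference parameters; ``burn_in`` integrates with
    pre-switch parameters for that long before the schedule's t=0 switch.
    """

    name: str = "development"
    width: int = 30
    height: int = 30
    density: float = 1.0
    boundary: str = "periodic"
    mask: object = None  # explicit occupancy array or Tissue; overrides density
    init: str = "embryo"
    params: ModelParams = field(default_factory=ModelParams)
    schedule: tuple = ()
    t_end: float = 100.0
    burn_in: float = 0.0
    dt: float = 0.02
    record_every: int = 25
    replicates: int = 1
    seed: int = 0
    t_rec: float | None = None
    keep_trajectories: bool = False

    def with_(self, **changes) -> "ScenarioSpec":
        return dc_replace(self, **changes)


@dataclass
class ScenarioResult:
    """Per-replicate conversion statistics and final fate maps.

    ``conversion_fraction`` uses the cells occupying the tissue at t=0 as
    denominator (in the adult preset all of them start acinar);
    ``time_to_half`` is the first recorded time the islet fraction of a
    replicate exceeds 0.5, NaN when never reached.
    """

    spec: ScenarioSpec
    tissues: list
    times: np.ndarray
    islet_fraction: np.ndarray  # (replicates, n_samples)
    conversion_fraction: np.ndarray  # (replicates,)
    time_to_half: np.ndarray  # (replicates,), NaN when never reached
    final_states: list
    final_fates: list
    trajectories: list | None = None
    outcomes: list | None = None  # recovery only

    @property
    def mean_conversion(self) -> float:
        return float(self.conversion_fraction.mean())

    @property
    def se_conversion(self) -> float:
        n = len(self.conversion_fraction)
        return float(self.conversion_fraction.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")


def development_spec(**overrides) -> ScenarioSpec:
    return ScenarioSpec(name="development", init="embryo", t_end=100.0, burn_in=0.0).with_(**overrides)


def conversion_spec(variant: str = "stab", **overrides) -> ScenarioSpec:
    """Adult tissue losing lateral signaling at t=0.

    ``variant``: ``stab`` (b=0), ``both`` (a=b=0) or ``inhibition``
    (a=0 only; a control in which acinar identity persists).
    """
    schedules = {
        "stab": ((0.0, {"b": 0.0}),),
        "both": ((0.0, {"a": 0.0, "b": 0.0}),),
        "inhibition": ((0.0, {"a": 0.0}),),
    }
    if variant not in schedules:
        raise ValueError(f"unknown conversion variant {variant!r}")
    name = {"stab": "conversion_stab", "both": "conversion_both", "inhibition": "inhibition_only"}[variant]
    return ScenarioSpec(
        name=name, init="adult", t_end=200.0, burn_in=20.0, schedule=schedules[variant]
    ).with_(**overrides)


def recovery_spec(t_rec: float, **overrides) -> ScenarioSpec:
    """Stabilization lost at t=0 and restored at ``t_rec`` > 0."""
    if t_rec <= 0:
        raise ValueError("t_rec must be > 0 (the loss marks t=0)")
    params = overrides.pop("params", ModelParams())
    schedule = ((0.0, {"b": 0.0}), (t_rec, {"b": params.b}))
    return ScenarioSpec(
        name="recovery", init="adult", params=params, t_end=200.0, burn_in=20.0,
        schedule=schedule, t_rec=t_rec,
    ).with_(**overrides)


def _replicate_tissues(spec: ScenarioSpec) -> list:
    base = np.random.SeedSequence(spec.seed)
    children = base.spawn(spec.replicates)
    tissues = []
    for r in range(spec.replicates):
        if spec.mask is not None:
            if isinstance(spec.mask, Tissue):
                tissues.append(spec.mask)
            else:
                tissues.append(from_occupancy(np.asarray(spec.mask, dtype=bool), boundary=spec.boundary))
        else:
            rng = np.random.default_rng(children[r])
            tissues.append(
                make_hex_lattice(spec.width, spec.height, spec.density, seed=rng, boundary=spec.boundary)
            )
    return tissues


def _noise_rng(spec: ScenarioSpec) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec.seed, 7**5]))


def run_scenario(spec: ScenarioSpec) -> ScenarioResult:
    """Run all replicates of a protocol and summarize fate conversion.

    All replicates advance as one disjoint-union system; when
    ``spec.keep_trajectories`` is set, full per-replicate trajectories are
    reconstructed from the recorded samples (memory permitting).
    """
    if spec.replicates < 1:
        raise ValueError("replicates must be >= 1")
    if spec.init not in _PRESETS:
        raise ValueError(f"unknown initial-condition preset {spec.init!r}")
    tissues = _replicate_tissues(spec)
    union = disjoint_union(tissues) if len(tissues) > 1 else tissues[0]
    n = union.n_cells
    init = np.tile(_PRESETS[spec.init], (n, 1))

    t0 = -float(spec.burn_in)
    p = spec.params
    sched = sorted(spec.schedule, key=lambda item: item[0])
    for t_ev, _ in sched:
        if t_ev > spec.t_end:
            warnings.warn(f"schedule entry at t={t_ev} is beyond t_end={spec.t_end}; ignored")
    sched = [(t_ev, dict(ov)) for t_ev, ov in sched if t_ev <= spec.t_end]

    n_steps = int(round((spec.t_end - t0) / spec.dt))
    rng = _noise_rng(spec)

    offsets = np.cumsum([0] + [t.n_cells for t in tissues])
    slices = [slice(offsets[i], offsets[i + 1]) for i in range(len(tissues))]

    times = [t0]
    islet_series = [[float((init[sl, Z] > 0.5).mean()) if sl.stop > sl.start else np.nan for sl in slices]]
    samples = [init.copy()] if spec.keep_trajectories else None

    states = init
    next_ev = 0
    for k in range(n_steps):
        t = t0 + k * spec.dt
        while next_ev < len(sched) and sched[next_ev][0] <= t + spec.dt / 2:
            p = p.replace(**sched[next_ev][1])
            next_ev += 1
        draws = rng.standard_normal((n, 2)) if p.eta_x or p.eta_y else None
        states = heun_maruyama_step(states, union, p, spec.dt, draws)
        if (k + 1) % spec.record_every == 0 or k + 1 == n_steps:
            if not np.isfinite(states).all():
                raise FloatingPointError(f"non-finite state at t={t + spec.dt:.6g}")
            times.append(t0 + (k + 1) * spec.dt)
            islet_series.append(
                [float((states[sl, Z] > 0.5).mean()) if sl.stop > sl.start else np.nan for sl in slices]
            )
            if samples is not None:
                samples.append(states.copy())

    times = np.asarray(times)
    islet_frac = np.asarray(islet_series).T  # (replicates, n_samples)
    conv = islet_frac[:, -1].copy()
    tth = np.full(spec.replicates, np.nan)
    for r in range(spec.replicates):
        above = np.nonzero(islet_frac[r] > 0.5)[0]
        if above.size:
            tth[r] = times[above[0]]

    final_states = [states[sl].copy() for sl in slices]
    final_fates = [classify_fate(fs) if len(fs) else np.array([], dtype=object) for fs in final_states]

    trajectories = None
    if samples is not None:
        stacked = np.asarray(samples)
        trajectories = [
            Trajectory(times=times.copy(), states=stacked[:, sl, :].copy(), tissue=tissues[i])
            for i, sl in enumerate(slices)
        ]

    outcomes = None
    if spec.name == "recovery":
        # classified from the final fate map: conversion that ran to the end
        # is "completed", a tissue that returned entirely to the acinar fate
        # is "arrested", and a final pattern with both fates marks the
        # development-like re-decision from the multipotent state
        outcomes = []
        for r in range(spec.replicates):
            if conv[r] >= 0.99:
                outcomes.append("completed")
            elif conv[r] <= 0.01:
                outcomes.append("arrested")
            else:
                outcomes.append("mixed_redecision")

    return ScenarioResult(
        spec=spec,
        tissues=tissues,
        times=times,
        islet_fraction=islet_frac,
        conversion_fraction=conv,
        time_to_half=tth,
        final_states=final_states,
        final_fates=final_fates,
        trajectories=trajectories,
        outcomes=outcomes,
    )


def run_development(spec: ScenarioSpec | None = None, **overrides) -> ScenarioResult:
    spec = development_spec(**overrides) if spec is None else spec
    if spec.init != "embryo":
        raise ValueError("development runs start from the embryo preset")
    return run_scenario(spec)


def run_conversion(spec: ScenarioSpec | None = None, variant: str = "stab", **overrides) -> ScenarioResult:
    spec = conversion_spec(variant, **overrides) if spec is None else spec
    if spec.init != "adult":
        raise ValueError("conversion runs start from the adult preset")
    return run_scenario(spec)


def run_recovery(spec: ScenarioSpec | None = None, t_rec: float | None = None, **overrides) -> ScenarioResult:
    if spec is None:
        if t_rec is None:
            raise ValueError("recovery needs t_rec")
        spec = recovery_spec(t_rec, **overrides)
    if spec.t_rec is None or spec.t_rec <= 0:
        raise ValueError("recovery needs t_rec > 0")
    return run_scenario(spec)


def run_density_sweep(
    densities: Sequence[float],
    b_values: Sequence[float],
    replicates: int = 20,
    spec: ScenarioSpec | None = None,
    seed: int = 0,
    t_end: float = 300.0,
) -> pd.DataFrame:
    """Mean conversion fraction over replicate lattices per (density, b).

    The adult tissue is integrated with b held at the given value
    throughout -- conversion here is driven by missing neighbours, not by
    a schedule.  Returns columns density, b, n_replicates,
    mean_conversion_fraction, se.
    """
    densities = list(densities)
    b_values = list(b_values)
    if not densities or not b_values or replicates < 1:
        raise ValueError("need at least one density, one b value and one replicate")
    base = spec if spec is not None else ScenarioSpec(name="density_sweep", init="adult")
    rows = []
    for bi, b in enumerate(b_values):
        for di, dens in enumerate(densities):
            cell_seed = int(np.random.SeedSequence([seed, bi, di]).generate_state(1)[0] % 2**31)
            res = run_scenario(
                base.with_(
                    name="density_sweep",
                    init="adult",
                    density=dens,
                    params=base.params.replace(b=b),
                    schedule=(),
                    burn_in=0.0,
                    t_end=t_end,
                    replicates=replicates,
                    seed=cell_seed,
                )
            )
            valid = res.conversion_fraction[np.isfinite(res.conversion_fraction)]
            rows.append(
                {
                    "density": dens,
                    "b": b,
                    "n_replicates": len(valid),
                    "mean_conversion_fraction": float(valid.mean()),
                    "se": float(valid.std(ddof=1) / np.sqrt(len(valid))) if len(valid) > 1 else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def run_shape_sweep(
    masks: Sequence,
    params: ModelParams | None = None,
    replicates: int = 20,
    seed: int = 0,
    t_end: float = 300.0,
    boundary: str = "fixed",
) -> pd.DataFrame:
    """Conversion fraction versus aggregate compactness for given shapes.

    Each mask (a boolean occupancy array or a Tissue) is run ``replicates``
    times from the adult preset; masks of unequal cell count trigger a
    warning since the comparison is then confounded by aggregate size.
    Returns columns mask_index, n_cells, mean_neighbors, n_replicates,
    mean_conversion_fraction, se.
    """
    if not masks:
        raise ValueError("need at least one occupancy mask")
    params = ModelParams() if params is None else params
    tissues = [
        m if isinstance(m, Tissue) else from_occupancy(np.asarray(m, dtype=bool), boundary=boundary)
        for m in masks
    ]
    counts = {t.n_cells for t in tissues}
    if len(counts) > 1:
        warnings.warn("masks have unequal cell counts; shape comparison is confounded")
    rows = []
    for mi, tissue in enumerate(tissues):
        stats = aggregate_stats(tissue)
        cell_seed = int(np.random.SeedSequence([seed, mi]).generate_state(1)[0] % 2**31)
        res = run_scenario(
            ScenarioSpec(
                name="shape_sweep",
                init="adult",
                mask=tissue,
                params=params,
                t_end=t_end,
                replicates=replicates,
                seed=cell_seed,
            )
        )
        conv = res.conversion_fraction
        rows.append(
            {
                "mask_index": mi,
                "n_cells": stats.n_cells,
                "mean_neighbors": stats.mean_neighbors,
                "n_replicates": replicates,
                "mean_conversion_fraction": float(conv.mean()),
                "se": float(conv.std(ddof=1) / np.sqrt(len(conv))) if len(conv) > 1 else float("nan"),
            }
        )
    return pd.DataFrame(rows)


# -- spatial pattern statistics ---------------------------------------------


def neighbor_pair_fraction(tissue: Tissue, members: np.ndarray) -> float:
    """Fraction of adjacency edges whose two endpoints are both members."""
    members = np.asarray(members, dtype=bool)
    total = 0
    both = 0
    for i, nbrs in enumerate(tissue.neighbors):
        for j in nbrs:
            if j > i:
                total += 1
                both += int(members[i] and members[j])
    return both / total if total else float("nan")


def shuffled_pair_fraction(
    tissue: Tissue, n_members: int, rng: np.random.Generator, n_shuffles: int = 200
) -> np.ndarray:
    """Null distribution of :func:`neighbor_pair_fraction` for random labels."""
    n = tissue.n_cells
    out = np.empty(n_shuffles)
    members = np.zeros(n, dtype=bool)
    for k in range(n_shuffles):
        members[:] = False
        members[rng.choice(n, size=n_members, replace=False)] = True
        out[k] = neighbor_pair_fraction(tissue, members)
    return out


def commitment_times(traj: Trajectory, var: int, threshold: float = 0.5) -> np.ndarray:
    """First sampled time each cell's ``var`` exceeds ``threshold`` (NaN if never).

    ``var`` is a state column index (e.g. ``model.Y`` for acinar
    commitment, ``model.Z`` for islet commitment).
    """
    above = traj.states[:, :, var] > threshold
    out = np.full(traj.n_cells, np.nan)
    for i in range(traj.n_cells):
        idx = np.nonzero(above[:, i])[0]
        if idx.size:
            out[i] = traj.times[idx[0]]
    return out
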