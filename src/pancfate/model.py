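"""Per-cell gene regulatory dynamics of the pancreatic fate-control network.

Each cell carries four dimensionless transcription-factor levels:

=====  ==============================================================
``A``  upstream inducer (Hnf6-like); high in early progenitors
``X``  pro-endocrine factor (Ngn3-like); transient, laterally inhibited
``Y``  exocrine/acinar factor (Ptf1a-like); laterally stabilized
``Z``  terminal islet factor (Isl1-like); self-activating
=====  ==============================================================

The deterministic drift uses Hill kinetics with exponent ``n``.  Cells are
coupled only through the average expression of ``X`` and ``Y`` in directly
adjacent cells (``Xbar``, ``Ybar``): neighbouring ``X`` suppresses a cell's
own ``X`` production (lateral inhibition, strength ``a``), while the
multiplicative ``(Y*Ybar)**n`` term up-regulates ``Y`` only when the factor
is expressed on *both* sides of a contact (lateral stabilization, strength
``b``).  Gaussian white noise of amplitude ``eta_x``/``eta_y`` is added to
``X`` and ``Y`` by the stochastic integrator, never here.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "A",
    "X",
    "Y",
    "Z",
    "VAR_NAMES",
    "ModelParams",
    "CellState",
    "NeighborSignal",
    "ACINAR",
    "ISLET",
    "PROGENITOR",
    "default_params",
    "rhs",
    "classify_fate",
]

# Column indices of the state layout used throughout the package.
A, X, Y, Z = 0, 1, 2, 3
VAR_NAMES = ("A", "X", "Y", "Z")

ACINAR = "acinar"
ISLET = "islet"
PROGENITOR = "progenitor"


@dataclass(frozen=True)
class ModelParams:
    """Rate, coupling and noise constants of the regulatory network.

    Defaults are the reference parameter set used for every headline
    result: strong lateral inhibition (a=1000) and stabilization (b=2000),
    weak induction (q=1e-4), and cubic Hill nonlinearity (n=3).

    Parameters
    ----------
    a : lateral-inhibition strength (neighbour X represses own X).
    b : lateral-stabilization strength (mutual Y-Y reinforcement).
    c : strength of the X -| Y and Z -| Y repressions.
    q : induction strength of A -> X and A -> Y.
    r : strength of the Y -| A and Z -| A repressions.
    s : Z auto-activation strength.
    n : Hill coefficient (positive integer).
    eta_x, eta_y : additive noise amplitudes on X and Y.
    """

    a: float = 1000.0
    b: float = 2000.0
    c: float = 500.0
    q: float = 1e-4
    r: float = 100.0
    s: float = 50.0
    n: int = 3
    eta_x: float = 1e-3
    eta_y: float = 1e-3

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "q", "r", "s", "eta_x", "eta_y"):
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"parameter {name!r} must be finite and >= 0, got {value}")
        if int(self.n) != self.n or self.n < 1:
            raise ValueError(f"parameter 'n' must be a positive integer, got {self.n}")
        object.__setattr__(self, "n", int(self.n))

    def replace(self, **changes: float) -> "ModelParams":
        """Return a copy with the given fields overridden (re-validated)."""
        return dataclasses.replace(self, **changes)


def default_params() -> ModelParams:
    """The reference parameter set (see :class:`ModelParams` defaults)."""
    return ModelParams()


class CellState(NamedTuple):
    """Expression levels of one cell; components are >= 0 by contract."""

    A: float
    X: float
    Y: float
    Z: float


class NeighborSignal(NamedTuple):
    """Average X and Y expression over a cell's adjacent neighbour sites.

    Both are zero for an isolated cell.
    """

    Xbar: float
    Ybar: float


def _ipow(v, k: int):
    """v**k for small non-negative integer k via repeated multiplication.

    Much cheaper than ``np.power`` on large float arrays for the Hill
    exponents used here.
    """
    if k == 0:
        return np.ones_like(v) if isinstance(v, np.ndarray) else 1.0
    out = v
    for _ in range(k - 1):
        out = out * v
    return out


def rhs(states, signals, p: ModelParams):
    """Deterministic drift (dA/dt, dX/dt, dY/dt, dZ/dt) for one or many cells.

    Parameters
    ----------
    states : array_like, shape (4,) or (n_cells, 4)
        Non-negative expression levels in (A, X, Y, Z) order.
    signals : array_like, shape (2,) or (n_cells, 2)
        Neighbour averages (Xbar, Ybar) matching ``states``.
    p : ModelParams

    Returns
    -------
    ndarray with the same shape as ``states``.  Noise is *not* included;
    the stochastic integrator adds it to the X and Y components.
    """
    st = np.asarray(states, dtype=float)
    sg = np.asarray(signals, dtype=float)
    single = st.ndim == 1
    st = np.atleast_2d(st)
    sg = np.atleast_2d(sg)
    if st.shape[1] != 4 or sg.shape[1] != 2 or st.shape[0] != sg.shape[0]:
        raise ValueError(f"incompatible shapes {st.shape} and {sg.shape}")
    if not (np.isfinite(st).all() and np.isfinite(sg).all()):
        raise ValueError("non-finite cell state or neighbour signal")

    n = p.n
    av, xv, yv, zv = st[:, A], st[:, X], st[:, Y], st[:, Z]
    xb, yb = sg[:, 0], sg[:, 1]

    an = _ipow(av, n)
    xn = _ipow(xv, n)
    yn = _ipow(yv, n)
    zn = _ipow(zv, n)
    u = _ipow(yv * yb, n)  # mutual-stabilization drive
    szn = p.s * zn

    out = np.empty_like(st)
    out[:, A] = 1.0 / (1.0 + p.r * yn + p.r * zn) - av
    out[:, X] = p.q * an / (p.q + p.a * _ipow(xb, n)) - xv
    stab = p.b * u
    out[:, Y] = (p.q * an + stab) / (p.q + stab + p.c * xn + p.c * zn) - yv
    out[:, Z] = (xn + szn) / (1.0 + szn) - zv
    return out[0] if single else out


def classify_fate(states, y_threshold: float = 0.5, z_threshold: float = 0.5):
    """Assign each cell one of ``acinar`` / ``islet`` / ``progenitor``.

    A cell is *islet* when Z exceeds ``z_threshold`` (islet takes precedence:
    the fates are mutually exclusive at the reference parameters, so a state
    with both markers high occurs at most transiently), *acinar* when Y
    exceeds ``y_threshold`` with Z at or below ``z_threshold``, and
    *progenitor* otherwise.  Steady states cluster near 0 and 1, so any
    mid-range threshold gives the same labels; 0.5 is the symmetric default.

    Accepts a single state (shape ``(4,)``) or a stack ``(n_cells, 4)``;
    returns a single label string or an object array of labels.
    """
    st = np.asarray(states, dtype=float)
    single = st.ndim == 1
    st = np.atleast_2d(st)
    labels = np.full(st.shape[0], PROGENITOR, dtype=object)
    islet = st[:, Z] > z_threshold
    acinar = (st[:, Y] > y_threshold) & ~islet
    labels[islet] = ISLET
    labels[acinar] = ACINAR
    return labels[0] if single else labels
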