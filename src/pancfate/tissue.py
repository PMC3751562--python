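"""Cell collections and neighbour topology.

Supported topologies:

* ``hex_lattice`` -- a width x height hexagonal lattice in odd-r offset
  coordinates (odd rows shifted right), with Bernoulli site occupancy to
  model cell density, and either periodic or fixed (void) boundaries.
* ``triangle3`` -- three mutually adjacent cells, the minimal tissue in
  which a mixed fate pattern can exist.  Its nominal coordination is 2.
* ``explicit_graph`` -- arbitrary symmetric adjacency from an edge list.

Neighbour signals divide the summed neighbour expression by the topology's
*nominal* coordination number (6 on the hex lattice, 2 on triangle3), so
empty neighbour sites dilute the received signal.  This makes lateral
signalling scale with local cell density -- a cell pair is less stabilized
than a cell in bulk tissue -- which is what drives the density dependence
of fate conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .model import VAR_NAMES, X, Y, classify_fate

__all__ = [
    "Tissue",
    "AggregateStats",
    "make_hex_lattice",
    "make_triangle3",
    "from_occupancy",
    "from_edge_list",
    "neighbor_signals",
    "aggregate_stats",
    "save_mask",
    "load_mask",
    "save_states",
]

# odd-r offset stencils: (drow, dcol) for even and odd rows
_EVEN_ROW_STENCIL = ((0, -1), (0, 1), (-1, -1), (-1, 0), (1, -1), (1, 0))
_ODD_ROW_STENCIL = ((0, -1), (0, 1), (-1, 0), (-1, 1), (1, 0), (1, 1))


@dataclass
class Tissue:
    """A set of cells with a symmetric, irreflexive neighbour relation.

    Attributes
    ----------
    topology : one of ``hex_lattice``, ``triangle3``, ``explicit_graph``.
    coordination : nominal neighbour-site count used to normalize signals.
    neighbors : per-cell integer arrays of adjacent occupied cells.
    positions : (n_cells, 2) ``(row, col)`` site coordinates, lattices only.
    occupied : (height, width) boolean site mask, lattices only.
    boundary : ``periodic`` or ``fixed``, lattices only.
    """

    topology: str
    coordination: int
    neighbors: list
    positions: np.ndarray | None = None
    occupied: np.ndarray | None = None
    width: int | None = None
    height: int | None = None
    boundary: str = "periodic"
    coupling: sp.csr_matrix = field(init=False, repr=False)

    def __post_init__(self) -> None:
        n = self.n_cells
        rows, cols = [], []
        for i, nbrs in enumerate(self.neighbors):
            self.neighbors[i] = np.asarray(sorted(nbrs), dtype=np.intp)
            for j in self.neighbors[i]:
                if j == i:
                    raise ValueError(f"cell {i} listed as its own neighbour")
                rows.append(i)
                cols.append(int(j))
        data = np.full(len(rows), 1.0 / self.coordination)
        self.coupling = sp.csr_matrix((data, (rows, cols)), shape=(n, n))
        if (abs(self.coupling - self.coupling.T) > 0).nnz:
            raise ValueError("neighbour relation is not symmetric")

    @property
    def n_cells(self) -> int:
        return len(self.neighbors)

    def degree(self) -> np.ndarray:
        """Number of occupied neighbours per cell."""
        return np.array([len(nb) for nb in self.neighbors], dtype=int)


@dataclass(frozen=True)
class AggregateStats:
    """Occupancy summary; ``mean_neighbors`` measures aggregate compactness."""

    n_cells: int
    mean_neighbors: float
    density: float


def _hex_neighbor_sites(r: int, c: int, height: int, width: int, boundary: str):
    stencil = _EVEN_ROW_STENCIL if r % 2 == 0 else _ODD_ROW_STENCIL
    for dr, dc in stencil:
        rr, cc = r + dr, c + dc
        if boundary == "periodic":
            yield rr % height, cc % width
        elif 0 <= rr < height and 0 <= cc < width:
            yield rr, cc


def from_occupancy(occupied: np.ndarray, boundary: str = "periodic") -> Tissue:
    """Build a hex-lattice tissue from an explicit boolean site mask."""
    occupied = np.asarray(occupied, dtype=bool)
    if occupied.ndim != 2:
        raise ValueError("occupancy mask must be 2-D (height x width)")
    height, width = occupied.shape
    if boundary not in ("periodic", "fixed"):
        raise ValueError(f"unknown boundary {boundary!r}")
    if boundary == "periodic" and height > 1 and height % 2:
        raise ValueError("periodic hex lattice requires an even number of rows")
    index = -np.ones(occupied.shape, dtype=np.intp)
    positions = np.argwhere(occupied)
    for k, (r, c) in enumerate(positions):
        index[r, c] = k
    neighbors: list[list[int]] = [[] for _ in range(len(positions))]
    for k, (r, c) in enumerate(positions):
        seen = set()
        for rr, cc in _hex_neighbor_sites(int(r), int(c), height, width, boundary):
            j = index[rr, cc]
            # a site can alias itself/neighbours on tiny periodic lattices
            if j >= 0 and j != k and (rr, cc) not in seen:
                neighbors[k].append(int(j))
                seen.add((rr, cc))
    return Tissue(
        topology="hex_lattice",
        coordination=6,
        neighbors=neighbors,
        positions=positions,
        occupied=occupied,
        width=width,
        height=height,
        boundary=boundary,
    )


def make_hex_lattice(
    width: int,
    height: int,
    density: float = 1.0,
    seed: int | np.random.Generator | None = None,
    boundary: str = "periodic",
) -> Tissue:
    """Hexagonal lattice with sites occupied independently at ``density``.

    ``density`` is the Bernoulli occupancy probability per site; ``seed``
    may be an integer or a ``numpy.random.Generator``.
    """
    if width < 1 or height < 1:
        raise ValueError("width and height must be >= 1")
    if not 0.0 <= density <= 1.0:
        raise ValueError(f"density must lie in [0, 1], got {density}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    occupied = rng.random((height, width)) < density
    return from_occupancy(occupied, boundary=boundary)


def make_triangle3() -> Tissue:
    """Three mutually adjacent cells (nominal coordination 2).

    The smallest tissue on which homogeneous, alternating and mixed fate
    configurations can all be realized.
    """
    return Tissue(
        topology="triangle3",
        coordination=2,
        neighbors=[[1, 2], [0, 2], [0, 1]],
    )


def from_edge_list(
    edges: str | Iterable[Sequence[int]],
    n_cells: int | None = None,
    coordination: int | None = None,
) -> Tissue:
    """Explicit-graph tissue from ``(i, j)`` pairs or an edge-list text file.

    File format: two whitespace-separated integer cell ids per line; blank
    lines and ``#`` comments are ignored.  ``coordination`` defaults to the
    maximum degree of the graph.
    """
    if isinstance(edges, str):
        pairs = []
        with open(edges) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                i, j = (int(tok) for tok in line.split())
                pairs.append((i, j))
    else:
        pairs = [(int(i), int(j)) for i, j in edges]
    if any(i == j for i, j in pairs):
        raise ValueError("self-edges are not allowed")
    n = n_cells if n_cells is not None else (max(max(p) for p in pairs) + 1 if pairs else 0)
    neighbors: list[set[int]] = [set() for _ in range(n)]
    for i, j in pairs:
        neighbors[i].add(j)
        neighbors[j].add(i)
    coord = coordination if coordination is not None else max((len(s) for s in neighbors), default=1)
    return Tissue(
        topology="explicit_graph",
        coordination=max(coord, 1),
        neighbors=[sorted(s) for s in neighbors],
    )


def disjoint_union(tissues: Sequence[Tissue]) -> Tissue:
    """Concatenate tissues into one with no edges between the parts.

    All parts must share the same coordination number (signal normalization
    is per-topology).  Cells are renumbered part by part; independent
    replicate simulations can thereby be advanced in one vectorized system.
    """
    if not tissues:
        raise ValueError("need at least one tissue")
    coord = tissues[0].coordination
    if any(t.coordination != coord for t in tissues):
        raise ValueError("all tissues in a union must share a coordination number")
    neighbors: list[list[int]] = []
    offset = 0
    for t in tissues:
        for nb in t.neighbors:
            neighbors.append([offset + int(j) for j in nb])
        offset += t.n_cells
    return Tissue(topology="explicit_graph", coordination=coord, neighbors=neighbors)


def neighbor_signals(tissue: Tissue, states: np.ndarray) -> np.ndarray:
    """Per-cell ``(Xbar, Ybar)``: summed neighbour expression / coordination.

    Empty neighbour sites contribute zero to the sum but are still counted
    in the denominator; an isolated cell receives ``(0, 0)``.
    """
    states = np.asarray(states, dtype=float)
    if states.shape != (tissue.n_cells, 4):
        raise ValueError(f"states must have shape ({tissue.n_cells}, 4), got {states.shape}")
    if tissue.n_cells == 0:
        return np.zeros((0, 2))
    return tissue.coupling @ states[:, [X, Y]]


def aggregate_stats(tissue: Tissue) -> AggregateStats:
    """Cell count, mean occupied neighbours per cell, and site density.

    ``density`` is the occupied fraction of lattice sites; for non-lattice
    topologies it is reported as NaN.
    """
    n = tissue.n_cells
    mean_nb = float(tissue.degree().mean()) if n else 0.0
    if tissue.occupied is not None:
        density = float(n / tissue.occupied.size)
    else:
        density = float("nan")
    return AggregateStats(n_cells=n, mean_neighbors=mean_nb, density=density)


def save_mask(tissue: Tissue, path: str) -> None:
    """Write a lattice occupancy mask as CSV with columns row, col, occupied."""
    if tissue.occupied is None:
        raise ValueError("tissue has no lattice occupancy mask")
    h, w = tissue.occupied.shape
    rows, cols = np.divmod(np.arange(h * w), w)
    pd.DataFrame(
        {"row": rows, "col": cols, "occupied": tissue.occupied.ravel().astype(int)}
    ).to_csv(path, index=False)


def load_mask(path: str, boundary: str = "periodic") -> Tissue:
    """Read an occupancy-mask CSV written by :func:`save_mask`."""
    df = pd.read_csv(path)
    for col in ("row", "col", "occupied"):
        if col not in df.columns:
            raise ValueError(f"mask file missing column {col!r}")
    height = int(df["row"].max()) + 1
    width = int(df["col"].max()) + 1
    occupied = np.zeros((height, width), dtype=bool)
    occupied[df["row"].to_numpy(), df["col"].to_numpy()] = df["occupied"].to_numpy().astype(bool)
    return from_occupancy(occupied, boundary=boundary)


def save_states(tissue: Tissue, states: np.ndarray, path: str) -> None:
    """Snapshot CSV: one row per cell with coordinates, levels and fate."""
    states = np.asarray(states, dtype=float)
    data = {"cell_id": np.arange(tissue.n_cells)}
    if tissue.positions is not None:
        data["row"] = tissue.positions[:, 0]
        data["col"] = tissue.positions[:, 1]
    for k, name in enumerate(VAR_NAMES):
        data[name] = states[:, k]
    data["fate"] = classify_fate(states) if tissue.n_cells else np.array([], dtype=object)
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")
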