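"""Spatial adjacency structures and the intrinsic-CAR precision scaffold.

Small-area models borrow strength between neighbouring areas through an
intrinsic conditional autoregressive (ICAR) prior whose precision matrix is
``tau * R`` with ``R = D - W`` (degree matrix minus adjacency matrix).  This
module holds the area graph, readers/writers for a plain-text neighbour-list
format, and the structure matrix ``R`` itself.  The area ordering of the
graph is the single canonical index mapping used by every vector downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

__all__ = [
    "AreaGraph",
    "GraphError",
    "SymmetryError",
    "DuplicateAreaError",
    "UnknownAreaError",
    "AdjacencyFormatError",
    "build_grid_lattice",
    "read_adjacency",
    "write_adjacency",
    "connected_components",
    "icar_structure",
]


class GraphError(ValueError):
    """Base class for invalid adjacency input."""


class SymmetryError(GraphError):
    """A neighbour listing that is not symmetric (i lists j but j not i)."""


class DuplicateAreaError(GraphError):
    """The same area identifier appears more than once."""


class UnknownAreaError(GraphError):
    """A neighbour refers to an identifier that is not an area."""


class AdjacencyFormatError(GraphError):
    """The neighbour-list file is structurally malformed."""


@dataclass(frozen=True)
class AreaGraph:
    """Symmetric adjacency structure over ``n_areas`` areas.

    Parameters
    ----------
    area_ids
        Ordered, unique, whitespace-free identifiers.  The position of an id
        in this tuple is its index everywhere else in the package.
    neighbors
        Per-area tuple of neighbour *indices*; must be symmetric and free of
        self-loops.
    """

    area_ids: tuple[str, ...]
    neighbors: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        ids = self.area_ids
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            for a in ids:
                if a in seen:
                    raise DuplicateAreaError(f"duplicate area id {a!r}")
                seen.add(a)
        if any(" " in a or not a for a in ids):
            raise AdjacencyFormatError("area ids must be non-empty and whitespace-free")
        n = len(ids)
        if len(self.neighbors) != n:
            raise GraphError("neighbors list length does not match area_ids")
        sets = [set(nb) for nb in self.neighbors]
        for i, nb in enumerate(self.neighbors):
            if len(sets[i]) != len(nb):
                raise GraphError(f"area {ids[i]!r} lists a neighbour twice")
            for j in nb:
                if not (0 <= j < n):
                    raise UnknownAreaError(f"neighbour index {j} of area {ids[i]!r} out of range")
                if j == i:
                    raise GraphError(f"area {ids[i]!r} lists itself as neighbour")
                if i not in sets[j]:
                    raise SymmetryError(
                        f"asymmetric adjacency: {ids[i]!r} lists {ids[j]!r} but not vice versa"
                    )

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    @property
    def n_edges(self) -> int:
        return sum(len(nb) for nb in self.neighbors) // 2

    def edges(self) -> list[tuple[int, int]]:
        """Unordered neighbour pairs (i < j)."""
        return [(i, j) for i, nb in enumerate(self.neighbors) for j in nb if i < j]

    def degrees(self) -> np.ndarray:
        return np.array([len(nb) for nb in self.neighbors], dtype=float)

    def adjacency_matrix(self) -> np.ndarray:
        W = np.zeros((self.n_areas, self.n_areas))
        for i, j in self.edges():
            W[i, j] = W[j, i] = 1.0
        return W

    def index_of(self, area_id: str) -> int:
        try:
            return self.area_ids.index(area_id)
        except ValueError:
            raise UnknownAreaError(f"unknown area id {area_id!r}") from None

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_areas))
        g.add_edges_from(self.edges())
        return g


def build_grid_lattice(rows: int, cols: int) -> AreaGraph:
    """Rook-contiguity rectangular lattice with ``rows * cols`` areas.

    A synthetic stand-in for an administrative district map: interior cells
    have four neighbours, corners two.  Ids are ``r<row>c<col>`` in row-major
    order.
    """
    if rows < 1 or cols < 1:
        raise GraphError(f"lattice dimensions must be positive, got {rows}x{cols}")
    if rows * cols < 2:
        raise GraphError("lattice needs at least two areas")
    ids = tuple(f"r{r}c{c}" for r in range(rows) for c in range(cols))
    neighbors = []
    for r in range(rows):
        for c in range(cols):
            nb = []
            if r > 0:
                nb.append((r - 1) * cols + c)
            if r < rows - 1:
                nb.append((r + 1) * cols + c)
            if c > 0:
                nb.append(r * cols + c - 1)
            if c < cols - 1:
                nb.append(r * cols + c + 1)
            neighbors.append(tuple(sorted(nb)))
    return AreaGraph(ids, tuple(neighbors))


def read_adjacency(path: str | Path) -> AreaGraph:
    """Read a neighbour-list text file.

    Format: first line is the number of areas ``n``; each of the following
    ``n`` lines is ``<area_id> <neighbor_id> ...`` (whitespace separated).
    Symmetry is validated, never silently repaired.
    """
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    lines = [ln for ln in lines if ln]
    if not lines:
        raise AdjacencyFormatError(f"{path}: empty file")
    try:
        n = int(lines[0])
    except ValueError:
        raise AdjacencyFormatError(f"{path}: first line must be the area count") from None
    if len(lines) - 1 != n:
        raise AdjacencyFormatError(f"{path}: expected {n} area lines, found {len(lines) - 1}")
    rows = [ln.split() for ln in lines[1:]]
    ids = [r[0] for r in rows]
    if len(set(ids)) != len(ids):
        dup = next(a for i, a in enumerate(ids) if a in ids[:i])
        raise DuplicateAreaError(f"{path}: duplicate area id {dup!r}")
    index = {a: i for i, a in enumerate(ids)}
    neighbors = []
    for r in rows:
        nb = []
        for name in r[1:]:
            if name not in index:
                raise UnknownAreaError(f"{path}: unknown neighbour id {name!r}")
            nb.append(index[name])
        neighbors.append(tuple(nb))
    return AreaGraph(tuple(ids), tuple(neighbors))


def write_adjacency(graph: AreaGraph, path: str | Path) -> None:
    """Write the neighbour-list dialect read by :func:`read_adjacency`."""
    lines = [str(graph.n_areas)]
    for i, nb in enumerate(graph.neighbors):
        lines.append(" ".join([graph.area_ids[i]] + [graph.area_ids[j] for j in nb]))
    Path(path).write_text("\n".join(lines) + "\n")


def connected_components(graph: AreaGraph) -> list[list[int]]:
    """Disjoint components as sorted index lists, ordered by smallest member.

    The component count ``c`` sets the rank deficiency of the ICAR structure
    matrix and the per-component centring of the structured spatial effect.
    """
    comps = [sorted(c) for c in nx.connected_components(graph.to_networkx())]
    return sorted(comps, key=lambda c: c[0])


def icar_structure(graph: AreaGraph) -> np.ndarray:
    """ICAR structure matrix ``R = D - W``.

    ``R`` is symmetric positive semi-definite with zero row sums; its rank is
    ``n_areas - c`` where ``c`` is the number of connected components, and
    the quadratic form ``v' R v`` equals the sum of squared differences over
    neighbour pairs.
    """
    W = graph.adjacency_matrix()
    return np.diag(W.sum(axis=1)) - W
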