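"""Cell-network topologies for intercellular calcium-wave simulation.

Cells are unit squares on an integer lattice.  Two cells that share a side
are coupled through an *edge* gap-junction contact (coefficient ``d_edge``,
the dimensionless diffusion coefficient of a linear chain); two cells that
share only a corner are coupled through a *vertex* contact (coefficient
``dv``), the weaker diagonal pathway found in the junction cluster of a
branched ("T") structure.

Two architectures are provided:

* a finite single-file chain of ``n`` cells, and
* a "T" structure: a 61-cell backbone, a 30-cell side branch rising from
  backbone cell 31, and two cluster cells 1' and 2' flanking the first
  branch cell, mimicking the multi-cell cluster that forms where patterned
  branches meet.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "Cell",
    "Coupling",
    "CouplingKind",
    "CellNetwork",
    "build_chain",
    "build_t_structure",
    "validate_network",
    "network_to_json",
    "network_from_json",
]


class CouplingKind(str, Enum):
    EDGE = "edge"
    VERTEX = "vertex"


@dataclass(frozen=True)
class Cell:
    """A cell with a unique label and an integer lattice position.

    ``column``/``row`` are in units of one cell width; the backbone of a
    chain or T structure sits on row 0.
    """

    label: str
    column: int
    row: int

    @property
    def position(self) -> tuple[int, int]:
        return (self.column, self.row)


@dataclass(frozen=True)
class Coupling:
    """A symmetric diffusive link between two cells.

    ``kind`` must agree with the geometry: edge couplings join orthogonally
    adjacent cells, vertex couplings join diagonally adjacent cells.
    """

    a: str
    b: str
    kind: CouplingKind
    coefficient: float

    def pair(self) -> frozenset[str]:
        return frozenset((self.a, self.b))


@dataclass
class CellNetwork:
    """A set of cells plus the weighted couplings between them."""

    cells: list[Cell]
    couplings: list[Coupling]
    architecture: str = "custom"

    def __post_init__(self) -> None:
        self._index = {c.label: i for i, c in enumerate(self.cells)}

    # -- basic accessors -------------------------------------------------

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.cells]

    def index_of(self, label: str) -> int:
        return self._index[label]

    def cell(self, label: str) -> Cell:
        return self.cells[self._index[label]]

    def __contains__(self, label: str) -> bool:
        return label in self._index

    def neighbors(self, label: str) -> list[tuple[str, Coupling]]:
        out = []
        for cp in self.couplings:
            if cp.a == label:
                out.append((cp.b, cp))
            elif cp.b == label:
                out.append((cp.a, cp))
        return out

    # -- numeric views ---------------------------------------------------

    def coupling_matrix(self) -> np.ndarray:
        """Dense symmetric matrix of coupling coefficients (zero diagonal)."""
        n = self.n_cells
        w = np.zeros((n, n))
        for cp in self.couplings:
            i, j = self._index[cp.a], self._index[cp.b]
            w[i, j] = w[j, i] = cp.coefficient
        return w

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for c in self.cells:
            g.add_node(c.label, column=c.column, row=c.row)
        for cp in self.couplings:
            g.add_edge(cp.a, cp.b, kind=cp.kind.value, coefficient=cp.coefficient)
        return g


# ---------------------------------------------------------------------------
# constructors
# ---------------------------------------------------------------------------


def build_chain(n_cells: int, d_edge: float) -> CellNetwork:
    """A single-file chain of ``n_cells`` cells labelled ``1`` … ``n_cells``.

    Every pair of neighbouring cells is joined by one edge coupling with
    coefficient ``d_edge``.  Terminal cells simply have a single coupling
    (zero-flux boundary; there are no ghost cells).
    """
    if n_cells < 2:
        raise ValueError(f"a chain needs at least 2 cells, got {n_cells}")
    if d_edge < 0:
        raise ValueError(f"coupling coefficient must be >= 0, got {d_edge}")
    cells = [Cell(str(i), i, 0) for i in range(1, n_cells + 1)]
    couplings = [
        Coupling(str(i), str(i + 1), CouplingKind.EDGE, d_edge)
        for i in range(1, n_cells)
    ]
    return CellNetwork(cells, couplings, architecture="chain")


#: Diagonal (vertex-contact) pairs confined to the junction cluster: the
#: first branch cell against the flanking backbone cells, and the two
#: cluster cells against the branch-bearing backbone cell.  This is the
#: default vertex wiring; it reproduces the junction phenomenology of the
#: model (first propagation failure at backbone cell 30, dual stimulation
#: sustaining propagation at stronger vertex coupling than single).
CLUSTER_VERTEX_PAIRS = (("1s", "30"), ("1s", "32"), ("1'", "31"), ("2'", "31"))

#: Additional diagonal pairs present in the lattice outside the immediate
#: cluster; with rule="all_diagonals" every geometrically diagonal pair is
#: coupled.
EXTRA_VERTEX_PAIRS = (("1'", "29"), ("2'", "33"), ("1'", "2s"), ("2'", "2s"))


def build_t_structure(
    d_edge: float,
    dv: float,
    *,
    n_backbone: int = 61,
    n_branch: int = 30,
    vertex_rule: str = "cluster",
) -> CellNetwork:
    """The branched "T" network: backbone, side branch and junction cluster.

    Backbone cells ``1`` … ``61`` occupy row 0; branch cells ``1s`` … ``30s``
    rise from the column of backbone cell 31 (rows 1…30); cluster cells
    ``1'`` and ``2'`` sit at (30, 1) and (32, 1), flanking ``1s``.  All
    orthogonally adjacent pairs receive edge couplings with ``d_edge``.
    Diagonally adjacent pairs receive vertex couplings with ``dv``:

    * ``vertex_rule="cluster"`` (default): only the four cluster diagonals
      (``1s``–30, ``1s``–32, ``1'``–31, ``2'``–31).
    * ``vertex_rule="all_diagonals"``: every diagonal pair present in the
      lattice (adds ``1'``–29, ``2'``–33, ``1'``–``2s``, ``2'``–``2s``).
    """
    if d_edge < 0 or dv < 0:
        raise ValueError("coupling coefficients must be >= 0")
    if vertex_rule not in ("cluster", "all_diagonals"):
        raise ValueError(f"unknown vertex_rule {vertex_rule!r}")
    if n_backbone < 35 or n_branch < 2:
        raise ValueError("T structure needs a 35+ cell backbone and 2+ cell branch")

    mid = 31  # branch-bearing backbone cell
    cells = [Cell(str(i), i, 0) for i in range(1, n_backbone + 1)]
    cells += [Cell(f"{k}s", mid, k) for k in range(1, n_branch + 1)]
    cells += [Cell("1'", mid - 1, 1), Cell("2'", mid + 1, 1)]

    by_pos = {(c.column, c.row): c.label for c in cells}
    couplings: list[Coupling] = []
    for c in cells:
        for dc, dr in ((1, 0), (0, 1)):
            other = by_pos.get((c.column + dc, c.row + dr))
            if other is not None:
                couplings.append(Coupling(c.label, other, CouplingKind.EDGE, d_edge))

    vertex_pairs = list(CLUSTER_VERTEX_PAIRS)
    if vertex_rule == "all_diagonals":
        vertex_pairs += list(EXTRA_VERTEX_PAIRS)
    for a, b in vertex_pairs:
        couplings.append(Coupling(a, b, CouplingKind.VERTEX, dv))

    return CellNetwork(cells, couplings, architecture="t_structure")


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def _kind_for_positions(pa: tuple[int, int], pb: tuple[int, int]) -> CouplingKind | None:
    dc, dr = abs(pa[0] - pb[0]), abs(pa[1] - pb[1])
    if dc + dr == 1:
        return CouplingKind.EDGE
    if dc == 1 and dr == 1:
        return CouplingKind.VERTEX
    return None


def validate_network(net: CellNetwork) -> list[str]:
    """Check the structural invariants; return a list of violation messages.

    An empty list means the network is valid.  Violations name the offending
    cells or couplings; nothing is raised.
    """
    problems: list[str] = []

    seen_labels: dict[str, Cell] = {}
    seen_pos: dict[tuple[int, int], str] = {}
    for c in net.cells:
        if c.label in seen_labels:
            problems.append(f"duplicate cell label {c.label!r}")
        seen_labels[c.label] = c
        if c.position in seen_pos:
            problems.append(
                f"cells {seen_pos[c.position]!r} and {c.label!r} share position {c.position}"
            )
        else:
            seen_pos[c.position] = c.label

    for cp in net.couplings:
        if cp.a not in seen_labels or cp.b not in seen_labels:
            problems.append(f"coupling ({cp.a}, {cp.b}) references unknown cell")
            continue
        if cp.coefficient < 0:
            problems.append(
                f"coupling ({cp.a}, {cp.b}) has negative coefficient {cp.coefficient}"
            )
        expected = _kind_for_positions(
            seen_labels[cp.a].position, seen_labels[cp.b].position
        )
        if expected is None:
            problems.append(f"coupling ({cp.a}, {cp.b}) joins non-adjacent cells")
        elif expected is not cp.kind:
            problems.append(
                f"coupling ({cp.a}, {cp.b}) declared {cp.kind.value} but cells are "
                f"{expected.value}-adjacent"
            )

    if net.n_cells > 0:
        g = net.graph()
        if not nx.is_connected(g):
            comps = sorted(nx.connected_components(g), key=len)
            problems.append(
                f"network is disconnected; smallest component: {sorted(comps[0])}"
            )

    if net.architecture == "chain":
        degree = {c.label: 0 for c in net.cells}
        for cp in net.couplings:
            if cp.kind is not CouplingKind.EDGE:
                problems.append(
                    f"chain network contains a {cp.kind.value} coupling ({cp.a}, {cp.b})"
                )
            degree[cp.a] = degree.get(cp.a, 0) + 1
            degree[cp.b] = degree.get(cp.b, 0) + 1
        n = net.n_cells
        for c in net.cells:
            terminal = c.column in (1, n)
            want = 1 if terminal else 2
            if degree[c.label] != want:
                problems.append(
                    f"chain cell {c.label!r} has {degree[c.label]} couplings, expected {want}"
                )

    return problems


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def network_to_json(net: CellNetwork) -> str:
    doc = {
        "architecture": net.architecture,
        "cells": [
            {"label": c.label, "column": c.column, "row": c.row} for c in net.cells
        ],
        "couplings": [
            {"a": cp.a, "b": cp.b, "kind": cp.kind.value, "coefficient": cp.coefficient}
            for cp in net.couplings
        ],
    }
    return json.dumps(doc, indent=1)


def network_from_json(text: str) -> CellNetwork:
    doc = json.loads(text)
    cells = [Cell(d["label"], int(d["column"]), int(d["row"])) for d in doc["cells"]]
    couplings = [
        Coupling(d["a"], d["b"], CouplingKind(d["kind"]), float(d["coefficient"]))
        for d in doc["couplings"]
    ]
    return CellNetwork(cells, couplings, architecture=doc.get("architecture", "custom"))
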