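"""The four in-silico stimulation experiments and propagation classification.

* single stimulation of the middle cell of a 61-cell chain,
* simultaneous dual stimulation of a chain (two cells a short distance
  apart, relabelled 1…8 in the outputs for a separation of 7),
* single stimulation of the backbone of the "T" structure (cell 28),
* simultaneous dual stimulation of the "T" backbone (cells 28 and 34),

plus a sweep over the vertex diffusion coefficient that locates the
transition between junction-crossing and junction-blocked propagation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .dynamics import (
    ReactionParameters,
    SimulationResult,
    SimulationSettings,
    simulate,
)
from .network import CellNetwork, build_chain, build_t_structure

__all__ = [
    "StimulationProtocol",
    "PropagationOutcome",
    "run_chain_single",
    "run_chain_dual",
    "run_t_single",
    "run_t_dual",
    "classify_propagation",
    "sweep_dv",
    "SweepResult",
    "DEFAULT_C0",
    "BRANCH_SENTINEL",
]

#: Default initial concentration of a stimulated cell (above UC1, below UC2).
DEFAULT_C0 = 2.0

#: Mid-branch cell used to decide whether a wave entered the side branch:
#: far enough from the junction to exclude partial leakage, far from the
#: branch tip to exclude edge effects.
BRANCH_SENTINEL = "15s"


@dataclass(frozen=True)
class StimulationProtocol:
    """Mechano-stimulation modelled as an initial concentration assignment."""

    stimulated_cells: tuple[str, ...]
    initial_concentration: float = DEFAULT_C0
    simultaneous: bool = True

    def __post_init__(self) -> None:
        if not self.stimulated_cells:
            raise ValueError("at least one cell must be stimulated")
        if self.initial_concentration <= 0:
            raise ValueError("stimulus concentration must be positive")


@dataclass
class PropagationOutcome:
    """Classification of where a wave reached within the horizon."""

    activated_cells: set[str]
    reached_side_branch: bool
    reached_full_structure: bool
    blocking_location: str | None = None
    inconclusive: bool = False

    def __post_init__(self) -> None:
        if self.reached_full_structure and not self.reached_side_branch:
            raise ValueError("full-structure propagation implies side-branch propagation")


# ---------------------------------------------------------------------------
# chain protocols
# ---------------------------------------------------------------------------


def run_chain_single(
    p: ReactionParameters,
    s: SimulationSettings,
    d_edge: float,
    *,
    n_cells: int = 61,
    c0: float = DEFAULT_C0,
) -> SimulationResult:
    """Single stimulation of the middle-most cell of a chain.

    With the default 61 cells the stimulated cell is 31, far enough from the
    chain ends that boundary effects never reach the measured region.
    """
    net = build_chain(n_cells, d_edge)
    middle = str((n_cells + 1) // 2)
    stim = StimulationProtocol((middle,), c0)
    result = simulate(net, p, s, stim)
    result.metadata["protocol"] = "chain_single"
    return result


def run_chain_dual(
    p: ReactionParameters,
    s: SimulationSettings,
    d_edge: float,
    *,
    separation: int = 7,
    n_cells: int = 61,
    c0: float = DEFAULT_C0,
) -> SimulationResult:
    """Simultaneous dual stimulation of a chain.

    The two stimulated cells sit centrally, ``separation`` positions apart
    (``separation - 1`` cells between them).  For the default separation of
    7 on 61 cells the stimuli land on chain cells 28 and 35; outputs carry a
    relabelling of the stimulated segment to 1…8 so the stimulated cells are
    "1" and "8" with six cells between, matching the experimental layout.
    """
    if separation < 1:
        raise ValueError("separation must be >= 1")
    if separation > n_cells - 2:
        raise ValueError(
            f"separation {separation} too large for a {n_cells}-cell chain"
        )
    net = build_chain(n_cells, d_edge)
    lo = (n_cells + 1 - separation) // 2 + 1
    hi = lo + separation
    stim = StimulationProtocol((str(lo), str(hi)), c0)
    result = simulate(net, p, s, stim)
    result.metadata["protocol"] = "chain_dual"
    result.metadata["segment_labels"] = {
        str(lo + i): str(i + 1) for i in range(separation + 1)
    }
    return result


# ---------------------------------------------------------------------------
# T-structure protocols
# ---------------------------------------------------------------------------


def run_t_single(
    p: ReactionParameters,
    s: SimulationSettings,
    d_edge: float,
    dv: float,
    *,
    c0: float = DEFAULT_C0,
    vertex_rule: str = "cluster",
) -> tuple[SimulationResult, PropagationOutcome]:
    """Single stimulation of the T structure at backbone cell 28."""
    net = build_t_structure(d_edge, dv, vertex_rule=vertex_rule)
    stim = StimulationProtocol(("28",), c0)
    result = simulate(net, p, s, stim)
    result.metadata["protocol"] = "t_single"
    result.metadata["dv"] = dv
    return result, classify_propagation(result)


def run_t_dual(
    p: ReactionParameters,
    s: SimulationSettings,
    d_edge: float,
    dv: float,
    *,
    c0: float = DEFAULT_C0,
    vertex_rule: str = "cluster",
) -> tuple[SimulationResult, PropagationOutcome]:
    """Simultaneous dual stimulation of the T structure at backbone cells
    28 and 34 (symmetric about the branch-bearing cell 31)."""
    net = build_t_structure(d_edge, dv, vertex_rule=vertex_rule)
    stim = StimulationProtocol(("28", "34"), c0)
    result = simulate(net, p, s, stim)
    result.metadata["protocol"] = "t_dual"
    result.metadata["dv"] = dv
    return result, classify_propagation(result)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def classify_propagation(result: SimulationResult) -> PropagationOutcome:
    """Classify a run by which cells entered the refractory regime.

    * ``activated_cells``: cells whose regime reached refractory.
    * ``reached_side_branch``: the mid-branch sentinel cell activated (on a
      network without a side branch this falls back to full-structure
      propagation).
    * ``reached_full_structure``: every cell activated except the terminal
      (single-coupling) cells, which are allowed to fail from edge effects.
    * ``blocking_location``: when blocked, the non-activated cell closest
      (graph distance) to a stimulated cell.
    * ``inconclusive``: some cell activated within the last 5% of the
      horizon, i.e. the front may still have been advancing.
    """
    net = result.network
    activated = result.activated_labels()

    horizon = result.settings.n_steps * result.settings.dt
    finite = result.activation_times[np.isfinite(result.activation_times)]
    inconclusive = bool(finite.size) and bool(np.max(finite) > 0.95 * horizon)

    degree: dict[str, int] = {c.label: 0 for c in net.cells}
    for cp in net.couplings:
        degree[cp.a] += 1
        degree[cp.b] += 1
    terminals = {lab for lab, d in degree.items() if d <= 1}
    required = set(net.labels) - terminals
    reached_full = required <= activated

    if BRANCH_SENTINEL in net:
        reached_branch = BRANCH_SENTINEL in activated
    else:
        reached_branch = reached_full

    blocking = None
    if not reached_full:
        stim_cells = result.stimulus["stimulated_cells"]
        g = net.graph()
        dist: dict[str, int] = {}
        for src in stim_cells:
            for lab, d in nx.single_source_shortest_path_length(g, src).items():
                if lab not in dist or d < dist[lab]:
                    dist[lab] = d
        missing = [lab for lab in net.labels if lab not in activated]
        if missing:
            blocking = min(missing, key=lambda lab: (dist.get(lab, np.inf), lab))

    return PropagationOutcome(
        activated_cells=activated,
        reached_side_branch=reached_branch,
        reached_full_structure=reached_full,
        blocking_location=blocking,
        inconclusive=inconclusive,
    )


# ---------------------------------------------------------------------------
# vertex-coefficient sweep
# ---------------------------------------------------------------------------


@dataclass
class SweepResult:
    """Classified outcomes over a grid of vertex diffusion coefficients."""

    table: pd.DataFrame
    largest_propagating: float | None
    smallest_blocked: float | None

    def contiguous_prefix(self) -> bool:
        """True if side-branch propagation holds on a contiguous prefix of
        the grid (reported as a model finding, not assumed)."""
        flags = self.table["reached_side_branch"].to_numpy()
        seen_block = False
        for f in flags:
            if not f:
                seen_block = True
            elif seen_block:
                return False
        return True


def sweep_dv(
    p: ReactionParameters,
    s: SimulationSettings,
    d_edge: float,
    dv_grid: Sequence[float],
    mode: str = "single",
    *,
    c0: float = DEFAULT_C0,
    vertex_rule: str = "cluster",
) -> SweepResult:
    """Run one classified T-structure simulation per grid value.

    ``mode`` selects single (cell 28) or dual (cells 28 and 34) stimulation.
    The grid must be non-empty and sorted ascending.  Returns the per-value
    classification table together with the largest coefficient that still
    allowed side-branch propagation and the smallest that blocked it.
    """
    if mode not in ("single", "dual"):
        raise ValueError(f"mode must be 'single' or 'dual', got {mode!r}")
    dv_grid = list(dv_grid)
    if not dv_grid:
        raise ValueError("dv_grid must be non-empty")
    if any(b < a for a, b in zip(dv_grid, dv_grid[1:])):
        raise ValueError("dv_grid must be sorted ascending")

    runner = run_t_single if mode == "single" else run_t_dual
    rows = []
    for dv in dv_grid:
        _, outcome = runner(p, s, d_edge, dv, c0=c0, vertex_rule=vertex_rule)
        rows.append(
            {
                "dv": dv,
                "mode": mode,
                "reached_side_branch": outcome.reached_side_branch,
                "reached_full_structure": outcome.reached_full_structure,
                "n_activated": len(outcome.activated_cells),
                "blocking_location": outcome.blocking_location,
                "inconclusive": outcome.inconclusive,
            }
        )
    table = pd.DataFrame(rows)
    prop = table.loc[table["reached_side_branch"], "dv"]
    blocked = table.loc[~table["reached_side_branch"], "dv"]
    return SweepResult(
        table=table,
        largest_propagating=float(prop.max()) if len(prop) else None,
        smallest_blocked=float(blocked.min()) if len(blocked) else None,
    )
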