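"""Threshold-switched CICR dynamics and the explicit lattice integrator.

Each cell carries a cytosolic calcium concentration ``C`` (dimensionless)
evolving under two processes:

* **Intracellular reaction** ``f(C) = -k(C) * C`` where the release/intake
  rate constant ``k`` switches on two concentration thresholds:
  below ``UC1`` the ER absorbs calcium (``k1 > 0``, f < 0); between ``UC1``
  and ``UC2`` calcium-induced calcium release dominates (``k2 < 0``, f > 0);
  above ``UC2`` buffering/extrusion takes over (``k3 > 0``) and the cell
  locks into that refractory regime permanently — the model's refractory
  stage, which is what prevents colliding waves from crossing.

* **Intercellular diffusion** through gap junctions: a graph Laplacian on
  the cell network, with per-link coefficients from the network couplings.

Time stepping is synchronous and explicit: every right-hand-side term is
evaluated at the previous step.  Concentrations are clamped at zero from
below (clamping events are counted).

Scaling convention
------------------
The model is calibrated so that with the default parameter table the wave
crosses one cell per 0.87 dimensionless time units.  This fixes how the
tabulated coefficients enter one update of length ``dt``:

* diffusion coefficients are rates per unit dimensionless time — each link
  contributes ``coeff * dt * (C_j - C_i)`` per step;
* the tabulated rate constants are per-step dimensionless increments —
  the reaction contributes ``-k * C`` per step, with no extra ``dt``.

Both choices can be overridden (``SimulationSettings.diffusion_per_step``,
``reaction_per_step``) for numerical experiments; the defaults are the
calibrated convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from enum import IntEnum
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

import numpy as np
import pandas as pd
import yaml

from .network import CellNetwork

if TYPE_CHECKING:  # pragma: no cover
    from .protocols import StimulationProtocol

__all__ = [
    "RateRegime",
    "CellRateState",
    "ReactionParameters",
    "SimulationSettings",
    "SimulationState",
    "SimulationResult",
    "IntegrationInstabilityError",
    "rate_constant",
    "reaction_rate",
    "step",
    "simulate",
    "default_parameters",
    "load_config",
]


class RateRegime(IntEnum):
    """The three branches of the piecewise rate constant."""

    INTAKE_LOW = 0  # C < UC1, k = k1 (ER intake)
    RELEASE = 1  # UC1 <= C <= UC2, k = k2 < 0 (CICR release)
    REFRACTORY = 2  # C > UC2 reached at least once, k = k3 forever


@dataclass
class CellRateState:
    regime: RateRegime = RateRegime.INTAKE_LOW
    locked: bool = False


@dataclass(frozen=True)
class ReactionParameters:
    """Dimensionless CICR parameters (defaults are the calibrated table).

    ``uc1``/``uc2`` are the lower and upper concentration thresholds; ``k1``,
    ``k2``, ``k3`` the rate constants below, between and above them.  ``k2``
    is negative (release); once a cell's concentration exceeds ``uc2`` its
    rate constant stays ``k3`` indefinitely (permanent refractory lock).
    """

    uc1: float = 0.3
    uc2: float = 3.0
    k1: float = 0.03
    k2: float = -0.025
    k3: float = 0.0045

    def __post_init__(self) -> None:
        if not 0 < self.uc1 < self.uc2:
            raise ValueError(f"thresholds must satisfy 0 < uc1 < uc2, got {self.uc1}, {self.uc2}")
        if self.k1 <= 0 or self.k3 <= 0:
            raise ValueError("k1 and k3 must be positive (intake)")
        if self.k2 >= 0:
            raise ValueError("k2 must be negative (release)")

    def k_table(self) -> np.ndarray:
        return np.array([self.k1, self.k2, self.k3])


@dataclass(frozen=True)
class SimulationSettings:
    """Integration controls.

    ``dt`` is the dimensionless time step; ``n_steps`` the horizon;
    ``record_every`` the recording stride.  The two convention flags select
    how the tabulated coefficients scale with ``dt`` (see module docstring);
    the defaults are the calibrated convention.
    """

    dt: float = 0.01
    n_steps: int = 15_000
    record_every: int = 1
    diffusion_per_step: bool = False
    reaction_per_step: bool = True

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_steps < 1 or self.record_every < 1:
            raise ValueError("n_steps and record_every must be >= 1")


class IntegrationInstabilityError(RuntimeError):
    """Raised when the explicit update produces a non-finite concentration."""

    def __init__(self, step_index: int):
        self.step_index = step_index
        super().__init__(
            f"non-finite concentration at step {step_index}; "
            "the explicit scheme is unstable for these coefficients"
        )


# ---------------------------------------------------------------------------
# scalar operations
# ---------------------------------------------------------------------------


def rate_constant(
    c: float, state: CellRateState, p: ReactionParameters
) -> tuple[float, CellRateState]:
    """Rate constant for one cell at concentration ``c``, updating its state.

    The regime is memoryless in ``c`` except for the permanent refractory
    lock: once ``c`` strictly exceeds ``uc2`` the cell keeps ``k3`` forever.
    A concentration exactly at a threshold belongs to the release regime.
    """
    if c < 0:
        raise ValueError(f"concentration must be >= 0, got {c}")
    if state.locked:
        return p.k3, CellRateState(RateRegime.REFRACTORY, True)
    if c > p.uc2:
        return p.k3, CellRateState(RateRegime.REFRACTORY, True)
    if c < p.uc1:
        return p.k1, CellRateState(RateRegime.INTAKE_LOW, False)
    return p.k2, CellRateState(RateRegime.RELEASE, False)


def reaction_rate(c: float, k: float) -> float:
    """Reaction term ``f = -k * c``: negative for intake (k > 0), positive
    during CICR release (k < 0)."""
    if c < 0:
        raise ValueError(f"concentration must be >= 0, got {c}")
    return -k * c


# ---------------------------------------------------------------------------
# vectorized kernel
# ---------------------------------------------------------------------------


def _regimes(c: np.ndarray, locked: np.ndarray, p: ReactionParameters) -> np.ndarray:
    reg = np.where(c < p.uc1, RateRegime.INTAKE_LOW, RateRegime.RELEASE).astype(np.int8)
    reg[c > p.uc2] = RateRegime.REFRACTORY
    reg[locked] = RateRegime.REFRACTORY
    return reg


class _Kernel:
    """Precomputed update operator for one network + parameter set."""

    def __init__(self, net: CellNetwork, p: ReactionParameters, s: SimulationSettings):
        w = net.coupling_matrix()
        self.w = w if s.diffusion_per_step else w * s.dt
        self.degree = self.w.sum(axis=1)
        self.react_scale = 1.0 if s.reaction_per_step else s.dt
        self.p = p
        self.k_table = p.k_table()

    def advance(
        self,
        c: np.ndarray,
        locked: np.ndarray,
        include_reaction: bool = True,
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
        """One synchronous step from pre-step (c, locked).

        Returns (new_c, new_locked, pre_step_regimes, n_clamped).  The lock
        and the regimes are evaluated from the pre-step concentrations.
        """
        new_locked = locked | (c > self.p.uc2)
        reg = _regimes(c, new_locked, self.p)
        with np.errstate(over="ignore", invalid="ignore"):
            out = c + self.w @ c - self.degree * c
            if include_reaction:
                out = out - self.react_scale * self.k_table[reg] * c
            n_clamped = int(np.count_nonzero(out < 0))
            np.clip(out, 0.0, None, out=out)
        return out, new_locked, reg, n_clamped


@dataclass
class SimulationState:
    """Per-cell concentrations and refractory locks, aligned with a network's
    cell order."""

    concentrations: np.ndarray
    locked: np.ndarray

    @classmethod
    def initial(cls, net: CellNetwork) -> "SimulationState":
        n = net.n_cells
        return cls(np.zeros(n), np.zeros(n, dtype=bool))


def step(
    state: SimulationState,
    net: CellNetwork,
    p: ReactionParameters,
    s: SimulationSettings,
    *,
    include_reaction: bool = True,
) -> SimulationState:
    """One synchronous explicit update of ``state`` on ``net``.

    ``include_reaction=False`` disables the reaction term (diffusion only),
    which is useful for conservation checks.
    """
    if state.concentrations.shape[0] != net.n_cells:
        raise ValueError("state does not cover every cell of the network")
    kern = _Kernel(net, p, s)
    c, locked, _, _ = kern.advance(state.concentrations, state.locked, include_reaction)
    if not np.all(np.isfinite(c)):
        raise IntegrationInstabilityError(0)
    return SimulationState(c, locked)


# ---------------------------------------------------------------------------
# full simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulationResult:
    """Recorded trajectories of one simulation run.

    ``concentrations``/``regimes`` have shape (n_recorded_times, n_cells)
    with cells ordered as in ``network.labels``.  ``activation_times`` holds
    the dimensionless time at which each cell entered the refractory regime
    (NaN if it never fired).
    """

    times: np.ndarray
    concentrations: np.ndarray
    regimes: np.ndarray
    activation_times: np.ndarray
    network: CellNetwork
    reaction: ReactionParameters
    settings: SimulationSettings
    stimulus: dict
    n_clamped: int = 0
    metadata: dict = field(default_factory=dict)

    @property
    def labels(self) -> list[str]:
        return self.network.labels

    def trace(self, label: str) -> np.ndarray:
        return self.concentrations[:, self.network.index_of(label)]

    def activated_labels(self) -> set[str]:
        """Cells whose rate regime reached refractory within the horizon."""
        return {
            lab
            for lab, t in zip(self.labels, self.activation_times)
            if np.isfinite(t)
        }

    def to_frame(self) -> pd.DataFrame:
        n_t, n_c = self.concentrations.shape
        return pd.DataFrame(
            {
                "time": np.repeat(self.times, n_c),
                "cell_label": np.tile(np.array(self.labels, dtype=object), n_t),
                "concentration": self.concentrations.ravel(),
                "regime": self.regimes.ravel(),
            }
        )

    def provenance(self) -> dict:
        return {
            "reaction": asdict(self.reaction),
            "settings": asdict(self.settings),
            "stimulus": self.stimulus,
            "network": {
                "architecture": self.network.architecture,
                "n_cells": self.network.n_cells,
            },
            "n_clamped": self.n_clamped,
            **self.metadata,
        }

    def save(self, prefix: str | Path) -> None:
        """Write a tidy CSV of the trajectories plus a JSON parameter sidecar."""
        import json

        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(prefix.with_suffix(".csv"), index=False)
        prefix.with_suffix(".json").write_text(json.dumps(self.provenance(), indent=1))


def simulate(
    net: CellNetwork,
    p: ReactionParameters,
    s: SimulationSettings,
    stimulus: "StimulationProtocol",
) -> SimulationResult:
    """Run the CICR reaction-diffusion model on ``net``.

    All cells start at concentration 0 except the stimulated cells, which
    start at the stimulus concentration.  The run is deterministic and
    bit-reproducible for fixed inputs.
    """
    for lab in stimulus.stimulated_cells:
        if lab not in net:
            raise ValueError(f"stimulated cell {lab!r} is not in the network")

    kern = _Kernel(net, p, s)
    n = net.n_cells
    c = np.zeros(n)
    for lab in stimulus.stimulated_cells:
        c[net.index_of(lab)] = stimulus.initial_concentration
    locked = np.zeros(n, dtype=bool)
    activation = np.full(n, np.nan)

    n_rec = s.n_steps // s.record_every + 1
    rec_c = np.empty((n_rec, n))
    rec_reg = np.empty((n_rec, n), dtype=np.int8)
    rec_t = np.empty(n_rec)
    n_clamped = 0
    r = 0
    for step_i in range(s.n_steps + 1):
        newly = (~locked) & (c > p.uc2)
        if newly.any():
            activation[newly] = step_i * s.dt
            locked = locked | newly
        if step_i % s.record_every == 0:
            rec_t[r] = step_i * s.dt
            rec_c[r] = c
            rec_reg[r] = _regimes(c, locked, p)
            r += 1
        if step_i == s.n_steps:
            break
        c, locked, _, clamped = kern.advance(c, locked)
        n_clamped += clamped
        if not np.all(np.isfinite(c)):
            raise IntegrationInstabilityError(step_i + 1)

    return SimulationResult(
        times=rec_t[:r],
        concentrations=rec_c[:r],
        regimes=rec_reg[:r],
        activation_times=activation,
        network=net,
        reaction=p,
        settings=s,
        stimulus={
            "stimulated_cells": list(stimulus.stimulated_cells),
            "initial_concentration": stimulus.initial_concentration,
        },
        n_clamped=n_clamped,
    )


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


def default_parameters() -> dict:
    """The calibrated parameter block as a plain dict (YAML-serializable)."""
    return {
        "c0": 2.0,
        "uc1": 0.3,
        "uc2": 3.0,
        "k1": 0.03,
        "k2": -0.025,
        "k3": 0.0045,
        "dt": 0.01,
        "d_edge": 0.6,
        "n_steps": 15_000,
        "record_every": 1,
        "diffusion_per_step": False,
        "reaction_per_step": True,
    }


def load_config(path: str | Path | None) -> dict:
    """Merge a YAML/JSON config file over the default parameter block."""
    params = default_parameters()
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(loaded) - set(params)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        params.update(loaded)
    return params


def settings_from_config(cfg: dict, **overrides) -> SimulationSettings:
    base = SimulationSettings(
        dt=cfg["dt"],
        n_steps=cfg["n_steps"],
        record_every=cfg["record_every"],
        diffusion_per_step=cfg["diffusion_per_step"],
        reaction_per_step=cfg["reaction_per_step"],
    )
    return replace(base, **overrides) if overrides else base


def reaction_from_config(cfg: dict) -> ReactionParameters:
    return ReactionParameters(
        uc1=cfg["uc1"], uc2=cfg["uc2"], k1=cfg["k1"], k2=cfg["k2"], k3=cfg["k3"]
    )
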