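"""Wave descriptors extracted from simulated trajectories, and the
dimensionless-to-physical calibration.

The response time of a cell is the time at which its concentration attains
its maximum positive rate of change — the same fiducial used on measured
fluorescence traces, so simulated and experimental propagation times are
directly comparable.  A threshold-crossing fiducial is provided as an
option; on a steadily travelling wave the two give identical cell-to-cell
differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import find_peaks

from .dynamics import SimulationResult

__all__ = [
    "Calibration",
    "WaveReport",
    "InsufficientDataError",
    "response_time_from_trajectory",
    "cell_to_cell_time",
    "spatial_extent",
    "detect_crossing",
    "calibrate",
    "wave_report",
]

log = logging.getLogger(__name__)

#: Free cytosolic Ca2+ diffusion coefficient measured in Xenopus oocyte
#: extract, ~2.2e-10 m^2/s; used only as a sanity band for the calibrated
#: physical diffusion coefficient.
LITERATURE_CA_DIFFUSION_M2_S = 2.2e-10


class InsufficientDataError(ValueError):
    """Too few responding cells to compute a propagation statistic."""


# ---------------------------------------------------------------------------
# response times
# ---------------------------------------------------------------------------


def response_time_from_trajectory(
    times: np.ndarray,
    values: np.ndarray,
    *,
    method: str = "max_rate",
    threshold: float | None = None,
) -> float | None:
    """Response time of a single trace, or ``None`` if it never responds.

    ``method="max_rate"`` (default): the time of the maximum positive first
    difference of consecutive samples, stamped at the trailing sample; ties
    resolve to the earliest occurrence.  Returns ``None`` when no first
    difference is positive (monotone-decaying or flat trace).

    ``method="threshold"``: the first time the trace strictly exceeds
    ``threshold``.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError(f"trace needs >= 3 samples, got {values.size}")
    if method == "max_rate":
        diffs = np.diff(values)
        i = int(np.argmax(diffs))
        if diffs[i] <= 0:
            return None
        return float(times[i + 1])
    if method == "threshold":
        if threshold is None:
            raise ValueError("threshold method needs a threshold")
        above = np.nonzero(values > threshold)[0]
        return float(times[above[0]]) if above.size else None
    raise ValueError(f"unknown method {method!r}")


def cell_to_cell_time(response_times: Sequence[float]) -> tuple[np.ndarray, float]:
    """Per-pair differences of consecutive response times along a path, and
    their mean.  Requires at least two responding cells."""
    rts = [t for t in response_times if t is not None and np.isfinite(t)]
    if len(rts) < 2:
        raise InsufficientDataError(
            f"need >= 2 responding cells on the path, got {len(rts)}"
        )
    diffs = np.diff(np.asarray(rts, dtype=float))
    return diffs, float(diffs.mean())


# ---------------------------------------------------------------------------
# pulse geometry
# ---------------------------------------------------------------------------


def spatial_extent(
    result: SimulationResult,
    threshold: float,
    cells: Sequence[str] | None = None,
) -> int:
    """Maximum, over recorded times, of the longest contiguous run of cells
    whose concentration exceeds ``threshold``.

    ``cells`` restricts and orders the profile (e.g. one side of the
    stimulated cell, to measure a single travelling pulse rather than the
    merged pair of nascent counter-propagating pulses).  By default all
    cells are used in column order, which requires a single-chain result.
    """
    net = result.network
    if cells is None:
        if any(c.row != 0 for c in net.cells):
            raise ValueError("default cell ordering requires a single-chain result")
        order = [c.label for c in sorted(net.cells, key=lambda c: c.column)]
    else:
        order = list(cells)
    idx = [net.index_of(lab) for lab in order]
    above = result.concentrations[:, idx] > threshold

    best = 0
    for row in above:
        run = 0
        for flag in row:
            run = run + 1 if flag else 0
            if run > best:
                best = run
    return best


def detect_crossing(
    result: SimulationResult,
    *,
    noise_floor_frac: float = 0.1,
) -> tuple[bool, list[tuple[str, float]]]:
    """Did either wave of a dual-stimulus chain run pass the opposing wave?

    A crossing would show as a second distinct activation episode — a second
    local maximum of the positive rate of change, separated from the first
    by a decaying phase and exceeding ``noise_floor_frac`` of the cell's
    first-pulse peak rate — in a cell on the far side of a stimulated cell.
    The small tail hump that discrete diffusion produces in already-fired
    cells stays below that floor and is not counted.

    Returns the verdict and the evidence list of (cell, time) candidates.
    """
    stim = result.stimulus["stimulated_cells"]
    if len(stim) != 2:
        raise ValueError("crossing detection requires a dual-stimulus run")
    net = result.network
    if any(c.row != 0 for c in net.cells):
        raise ValueError("crossing detection is defined on chain results")

    lo = min(net.cell(s).column for s in stim)
    hi = max(net.cell(s).column for s in stim)
    outside = [c.label for c in net.cells if c.column < lo or c.column > hi]

    evidence: list[tuple[str, float]] = []
    for lab in outside:
        trace = result.trace(lab)
        rate = np.diff(trace)
        i_main = int(np.argmax(rate))
        r_main = rate[i_main]
        if r_main <= 0:
            continue  # never rose: no first pulse, nothing to cross
        floor = noise_floor_frac * r_main
        # positive-rate episodes separated by non-rising phases
        rising = rate > 0
        boundaries = np.nonzero(np.diff(rising.astype(int)))[0] + 1
        segments = np.split(np.arange(rate.size), boundaries)
        main_seen = False
        for seg in segments:
            if seg.size == 0 or not rising[seg[0]]:
                continue
            peak_i = seg[int(np.argmax(rate[seg]))]
            if not main_seen:
                if i_main in seg:
                    main_seen = True
                continue
            if rate[peak_i] >= floor:
                evidence.append((lab, float(result.times[peak_i + 1])))
    return bool(evidence), evidence


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Calibration:
    """Mapping between dimensionless model units and physical units.

    ``time_conversion_s`` is the number of seconds per dimensionless time
    unit, fixed by matching the simulated and experimental cell-to-cell
    propagation times; ``cell_spacing_um`` maps one lattice unit to µm.
    """

    cell_spacing_um: float
    experimental_cell_time_s: float
    simulated_cell_time: float
    time_conversion_s: float
    effective_step_s: float
    speed_um_per_s: float
    physical_diffusion_m2_s: float

    def to_seconds(self, t: np.ndarray | float) -> np.ndarray | float:
        return t * self.time_conversion_s

    def to_dimensionless(self, t_s: np.ndarray | float) -> np.ndarray | float:
        return t_s / self.time_conversion_s


def calibrate(
    simulated_cell_time: float,
    experimental_cell_time_s: float = 1.8,
    cell_spacing_um: float = 31.2,
    dt: float = 0.01,
    d_edge: float = 0.6,
) -> Calibration:
    """Build the physical calibration from the two cell-to-cell times.

    ``time_conversion = experimental / simulated`` seconds per dimensionless
    unit; the effective integration step is ``dt`` times that; the wave
    speed is spacing over experimental cell time; the physical diffusion
    coefficient converts the dimensionless edge coefficient (a rate per unit
    dimensionless time over one cell spacing) into m²/s.
    """
    for name, v in [
        ("simulated_cell_time", simulated_cell_time),
        ("experimental_cell_time_s", experimental_cell_time_s),
        ("cell_spacing_um", cell_spacing_um),
        ("dt", dt),
    ]:
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    conv = experimental_cell_time_s / simulated_cell_time
    spacing_m = cell_spacing_um * 1e-6
    physical_d = d_edge * spacing_m**2 / conv
    band = (LITERATURE_CA_DIFFUSION_M2_S / 10, LITERATURE_CA_DIFFUSION_M2_S * 10)
    if not band[0] <= physical_d <= band[1]:
        log.warning(
            "calibrated diffusion coefficient %.3g m^2/s is more than an order "
            "of magnitude away from the literature cytosolic value %.3g m^2/s",
            physical_d,
            LITERATURE_CA_DIFFUSION_M2_S,
        )
    return Calibration(
        cell_spacing_um=cell_spacing_um,
        experimental_cell_time_s=experimental_cell_time_s,
        simulated_cell_time=simulated_cell_time,
        time_conversion_s=conv,
        effective_step_s=dt * conv,
        speed_um_per_s=cell_spacing_um / experimental_cell_time_s,
        physical_diffusion_m2_s=physical_d,
    )


# ---------------------------------------------------------------------------
# assembled report
# ---------------------------------------------------------------------------


@dataclass
class WaveReport:
    """Per-cell response times and derived propagation descriptors."""

    response_times: dict[str, float | None]
    pair_times: list[tuple[str, str, float]]
    mean_cell_time: float
    spatial_extent_cells: int
    crossing_detected: bool | None
    calibration: Calibration | None = None

    @property
    def speed_um_per_s(self) -> float | None:
        return self.calibration.speed_um_per_s if self.calibration else None

    def to_dict(self) -> dict:
        out = {
            "response_times": self.response_times,
            "pair_times": [
                {"a": a, "b": b, "delta": d} for a, b, d in self.pair_times
            ],
            "mean_cell_time": self.mean_cell_time,
            "spatial_extent_cells": self.spatial_extent_cells,
            "crossing_detected": self.crossing_detected,
        }
        if self.calibration is not None:
            cal = self.calibration
            out["calibration"] = {
                "time_conversion_s": cal.time_conversion_s,
                "cell_spacing_um": cal.cell_spacing_um,
                "speed_um_per_s": cal.speed_um_per_s,
                "physical_diffusion_m2_s": cal.physical_diffusion_m2_s,
            }
            out["response_times_s"] = {
                lab: (None if t is None else t * cal.time_conversion_s)
                for lab, t in self.response_times.items()
            }
            out["mean_cell_time_s"] = self.mean_cell_time * cal.time_conversion_s
        return out

    def save(self, prefix) -> None:
        import json
        from pathlib import Path

        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        prefix.with_suffix(".json").write_text(json.dumps(self.to_dict(), indent=1))
        import pandas as pd

        pd.DataFrame(
            self.pair_times, columns=["a", "b", "delta"]
        ).to_csv(prefix.with_suffix(".csv"), index=False)


def wave_report(
    result: SimulationResult,
    path: Sequence[str],
    *,
    calibration: Calibration | None = None,
    extent_threshold: float | None = None,
    extent_cells: Sequence[str] | None = None,
) -> WaveReport:
    """Assemble a :class:`WaveReport` for the cells along ``path``.

    Response times use the maximum-rate fiducial and are ``None`` for cells
    that never activated (regime never left low-concentration intake).
    ``extent_threshold`` defaults to the lower CICR threshold ``uc1``.
    """
    activated = result.activated_labels()
    rts: dict[str, float | None] = {}
    for lab in path:
        if lab not in activated:
            rts[lab] = None
            continue
        rts[lab] = response_time_from_trajectory(result.times, result.trace(lab))

    pair_times = [
        (a, b, rts[b] - rts[a])
        for a, b in zip(path, path[1:])
        if rts[a] is not None and rts[b] is not None
    ]
    diffs, mean = cell_to_cell_time([rts[lab] for lab in path])

    threshold = result.reaction.uc1 if extent_threshold is None else extent_threshold
    try:
        extent = spatial_extent(result, threshold, cells=extent_cells)
    except ValueError:
        extent = spatial_extent(result, threshold, cells=list(path))

    crossing: bool | None = None
    if len(result.stimulus["stimulated_cells"]) == 2:
        crossing, _ = detect_crossing(result)

    return WaveReport(
        response_times=rts,
        pair_times=pair_times,
        mean_cell_time=mean,
        spatial_extent_cells=extent,
        crossing_detected=crossing,
        calibration=calibration,
    )
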