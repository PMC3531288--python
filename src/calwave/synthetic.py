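"""Seeded generation of experiment-style fluorescence trace sets.

The generator emulates the statistical structure of dye-based calcium
recordings on patterned cell chains: pulse-shaped responses (piecewise
linear rise, exponential decay), cell-to-cell onset lags with bounded
multiplicative variability, a finite propagation range, per-cell intensity
scale variation, a background offset, additive Gaussian noise on the
normalized scale, and uniform sampling (default 1.2 s).

Every random quantity flows through one ``numpy`` generator seeded from the
spec, so a fixed seed reproduces the trace set bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dynamics import SimulationResult
from .metrics import Calibration, response_time_from_trajectory
from .traces import FluorescenceTraceSet

__all__ = ["TraceGeneratorSpec", "GroundTruth", "generate", "from_simulation"]


@dataclass(frozen=True)
class TraceGeneratorSpec:
    """Parameters of one synthetic recording.

    ``mean_lag`` is the mean cell-to-cell onset lag; individual lags are
    uniform on ``mean_lag * [2/(1+d), 2d/(1+d)]`` with ``d = lag_dispersion``,
    so the mean is preserved while the extreme lags differ by the factor
    ``d`` (default 2).  ``propagation_range``/``propagation_range_sd``
    control how many cells beyond the stimulated cell respond (Gaussian,
    rounded).  ``amplitude`` is the pulse height above the unit baseline on
    the normalized-intensity scale and ``noise_sd`` the additive noise
    standard deviation on that same scale, so amplitude/noise_sd is the
    signal-to-noise ratio.
    """

    n_cells: int = 9
    stimulated: tuple[int, ...] = (4,)  # 1-based cell indices
    mean_lag: float = 1.8
    lag_dispersion: float = 2.0
    rise_time: float = 3.0
    decay_time: float = 12.0
    amplitude: float = 1.0
    noise_sd: float = 0.05
    sample_interval: float = 1.2
    propagation_range: float = 4.7
    propagation_range_sd: float = 1.1
    baseline_duration: float = 6.0
    duration: float = 60.0
    background_level: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 2:
            raise ValueError("need at least 2 cells")
        if not self.stimulated or any(
            not 1 <= i <= self.n_cells for i in self.stimulated
        ):
            raise ValueError("stimulated indices must lie in 1..n_cells")
        if not 0 < self.rise_time < self.decay_time:
            raise ValueError("need 0 < rise_time < decay_time")
        for name in ("mean_lag", "sample_interval", "duration", "amplitude"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.lag_dispersion < 1:
            raise ValueError("lag_dispersion must be >= 1")
        if self.noise_sd < 0 or self.propagation_range < 0:
            raise ValueError("noise_sd and propagation_range must be >= 0")


@dataclass
class GroundTruth:
    """What the generator actually produced, for recovery tests."""

    response_times: dict[str, float | None]
    responders: set[str]
    pair_lags: dict[tuple[str, str], float]

    @property
    def mean_lag(self) -> float:
        return float(np.mean(list(self.pair_lags.values())))


def _pulse(t: np.ndarray, onset: float, rise: float, amplitude: float, decay: float) -> np.ndarray:
    """Unit-baseline pulse: linear rise to ``amplitude`` over ``rise``, then
    exponential decay with time constant ``decay/3`` (≈95% decayed by
    ``decay`` after the peak)."""
    tau = decay / 3.0
    out = np.zeros_like(t)
    rising = (t >= onset) & (t < onset + rise)
    out[rising] = amplitude * (t[rising] - onset) / rise
    falling = t >= onset + rise
    out[falling] = amplitude * np.exp(-(t[falling] - onset - rise) / tau)
    return out


def generate(spec: TraceGeneratorSpec) -> tuple[FluorescenceTraceSet, GroundTruth]:
    """Generate one raw (unnormalized) trace set plus its ground truth.

    Onsets spread outward from each stimulated cell with independent
    per-pair lags; cells farther than the (per-direction, random) range do
    not respond; each cell's intensity has its own arbitrary scale so that
    only normalized traces are comparable across cells.  The true response
    time of a responder is the midpoint of its linear rise, where the
    sampled rate of change peaks in expectation.
    """
    rng = np.random.default_rng(spec.seed)
    labels = [str(i) for i in range(1, spec.n_cells + 1)]
    t = np.arange(0.0, spec.duration, spec.sample_interval)

    lo = 2.0 / (1.0 + spec.lag_dispersion)
    hi = 2.0 * spec.lag_dispersion / (1.0 + spec.lag_dispersion)

    # onset of each cell = earliest arrival over all stimulated cells
    onsets = np.full(spec.n_cells, np.inf)
    pair_lags: dict[tuple[str, str], float] = {}
    for origin in spec.stimulated:
        o = origin - 1
        reach = {
            +1: max(0, round(rng.normal(spec.propagation_range, spec.propagation_range_sd))),
            -1: max(0, round(rng.normal(spec.propagation_range, spec.propagation_range_sd))),
        }
        onsets[o] = min(onsets[o], spec.baseline_duration)
        for direction in (+1, -1):
            cum = spec.baseline_duration
            steps = 0
            i = o
            while 0 <= i + direction < spec.n_cells and steps < reach[direction]:
                lag = spec.mean_lag * rng.uniform(lo, hi)
                cum += lag
                i += direction
                steps += 1
                if cum < onsets[i]:
                    onsets[i] = cum
                    pair_lags[(labels[i - direction], labels[i])] = lag

    responders = {labels[i] for i in range(spec.n_cells) if np.isfinite(onsets[i])}
    pair_lags = {
        (a, b): lag for (a, b), lag in pair_lags.items() if a in responders and b in responders
    }

    data = {}
    background = np.full(t.size, spec.background_level)
    for i, lab in enumerate(labels):
        intensity = np.ones_like(t)
        if lab in responders:
            intensity += _pulse(t, onsets[i], spec.rise_time, spec.amplitude, spec.decay_time)
        if spec.noise_sd > 0:
            intensity = intensity + rng.normal(0.0, spec.noise_sd, t.size)
        scale = rng.uniform(50.0, 150.0)
        data[lab] = background + scale * intensity

    truth = GroundTruth(
        response_times={
            lab: (onsets[i] + spec.rise_time / 2 if lab in responders else None)
            for i, lab in enumerate(labels)
        },
        responders=responders,
        pair_lags=pair_lags,
    )
    ts = FluorescenceTraceSet(
        sample_times=t,
        traces=pd.DataFrame(data),
        background=background,
        normalized=False,
    )
    return ts, truth


def from_simulation(
    result: SimulationResult,
    calibration: Calibration,
    noise_sd: float = 0.05,
    sample_interval: float = 1.2,
    seed: int = 0,
    baseline_duration: float = 6.0,
) -> tuple[FluorescenceTraceSet, GroundTruth]:
    """Turn a simulated run into an experiment-style trace set.

    Times convert to seconds through the calibration; trajectories are
    linearly resampled at ``sample_interval``; concentration maps affinely
    to normalized intensity as ``I = 1 + C / C0`` (unit resting baseline).
    A resting baseline of ``baseline_duration`` seconds precedes the
    stimulus, as in a recording started before probing, so every trace
    starts at intensity 1.  Gaussian noise is added on the normalized
    scale.  The ground truth comes from the unnoised resampled traces:
    responders are the cells that entered the refractory regime, response
    times their maximum-rate times in seconds.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    times_s = np.asarray(calibration.to_seconds(result.times), dtype=float)
    recorded_step = float(times_s[1] - times_s[0])
    if sample_interval < recorded_step:
        raise ValueError(
            f"sample_interval {sample_interval} s is finer than the recorded "
            f"resolution {recorded_step:.4g} s"
        )
    rng = np.random.default_rng(seed)
    c0 = result.stimulus["initial_concentration"]
    grid = np.arange(0.0, baseline_duration + times_s[-1] + 1e-9, sample_interval)
    shifted = grid - baseline_duration

    clean = {}
    for lab in result.labels:
        resampled = np.interp(shifted, times_s, result.trace(lab))
        resampled[shifted < 0] = 0.0
        clean[lab] = 1.0 + resampled / c0

    activated = result.activated_labels()
    truth = GroundTruth(
        response_times={
            lab: (
                response_time_from_trajectory(grid, clean[lab])
                if lab in activated
                else None
            )
            for lab in result.labels
        },
        responders=activated,
        pair_lags={},
    )

    background = np.zeros(grid.size)
    noisy = {
        lab: v + rng.normal(0.0, noise_sd, grid.size) if noise_sd > 0 else v.copy()
        for lab, v in clean.items()
    }
    ts = FluorescenceTraceSet(
        sample_times=grid,
        traces=pd.DataFrame(noisy),
        background=background,
        normalized=True,
    )
    return ts, truth
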