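"""Analysis of fluorescence time series, mirroring the wet-lab procedure.

Whole-cell intensities are background-corrected and normalized by the
initial corrected intensity.  A cell counts as a responder when its trace
shows a pulse — a fast rise above the pre-rise baseline followed by a
slower decline — irrespective of absolute magnitude.  The response time is
the time of the maximum positive rate of change of the trace; for weak,
noisy responses a running average of the rate over four sampling intervals
is used instead, at the cost of a larger timing uncertainty (one full
sampling interval instead of half).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .metrics import InsufficientDataError

__all__ = [
    "FluorescenceTraceSet",
    "ResponseCall",
    "PropagationStats",
    "normalize",
    "call_response",
    "running_average_rate",
    "propagation_stats",
    "read_traces_csv",
    "write_traces_csv",
]

#: Column name reserved for the background trace in CSV files.
BACKGROUND_COLUMN = "background"

#: Default smoothing window (in sampling intervals) for weak signals.
RUNNING_AVERAGE_WINDOW = 4


@dataclass
class FluorescenceTraceSet:
    """Uniformly sampled per-cell intensity traces plus a background trace."""

    sample_times: np.ndarray
    traces: pd.DataFrame  # one column per cell label
    background: np.ndarray
    normalized: bool = False
    unusable: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if len(self.traces) != self.sample_times.size:
            raise ValueError("traces and sample_times disagree in length")
        if self.background.size != self.sample_times.size:
            raise ValueError("background and sample_times disagree in length")
        steps = np.diff(self.sample_times)
        if steps.size and not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise ValueError("sampling must be uniform")

    @property
    def cell_labels(self) -> list[str]:
        return [str(c) for c in self.traces.columns]

    @property
    def sample_interval(self) -> float:
        return float(self.sample_times[1] - self.sample_times[0])

    def trace(self, label: str) -> np.ndarray:
        return self.traces[label].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def normalize(raw: FluorescenceTraceSet) -> FluorescenceTraceSet:
    """Background-correct and normalize every trace by its initial value.

    Each trace becomes ``(trace - background) / (first corrected sample)``.
    Traces whose initial corrected intensity is not positive cannot be
    normalized; they are flagged unusable (and left as NaN) rather than
    aborting the whole set.
    """
    if raw.normalized:
        raise ValueError("trace set is already normalized")
    corrected = raw.traces.to_numpy(dtype=float) - raw.background[:, None]
    first = corrected[0]
    unusable = set(raw.unusable)
    out = np.full_like(corrected, np.nan)
    for j, lab in enumerate(raw.cell_labels):
        if first[j] <= 0:
            unusable.add(lab)
            continue
        out[:, j] = corrected[:, j] / first[j]
    return FluorescenceTraceSet(
        sample_times=raw.sample_times.copy(),
        traces=pd.DataFrame(out, columns=raw.traces.columns),
        background=np.zeros_like(raw.background),
        normalized=True,
        unusable=unusable,
    )


# ---------------------------------------------------------------------------
# response calling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ResponseCall:
    """Verdict for one cell: did it respond, and when."""

    responded: bool
    response_time: float | None
    method: str  # "raw_rate" or "running_average"
    uncertainty: float

    def __post_init__(self) -> None:
        if not self.responded and self.response_time is not None:
            raise ValueError("non-responders carry no response time")


def running_average_rate(trace: np.ndarray, window: int = RUNNING_AVERAGE_WINDOW) -> np.ndarray:
    """Moving mean of consecutive first differences over ``window`` intervals.

    Output element ``i`` averages the differences ending at sample
    ``i + window`` (trailing convention); ``window=1`` returns the raw first
    differences.
    """
    trace = np.asarray(trace, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if trace.size <= window:
        raise ValueError(f"trace of {trace.size} samples too short for window {window}")
    diffs = np.diff(trace)
    kernel = np.ones(window) / window
    return np.convolve(diffs, kernel, mode="valid")


def _earliest_argmax(seg: np.ndarray) -> int:
    """Index of the first value within floating tolerance of the maximum.

    Rate maxima can tie exactly (e.g. a linear rise sampled uniformly); the
    documented convention is that the earliest time wins, and the tolerance
    keeps that choice stable against last-bit rounding.
    """
    m = float(seg.max())
    eps = 1e-9 * max(1.0, abs(m))
    return int(np.argmax(seg >= m - eps))


def _smooth3(v: np.ndarray) -> np.ndarray:
    """Centered 3-sample moving mean with shrinking windows at the ends."""
    out = np.empty_like(v)
    for i in range(v.size):
        out[i] = v[max(0, i - 1) : i + 2].mean()
    return out


def call_response(
    trace: np.ndarray,
    sample_interval: float,
    weak_signal: bool = False,
    *,
    noise_multiple: float = 3.0,
    min_prominence: float = 0.25,
    window: int = RUNNING_AVERAGE_WINDOW,
) -> ResponseCall:
    """Decide whether a normalized trace contains a calcium response.

    Pulse geometry is assessed on a lightly smoothed copy of the trace
    (3-sample centered mean) so that single noisy samples neither mimic nor
    break a pulse; the noise level is estimated robustly from the residual
    about that smooth.  A responder must show (a) a peak whose prominence
    over the pre-rise baseline exceeds ``noise_multiple`` times the noise
    level and an absolute floor ``min_prominence``, and (b) a rise to the
    peak faster than the return from it — the fast-rise/slow-decline pulse
    shape.  The response time is the time of the maximum positive first
    difference of the *raw* trace (``weak_signal=False``) or of the maximum
    of the ``window``-interval running average of the differences
    (``weak_signal=True``), stamped at the trailing sample.  Uncertainties
    are half a sampling interval for the raw rate and a full interval for
    the running average.
    """
    v = np.asarray(trace, dtype=float)
    if v.size < 8:
        raise ValueError(f"response calling needs >= 8 samples, got {v.size}")
    if np.isnan(v).any():
        return ResponseCall(False, None, "raw_rate", sample_interval / 2)

    w = _smooth3(v)
    ip = int(np.argmax(w))
    # robust noise level from the first differences of the raw trace: the
    # few pulse-edge differences are outliers that the median ignores; for
    # white noise of sd s the differences have sd s*sqrt(2)
    dv = np.diff(v)
    noise = 1.4826 * float(np.median(np.abs(dv - np.median(dv)))) / np.sqrt(2.0)

    baseline = float(np.quantile(w, 0.25))
    # peak height from a 2-sample mean: nearly the raw peak of a multi-
    # sample pulse, but a single noisy sample cannot dominate it
    prominence = float(np.max((v[:-1] + v[1:]) / 2.0)) - baseline

    responded = (
        ip >= 2
        and prominence > noise_multiple * noise
        and prominence >= min_prominence
    )
    if responded:
        # pulse shape: the trace must spend more samples above the return
        # level after the peak (slow decline) than before it (fast rise).
        # The level sits 10% of the prominence above baseline, kept out of
        # the smoothed noise band (sd noise/sqrt(3)); counting samples
        # rather than locating crossings is insensitive to isolated noise
        # excursions.
        level = baseline + max(0.1 * prominence, 1.5 * noise / np.sqrt(3.0))
        rise_samples = int(np.count_nonzero(w[:ip] > level))
        fall_samples = int(np.count_nonzero(w[ip + 1 :] > level))
        responded = rise_samples < fall_samples

    if not responded:
        method = "running_average" if weak_signal else "raw_rate"
        unc = sample_interval if weak_signal else sample_interval / 2
        return ResponseCall(False, None, method, unc)

    # the response time is the steepest rise of the detected pulse, so the
    # search window runs from just below the pulse's onset to its peak —
    # a rate spike elsewhere in the trace (noise, tail wiggles) is not the
    # response
    a = ip
    while a > 0 and w[a - 1] > level:
        a -= 1
    lo_t, hi_t = max(1, a - 1), max(1, ip + 1)

    if weak_signal:
        smoothed = running_average_rate(v, window)
        # trailing timestamps of the smoothed rates are window .. n-1
        lo_i = max(0, lo_t - window)
        hi_i = min(smoothed.size, hi_t - window + 1)
        seg = smoothed[lo_i:hi_i] if hi_i > lo_i else smoothed
        off = lo_i if hi_i > lo_i else 0
        i = off + _earliest_argmax(seg)
        return ResponseCall(
            True, float((i + window) * sample_interval), "running_average", sample_interval
        )
    diffs = np.diff(v)
    seg = diffs[lo_t - 1 : hi_t]
    i = lo_t - 1 + _earliest_argmax(seg)
    return ResponseCall(True, float((i + 1) * sample_interval), "raw_rate", sample_interval / 2)


# ---------------------------------------------------------------------------
# propagation statistics
# ---------------------------------------------------------------------------


@dataclass
class PropagationStats:
    """Cell-to-cell lags along a chain of response calls.

    ``pair_lags`` holds one row per adjacent responder pair, oriented in the
    propagation direction (``wave`` is "up" toward increasing positions,
    "down" toward decreasing, or "meeting" for the pair where opposing
    waves merge in a dual-stimulus layout).  Pairs spanning non-responders
    are excluded and counted.
    """

    pair_lags: pd.DataFrame
    mean_lag: float
    sd_lag: float
    directional: dict[str, tuple[float, float, int]]
    n_excluded_pairs: int
    propagation_distance: dict[str, int]


def propagation_stats(
    calls: Mapping[str, ResponseCall],
    origins: Sequence[str],
) -> PropagationStats:
    """Directional cell-to-cell propagation times from ordered response calls.

    ``calls`` must be ordered along the chain (insertion order is the chain
    order); ``origins`` are the stimulated cells (one or two labels).
    """
    labels = list(calls.keys())
    pos = {lab: i for i, lab in enumerate(labels)}
    for o in origins:
        if o not in pos:
            raise ValueError(f"origin {o!r} is not among the calls")
    if not 1 <= len(origins) <= 2:
        raise ValueError("expected one or two origins")

    rts = {
        lab: c.response_time for lab, c in calls.items() if c.responded
    }
    if len(rts) < 2:
        raise InsufficientDataError(f"need >= 2 responders, got {len(rts)}")

    o_idx = sorted(pos[o] for o in origins)
    mid = sum(o_idx) / len(o_idx)

    rows = []
    n_excluded = 0
    for i, j in zip(range(len(labels) - 1), range(1, len(labels))):
        a, b = labels[i], labels[j]
        if a not in rts or b not in rts:
            if (a in rts) != (b in rts):
                n_excluded += 1
            continue
        center = (i + j) / 2
        if len(o_idx) == 2 and o_idx[0] <= i and j <= o_idx[1] and center == mid:
            rows.append({"from_cell": a, "to_cell": b, "lag": abs(rts[b] - rts[a]), "wave": "meeting"})
            continue
        upward = center > mid if len(o_idx) == 2 else center > o_idx[0]
        if len(o_idx) == 2 and o_idx[0] <= i and j <= o_idx[1]:
            # between the stimuli each pair belongs to the nearer origin
            upward = center < mid
        if upward:
            rows.append({"from_cell": a, "to_cell": b, "lag": rts[b] - rts[a], "wave": "up"})
        else:
            rows.append({"from_cell": b, "to_cell": a, "lag": rts[a] - rts[b], "wave": "down"})
    table = pd.DataFrame(rows, columns=["from_cell", "to_cell", "lag", "wave"])

    directional: dict[str, tuple[float, float, int]] = {}
    for wave in ("up", "down"):
        lags = table.loc[table["wave"] == wave, "lag"].to_numpy()
        if lags.size:
            directional[wave] = (
                float(lags.mean()),
                float(lags.std(ddof=1)) if lags.size > 1 else 0.0,
                int(lags.size),
            )
    lags = table.loc[table["wave"] != "meeting", "lag"].to_numpy()
    mean = float(lags.mean()) if lags.size else float("nan")
    sd = float(lags.std(ddof=1)) if lags.size > 1 else 0.0

    distance: dict[str, int] = {}
    for o in origins:
        i = pos[o]
        if len(o_idx) == 2 and i == o_idx[0]:
            side = labels[:i]
        elif len(o_idx) == 2:
            side = labels[i + 1 :]
        else:
            left = sum(1 for lab in labels[:i] if lab in rts)
            right = sum(1 for lab in labels[i + 1 :] if lab in rts)
            distance[o] = max(left, right)
            continue
        distance[o] = sum(1 for lab in side if lab in rts)

    return PropagationStats(
        pair_lags=table,
        mean_lag=mean,
        sd_lag=sd,
        directional=directional,
        n_excluded_pairs=n_excluded,
        propagation_distance=distance,
    )


# ---------------------------------------------------------------------------
# CSV input/output
# ---------------------------------------------------------------------------

_LONG_COLUMNS = {"time", "cell_label", "intensity"}


def write_traces_csv(
    ts: FluorescenceTraceSet, path: str | Path, layout: str = "wide"
) -> None:
    """Write a trace set as CSV, wide (one column per cell) or long/tidy."""
    path = Path(path)
    if layout == "wide":
        df = pd.DataFrame({"time": ts.sample_times})
        for lab in ts.cell_labels:
            df[lab] = ts.trace(lab)
        df[BACKGROUND_COLUMN] = ts.background
        df.to_csv(path, index=False)
    elif layout == "long":
        frames = [
            pd.DataFrame(
                {"time": ts.sample_times, "cell_label": lab, "intensity": ts.trace(lab)}
            )
            for lab in ts.cell_labels
        ]
        frames.append(
            pd.DataFrame(
                {
                    "time": ts.sample_times,
                    "cell_label": BACKGROUND_COLUMN,
                    "intensity": ts.background,
                }
            )
        )
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown layout {layout!r}")


def read_traces_csv(path: str | Path, normalized: bool = False) -> FluorescenceTraceSet:
    """Read a trace CSV, auto-detecting wide vs long layout."""
    df = pd.read_csv(path)
    df.columns = [str(c) for c in df.columns]
    if _LONG_COLUMNS <= set(df.columns):
        wide = df.pivot(index="time", columns="cell_label", values="intensity")
        wide = wide.sort_index()
        times = wide.index.to_numpy(dtype=float)
        if BACKGROUND_COLUMN in wide.columns:
            background = wide[BACKGROUND_COLUMN].to_numpy(dtype=float)
            wide = wide.drop(columns=[BACKGROUND_COLUMN])
        else:
            background = np.zeros(times.size)
        wide.columns = [str(c) for c in wide.columns]
        return FluorescenceTraceSet(
            times, wide.reset_index(drop=True), background, normalized=normalized
        )
    if "time" not in df.columns:
        raise ValueError("trace CSV needs a 'time' column")
    times = df["time"].to_numpy(dtype=float)
    cols = [c for c in df.columns if c != "time"]
    if BACKGROUND_COLUMN in cols:
        background = df[BACKGROUND_COLUMN].to_numpy(dtype=float)
        cols = [c for c in cols if c != BACKGROUND_COLUMN]
    else:
        background = np.zeros(times.size)
    return FluorescenceTraceSet(
        times, df[cols].reset_index(drop=True), background, normalized=normalized
    )
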