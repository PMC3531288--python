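"""Fluorescence trace normalization, response calling and propagation stats."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

import calwave as cw
from calwave.metrics import InsufficientDataError
from calwave.traces import BACKGROUND_COLUMN


def make_set(data: dict, background=None, interval=1.2, normalized=False):
    n = len(next(iter(data.values())))
    times = np.arange(n) * interval
    bg = np.zeros(n) if background is None else np.asarray(background, float)
    return cw.FluorescenceTraceSet(
        times, pd.DataFrame({k: np.asarray(v, float) for k, v in data.items()}), bg,
        normalized=normalized,
    )


def pulse(n, onset, rise, amplitude, tau, interval=1.2, baseline=1.0):
    t = np.arange(n) * interval
    out = np.full(n, baseline)
    rising = (t >= onset) & (t < onset + rise)
    out[rising] += amplitude * (t[rising] - onset) / rise
    falling = t >= onset + rise
    out[falling] += amplitude * np.exp(-(t[falling] - onset - rise) / tau)
    return out


class TestNormalize:
    def test_constant_offset_becomes_ones(self):
        bg = np.full(10, 40.0)
        ts = make_set({"a": bg + 7.0}, background=bg)
        out = cw.normalize(ts)
        assert np.allclose(out.trace("a"), 1.0)
        assert out.normalized

    def test_scale_invariance(self):
        bg = np.linspace(40, 42, 12)
        raw = bg + pulse(12, onset=3.6, rise=2.4, amplitude=2.0, tau=4.0) * 80
        a = cw.normalize(make_set({"a": raw}, background=bg))
        b = cw.normalize(make_set({"a": 2 * raw}, background=2 * bg))
        assert np.allclose(a.trace("a"), b.trace("a"))

    def test_known_peak_ratio(self):
        bg = np.full(20, 30.0)
        raw = bg + 50.0 * pulse(20, onset=6.0, rise=2.4, amplitude=1.0, tau=4.0)
        out = cw.normalize(make_set({"a": raw}, background=bg))
        assert out.trace("a").max() == pytest.approx(2.0, abs=1e-9)

    def test_nonpositive_initial_flags_unusable(self):
        bg = np.full(10, 40.0)
        ts = make_set({"bad": bg - 1.0, "good": bg + 10.0}, background=bg)
        out = cw.normalize(ts)
        assert out.unusable == {"bad"}
        assert np.isnan(out.trace("bad")).all()
        assert np.allclose(out.trace("good"), 1.0)

    def test_double_normalization_rejected(self):
        ts = make_set({"a": np.ones(10)}, normalized=True)
        with pytest.raises(ValueError):
            cw.normalize(ts)


class TestRunningAverageRate:
    def test_window_one_is_raw_differences(self):
        v = np.array([0.0, 1.0, 3.0, 2.0, 5.0])
        assert np.allclose(cw.running_average_rate(v, 1), np.diff(v))

    def test_linear_ramp_gives_constant_slope(self):
        v = 0.7 * np.arange(20.0)
        assert np.allclose(cw.running_average_rate(v, 4), 0.7)

    def test_step_change_peaks_at_first_covering_window(self):
        v = np.array([0.0] * 5 + [1.0] * 5)  # step between samples 4 and 5
        smoothed = cw.running_average_rate(v, 4)
        # oracle: enumerate all windows of 4 consecutive differences
        diffs = np.diff(v)
        windows = [diffs[i : i + 4].mean() for i in range(len(diffs) - 3)]
        assert np.allclose(smoothed, windows)
        assert np.argmax(smoothed) == int(np.argmax(windows)) == 1

    def test_window_too_large(self):
        with pytest.raises(ValueError):
            cw.running_average_rate(np.arange(4.0), 4)


class TestCallResponse:
    def test_flat_noisy_trace_is_no_response(self):
        rng = np.random.default_rng(11)
        v = 1.0 + rng.normal(0, 0.05, 40)
        call = cw.call_response(v, 1.2)
        assert not call.responded and call.response_time is None

    def test_clean_pulse_called_at_steepest_rise(self):
        v = pulse(40, onset=6.0, rise=3.6, amplitude=1.5, tau=4.0)
        call = cw.call_response(v, 1.2)
        assert call.responded
        assert call.method == "raw_rate" and call.uncertainty == pytest.approx(0.6)
        # steepest sampled rise occurs inside the linear rise (6.0 .. 9.6 s)
        assert 6.0 <= call.response_time <= 9.6 + 1.2

    def test_slow_symmetric_bump_is_rejected(self):
        # rise as slow as the decline: not the fast-rise/slow-decline shape
        t = np.arange(30) * 1.2
        v = 1.0 + 1.5 * np.exp(-((t - 18.0) ** 2) / (2 * 6.0**2))
        call = cw.call_response(v, 1.2)
        assert not call.responded

    def test_weak_signal_uses_running_average(self):
        v = pulse(40, onset=9.6, rise=3.6, amplitude=1.0, tau=5.0)
        call = cw.call_response(v, 1.2, weak_signal=True)
        assert call.responded
        assert call.method == "running_average"
        assert call.uncertainty == pytest.approx(1.2)
        raw = cw.call_response(v, 1.2)
        assert abs(call.response_time - raw.response_time) <= 2 * 1.2 + 1e-9

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            cw.call_response(np.ones(5), 1.2)

    def test_unusable_nan_trace_is_no_response(self):
        call = cw.call_response(np.full(12, np.nan), 1.2)
        assert not call.responded


class TestPropagationStats:
    def _calls(self, rts, interval=1.2):
        calls = {}
        for i, t in enumerate(rts, start=1):
            if t is None:
                calls[str(i)] = cw.ResponseCall(False, None, "raw_rate", 0.6)
            else:
                calls[str(i)] = cw.ResponseCall(True, float(t), "raw_rate", 0.6)
        return calls

    def test_exact_lags_single_origin(self):
        # stimulated cell 3 of 5, exact 1.8 s outward lags
        calls = self._calls([3.6, 1.8, 0.0, 1.8, 3.6])
        stats = cw.propagation_stats(calls, ["3"])
        assert stats.mean_lag == pytest.approx(1.8)
        assert stats.sd_lag == pytest.approx(0.0)
        assert stats.propagation_distance["3"] == 2

    def test_alternating_lags_closed_form(self):
        # lags 1.2, 2.4, 1.2, 2.4 away from cell 1
        calls = self._calls([0.0, 1.2, 3.6, 4.8, 7.2])
        stats = cw.propagation_stats(calls, ["1"])
        assert stats.mean_lag == pytest.approx(1.8)
        assert stats.sd_lag == pytest.approx(0.6928203, abs=1e-6)

    def test_dual_origin_directions_and_meeting_pair(self):
        # 8 cells, stimulated 1 and 8; waves meet between 4 and 5
        calls = self._calls([0.0, 1.8, 3.6, 5.4, 5.0, 3.4, 1.7, 0.0])
        stats = cw.propagation_stats(calls, ["1", "8"])
        up = stats.pair_lags[stats.pair_lags.wave == "up"]
        down = stats.pair_lags[stats.pair_lags.wave == "down"]
        meeting = stats.pair_lags[stats.pair_lags.wave == "meeting"]
        assert len(up) == 3 and len(down) == 3 and len(meeting) == 1
        assert stats.directional["up"][0] == pytest.approx(1.8)
        assert stats.directional["down"][0] == pytest.approx((1.7 + 1.7 + 1.6) / 3)
        assert (up.lag > 0).all() and (down.lag > 0).all()

    def test_pairs_spanning_non_responders_are_excluded(self):
        calls = self._calls([0.0, 1.8, None, 5.4, 7.2])
        stats = cw.propagation_stats(calls, ["1"])
        assert stats.n_excluded_pairs == 2
        assert len(stats.pair_lags) == 2  # (1,2) and (4,5)

    def test_insufficient_responders(self):
        calls = self._calls([0.0, None, None])
        with pytest.raises(InsufficientDataError):
            cw.propagation_stats(calls, ["1"])


class TestTraceIO:
    def _example(self):
        rng = np.random.default_rng(3)
        bg = np.full(15, 40.0)
        return make_set(
            {
                "1": bg + 80 * pulse(15, 3.6, 2.4, 1.0, 4.0),
                "2": bg + 120 * pulse(15, 6.0, 2.4, 1.0, 4.0),
            },
            background=bg + rng.normal(0, 0.1, 15),
        )

    @pytest.mark.parametrize("layout", ["wide", "long"])
    def test_round_trip(self, tmp_path, layout):
        ts = self._example()
        path = tmp_path / f"traces_{layout}.csv"
        cw.write_traces_csv(ts, path, layout=layout)
        back = cw.read_traces_csv(path)
        assert back.cell_labels == ts.cell_labels
        assert np.allclose(back.sample_times, ts.sample_times)
        assert np.allclose(back.background, ts.background)
        for lab in ts.cell_labels:
            assert np.allclose(back.trace(lab), ts.trace(lab))

    def test_background_column_is_reserved(self, tmp_path):
        ts = self._example()
        cw.write_traces_csv(ts, tmp_path / "t.csv")
        df = pd.read_csv(tmp_path / "t.csv")
        assert BACKGROUND_COLUMN in df.columns

    def test_nonuniform_sampling_rejected(self):
        times = np.array([0.0, 1.2, 3.0])
        with pytest.raises(ValueError):
            cw.FluorescenceTraceSet(
                times, pd.DataFrame({"a": np.zeros(3)}), np.zeros(3)
            )


@given(scale=st.floats(min_value=0.1, max_value=50), offset=st.floats(min_value=0, max_value=100))
@hyp_settings(deadline=None, max_examples=50, derandomize=True)
def test_normalization_is_scale_and_background_invariant(scale, offset):
    """Normalized traces depend only on the background-corrected shape."""
    bg = np.full(16, 20.0)
    shape = pulse(16, 4.8, 2.4, 1.5, 4.0)
    base = cw.normalize(make_set({"a": bg + 60 * shape}, background=bg))
    other = cw.normalize(
        make_set({"a": (bg + offset) + 60 * scale * shape}, background=bg + offset)
    )
    assert np.allclose(base.trace("a"), other.trace("a"), rtol=1e-9, atol=1e-9)
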