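"""Filtering, segmentation, normalization and averaging contracts."""

import numpy as np
import pytest

from rampgait import (
    EventSeries,
    GaitEvent,
    average_waveforms,
    gcv_smooth,
    lowpass,
    segment_cycles,
    time_normalize,
)
from rampgait.signal_prep import NormalizedCycle, RawCycle

from oracles import brute_force_hierarchical_mean


def _amplitude_after(f_hz, fs=60.0, n=600):
    t = np.arange(n) / fs
    x = np.sin(2 * np.pi * f_hz * t)
    y = lowpass(x, fs)
    core = slice(n // 4, 3 * n // 4)  # avoid edge transients
    return np.abs(y[core]).max()


class TestLowpass:
    def test_dc_preserved(self):
        x = np.full(200, 3.7)
        assert np.allclose(lowpass(x, 60.0), x, atol=1e-6)

    def test_passband_1hz_attenuation_below_1pct(self):
        assert _amplitude_after(1.0) > 0.99

    def test_stopband_15hz_attenuation_above_90pct(self):
        assert _amplitude_after(15.0) < 0.10

    def test_gain_at_cutoff_between_minus4_and_minus2_db(self):
        gain_db = 20 * np.log10(_amplitude_after(6.0, n=1200))
        assert -4.0 <= gain_db <= -2.0

    def test_zero_phase(self):
        """Forward-backward filtering leaves an isolated peak in place."""
        fs, n = 60.0, 600
        t = np.arange(n) / fs
        x = np.exp(-0.5 * ((t - 5.0) / 0.5) ** 2)
        y = lowpass(x, fs)
        assert abs(int(np.argmax(y)) - int(np.argmax(x))) <= 1

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            lowpass(np.zeros(10), 60.0)

    def test_fs_must_exceed_nyquist(self):
        with pytest.raises(ValueError, match="cutoff"):
            lowpass(np.zeros(100), 10.0)


class TestGcvSmooth:
    def test_noiseless_passthrough(self):
        t = np.arange(400) / 60.0
        x = 20 * np.sin(2 * np.pi * 0.9 * t) + 5 * np.sin(2 * np.pi * 2.7 * t)
        assert np.abs(gcv_smooth(x) - x).max() < 0.05

    def test_noise_reduction(self, rng):
        t = np.arange(400) / 60.0
        clean = 20 * np.sin(2 * np.pi * 0.9 * t)
        noisy = clean + rng.normal(0, 1.0, len(t))
        sm = gcv_smooth(noisy)
        assert np.sqrt(np.mean((sm - clean) ** 2)) < 0.6

    def test_matches_scipy_gcv_spline(self, rng):
        """Cross-check against scipy's GCV smoothing spline on noisy data."""
        from scipy.interpolate import make_smoothing_spline

        t = np.arange(360, dtype=float)
        clean = 15 * np.sin(2 * np.pi * t / 70) + 6 * np.cos(2 * np.pi * t / 33)
        y = clean + rng.normal(0, 1.0, len(t))
        ours = gcv_smooth(y)
        theirs = make_smoothing_spline(t, y)(t)
        assert np.sqrt(np.mean((ours - theirs) ** 2)) < 0.35


def _series_events(n_ics, fs=60.0, stride=60, to_off=36):
    events = []
    for i in range(n_ics):
        f = 30 + i * stride
        events.append(GaitEvent("left", "IC", f, f / fs))
        if i < n_ics - 1:
            events.append(GaitEvent("left", "TO", f + to_off, (f + to_off) / fs))
    return EventSeries(events=tuple(events), fs=fs)


class TestSegmentation:
    def test_five_ics_four_tos_give_four_cycles(self):
        events = _series_events(5)
        n = 30 + 4 * 60 + 10
        angles = {"knee": np.arange(n, dtype=float)}
        cycles = segment_cycles(angles, events, "left")
        assert len(cycles) == 4
        for c in cycles:
            assert c.start_frame < c.to_frame < c.end_frame
            assert np.allclose(c.samples["knee"], np.arange(c.start_frame, c.end_frame + 1))

    def test_cycle_with_double_toe_off_discarded(self):
        events = [
            GaitEvent("left", "IC", 30, 0.5),
            GaitEvent("left", "TO", 50, 50 / 60),
            GaitEvent("left", "TO", 70, 70 / 60),  # glitch
            GaitEvent("left", "IC", 90, 1.5),
        ]
        cycles = segment_cycles(
            {"knee": np.zeros(120)}, EventSeries(events=tuple(events), fs=60.0), "left"
        )
        assert cycles == []


class TestTimeNormalize:
    def _raw(self, y, to_rel):
        n = len(y)
        return RawCycle(
            side="left", start_frame=0, end_frame=n - 1, to_frame=to_rel, fs=60.0,
            samples={"knee": np.asarray(y, float)},
        )

    def test_constant_cycle(self):
        nc = time_normalize(self._raw(np.full(60, 30.0), 36))
        assert np.allclose(nc.samples["knee"], 30.0)
        assert nc.to_percent == pytest.approx(100 * 36 / 59)

    def test_linear_ramp_interpolates_linearly(self):
        y = np.linspace(0.0, 50.0, 51)
        nc = time_normalize(self._raw(y, 30))
        assert np.allclose(nc.samples["knee"], np.linspace(0, 50, 101), atol=1e-9)

    def test_endpoints_preserved_exactly(self, rng):
        y = rng.normal(size=64)
        nc = time_normalize(self._raw(y, 38))
        assert nc.samples["knee"][0] == y[0]
        assert nc.samples["knee"][-1] == y[-1]

    def test_sinusoid_amplitude_within_half_percent_of_dense_oracle(self):
        """63 frames at 60 Hz (1.05 s cycle) resampled to 101 points keeps
        the peak within 0.5% of the dense-sampled amplitude."""
        n = 64
        x = np.arange(n) / (n - 1)
        y = 30 * np.sin(2 * np.pi * x - 0.4)
        nc = time_normalize(self._raw(y, 38))
        assert nc.samples["knee"].max() == pytest.approx(30.0, rel=0.005)

    def test_idempotent_on_101_uniform_cycle(self, rng):
        y = np.cumsum(rng.normal(size=101))
        nc = time_normalize(self._raw(y, 60))
        assert np.allclose(nc.samples["knee"], y, atol=1e-9)

    def test_short_cycle_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            time_normalize(self._raw(np.zeros(8), 4))


def _ncycle(side, values, to=60.0):
    return NormalizedCycle(side=side, samples={"knee": np.asarray(values, float)}, to_percent=to)


class TestAveraging:
    def test_identical_cycles_mean_equals_cycle_sd_zero(self):
        w = np.sin(np.linspace(0, 2 * np.pi, 101))
        cycles = {f"t{i}": [_ncycle("left", w), _ncycle("right", w)] for i in range(3)}
        rep = average_waveforms(cycles)
        assert np.allclose(rep.mean["knee"], w)
        assert np.allclose(rep.sd["knee"], 0.0)
        assert rep.n_cycles == 6 and rep.n_trials == 3

    def test_left_10_right_20_mean_15(self):
        cycles = {"t1": [_ncycle("left", np.full(101, 10.0)), _ncycle("right", np.full(101, 20.0))]}
        rep = average_waveforms(cycles)
        assert np.allclose(rep.mean["knee"], 15.0)

    def test_missing_side_falls_back_with_warning(self):
        cycles = {"t1": [_ncycle("left", np.full(101, 10.0))]}
        with pytest.warns(UserWarning, match="only left"):
            rep = average_waveforms(cycles)
        assert np.allclose(rep.mean["knee"], 10.0)

    def test_hierarchical_mean_matches_brute_force(self, rng):
        """100 random trial/side/cycle layouts agree with an explicit-loop
        recomputation of the averaging hierarchy."""
        for _ in range(100):
            layout = {}
            store = {}
            for ti in range(rng.integers(1, 5)):
                tid = f"t{ti}"
                store[tid] = {"left": [], "right": []}
                ncl = {"left": int(rng.integers(0, 3)), "right": int(rng.integers(0, 3))}
                if ncl["left"] + ncl["right"] == 0:
                    ncl["left"] = 1
                cyc = []
                for side, k in ncl.items():
                    for _ in range(k):
                        w = rng.normal(size=101)
                        store[tid][side].append(w)
                        cyc.append(_ncycle(side, w))
                layout[tid] = cyc
            import warnings as _w

            with _w.catch_warnings():
                _w.simplefilter("ignore")
                rep = average_waveforms(layout)
            assert np.allclose(rep.mean["knee"], brute_force_hierarchical_mean(store), atol=1e-12)

    def test_averaging_linearity_under_shift(self):
        w1, w2 = np.sin(np.linspace(0, 6, 101)), np.cos(np.linspace(0, 6, 101))
        base = average_waveforms({"t1": [_ncycle("left", w1), _ncycle("right", w2)]})
        shifted = average_waveforms(
            {"t1": [_ncycle("left", w1 + 5.0), _ncycle("right", w2 + 5.0)]}
        )
        assert np.allclose(shifted.mean["knee"], base.mean["knee"] + 5.0, atol=1e-12)
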