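"""Raw-signal cleaning, R-wave detection, beat averaging, resampling."""

import numpy as np
import pytest

from cadenza import preprocess as pp

FS = 500.0


def sinusoid(f=1.0, dur=10.0, fs=FS, amp=1.0):
    t = np.arange(int(dur * fs)) / fs
    return t, amp * np.sin(2 * np.pi * f * t)


class TestRemoveSpikes:
    def test_clean_signal_untouched(self):
        _, x = sinusoid()
        out, rep = pp.remove_spikes(x, FS)
        np.testing.assert_array_equal(out, x)
        assert rep["n_spikes_removed"] == 0

    def test_narrow_spike_replaced_by_chord(self):
        t, x = sinusoid()
        spiked = x.copy()
        a, w = 2500, int(0.04 * FS)  # 40 ms rectangular spike
        spiked[a : a + w] += 50.0
        out, rep = pp.remove_spikes(spiked, FS)
        assert rep["n_spikes_removed"] == 1
        # outside the spike interval: bit-identical
        mask = np.ones_like(x, dtype=bool)
        mask[a - 1 : a + w + 1] = False
        np.testing.assert_array_equal(out[mask], spiked[mask])
        # inside: equal to the original within the linear-chord error
        lo, hi = a - 1, a + w
        chord = np.interp(np.arange(lo, hi + 1), [lo, hi], [x[lo], x[hi]])
        chord_err = np.abs(chord - x[lo : hi + 1]).max()
        assert np.abs(out[a : a + w] - x[a : a + w]).max() <= chord_err + 1e-12

    def test_wide_spike_left_untouched_but_flagged(self):
        _, x = sinusoid()
        spiked = x.copy()
        a, w = 2500, int(0.15 * FS)  # 150 ms: at/above the width gate
        spiked[a : a + w] += 50.0
        out, rep = pp.remove_spikes(spiked, FS)
        assert rep["n_spikes_removed"] == 0
        assert rep["n_wide_flagged"] >= 1
        np.testing.assert_array_equal(out, spiked)

    def test_edge_spike_held_constant(self):
        _, x = sinusoid()
        spiked = x.copy()
        spiked[:10] += 50.0  # spans the first sample
        out, rep = pp.remove_spikes(spiked, FS)
        assert rep["edge_regions"] >= 1
        assert np.abs(out[:10]).max() < 2.0  # artefact amplitude gone

    def test_unusable_signal_rejected(self):
        rng = np.random.default_rng(0)
        x = np.zeros(5000) + 0.01 * rng.standard_normal(5000)
        for a in range(100, 4800, 80):  # >10% of samples inside spikes
            x[a : a + 30] += 100.0
        with pytest.raises(ValueError, match="unusable"):
            pp.remove_spikes(x, FS)


class TestLowpass:
    def test_dc_gain_unity(self):
        x = np.full(5000, 3.7)
        out = pp.lowpass_filter(x, FS)
        np.testing.assert_allclose(out[500:-500], 3.7, rtol=1e-9)

    def test_passband_sinusoid_preserved_zero_phase(self):
        t, x = sinusoid(f=1.0)
        out = pp.lowpass_filter(x, FS)
        mid = slice(1000, 4000)
        np.testing.assert_allclose(out[mid], x[mid], atol=0.01)  # amp & phase

    def test_stopband_attenuation(self):
        t, x = sinusoid(f=100.0)  # 5x cutoff
        out = pp.lowpass_filter(x, FS)
        atten_db = 20 * np.log10(np.abs(out[1000:4000]).max())
        assert atten_db < -60.0

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            pp.lowpass_filter(np.ones(100), FS, cutoff_hz=300.0)
        with pytest.raises(ValueError):
            pp.lowpass_filter(np.ones(100), FS, order=7)


class TestMedianFilter:
    def test_monotone_ramp_unchanged_interior(self):
        x = np.linspace(0, 1, 1000)
        out = pp.median_filter_mcav(x, 5)
        np.testing.assert_allclose(out[2:-2], x[2:-2])

    def test_single_outlier_removed_exactly(self):
        x = np.full(100, 7.0)
        x[50] = 107.0
        out = pp.median_filter_mcav(x, 5)
        np.testing.assert_array_equal(out, np.full(100, 7.0))

    def test_alternating_square_majority(self):
        x = np.tile([1.0, -1.0], 50)
        out = pp.median_filter_mcav(x, 3)
        # window of 3 over +-1 alternation: median equals the majority value,
        # which is the value occupying two of three positions
        np.testing.assert_array_equal(out[1:-1], x[1:-1] * 0 + np.sign(x[0:-2] + x[1:-1] + x[2:]))

    def test_kernel_validation(self):
        with pytest.raises(ValueError):
            pp.median_filter_mcav(np.ones(10), 4)
        with pytest.raises(ValueError):
            pp.median_filter_mcav(np.ones(10), 11)


class TestRWaves:
    def make_ecg(self, rr=0.8, dur=30.0, noise=0.02, seed=0, drop=None):
        rng = np.random.default_rng(seed)
        n = int(dur * FS)
        x = noise * rng.standard_normal(n)
        beats = np.arange(0.5, dur - 0.5, rr)
        if drop is not None:
            beats = np.delete(beats, drop)
        x[(beats * FS).astype(int)] += 1.0
        return x, beats

    def test_impulse_train_recovered(self):
        x, beats = self.make_ecg()
        det, oog = pp.detect_r_waves(x, FS)
        assert len(det) == len(beats)
        np.testing.assert_allclose(det, beats, atol=2.0 / FS)
        assert not oog.any()

    def test_flat_signal_rejected(self):
        with pytest.raises(ValueError, match="no QRS"):
            pp.detect_r_waves(np.zeros(int(10 * FS)), FS)

    def test_missing_beat_flagged_out_of_gate(self):
        x, beats = self.make_ecg(drop=10)
        det, oog = pp.detect_r_waves(x, FS)
        assert oog.sum() == 1  # the 1.6 s RR gap exceeds the 0.3-2.0 s gate... no
        gap_idx = np.flatnonzero(oog)[0]
        assert det[gap_idx] - det[gap_idx - 1] == pytest.approx(1.6, abs=0.02)

    def test_manual_correction_hook(self):
        beats = np.array([0.0, 0.8, 2.4, 3.2])
        fixed = pp.correct_beats(beats, insert=(1.6,))
        np.testing.assert_allclose(np.diff(fixed), 0.8)
        removed = pp.correct_beats(fixed, delete=(1.61,))
        np.testing.assert_allclose(removed, beats)
        with pytest.raises(ValueError):
            pp.correct_beats(beats, delete=(10.0,))


class TestBeatAverage:
    def test_constant(self):
        x = np.full(5000, 4.2)
        out = pp.beat_average(x, FS, np.array([0.5, 1.3, 2.1, 2.9]))
        np.testing.assert_allclose(out, 4.2)

    def test_full_sine_cycles_average_to_zero(self):
        f = 1.25
        t, x = sinusoid(f=f)
        beats = np.arange(0.0, 8.0, 1.0 / f)  # beat = exactly one period
        out = pp.beat_average(x, FS, beats)
        np.testing.assert_allclose(out, 0.0, atol=1e-3)  # quadrature error

    def test_ramp_means_are_midpoints(self):
        x = np.arange(5000, dtype=float)
        beats = np.array([1.0, 2.0, 3.0])
        out = pp.beat_average(x, FS, beats)
        np.testing.assert_allclose(out, [(500 + 999) / 2, (1000 + 1499) / 2])

    def test_global_mean_conserved(self):
        """Duration-weighted mean of per-beat means equals the waveform mean."""
        rng = np.random.default_rng(5)
        x = rng.standard_normal(10000)
        beats = np.sort(rng.uniform(0, 20, 15))
        out = pp.beat_average(x, FS, beats)
        edges = np.round(beats * FS).astype(int)
        weights = np.diff(edges)
        direct = x[edges[0] : edges[-1]].mean()
        np.testing.assert_allclose(np.sum(out * weights) / weights.sum(), direct, rtol=1e-9)

    def test_empty_interval_rejected(self):
        with pytest.raises(ValueError):
            pp.beat_average(np.ones(100), FS, np.array([0.010, 0.0105, 0.2]))


class TestEtco2:
    def make_capno(self, values, period=4.0, fs=FS):
        dur = period * len(values)
        n = int(dur * fs)
        x = np.full(n, 2.0)
        for i, v in enumerate(values):
            a = int((i * period + 0.35 * period) * fs)
            b = int(min((i + 1) * period, dur) * fs)
            x[a:b] = v
        return x

    def test_constant_plateaus(self):
        x = self.make_capno([38.0] * 8)
        beats = np.arange(1.0, 30.0, 0.8)
        out = pp.etco2_per_beat(x, FS, beats)
        np.testing.assert_allclose(out, 38.0)

    def test_alternating_breaths_chord_bounds(self):
        x = self.make_capno([36.0, 40.0] * 4)
        beats = np.arange(1.0, 30.0, 0.8)
        out = pp.etco2_per_beat(x, FS, beats)
        assert np.all(out >= 36.0) and np.all(out <= 40.0)

    def test_beats_before_first_breath_held(self):
        x = self.make_capno([38.0, 38.0, 38.0])
        beats = np.array([0.1, 0.5, 5.0, 9.0])
        out = pp.etco2_per_beat(x, FS, beats)
        assert out[0] == pytest.approx(38.0)

    def test_too_few_breaths_rejected(self):
        with pytest.raises(ValueError, match="breath"):
            pp.etco2_per_beat(np.full(int(4 * FS), 38.0), FS, np.arange(0, 4, 0.8))


class TestResample:
    def make_beats(self, values, bt):
        n = len(bt) - 1
        rr = np.diff(bt)
        with np.errstate(divide="ignore"):
            hr = 60 / rr
        return pp.BeatSeries(
            beat_times=np.asarray(bt, float),
            map_mmHg=values,
            mcav_left=values,
            mcav_right=values,
            rr_interval_s=rr,
            hr_bpm=hr,
            etco2_mmHg=values,
        )

    def test_cubic_polynomial_reproduced(self):
        bt = np.arange(0, 20.8, 0.8)
        vals = 0.1 * bt[:-1] ** 3 - bt[:-1] + 2
        uni = pp.resample_uniform(self.make_beats(vals, bt), 5.0)
        expected = 0.1 * uni.time_s**3 - uni.time_s + 2
        np.testing.assert_allclose(uni.map_mmHg, expected, rtol=1e-8)

    def test_constant(self):
        bt = np.arange(0, 10, 0.8)
        uni = pp.resample_uniform(self.make_beats(np.full(len(bt) - 1, 5.0), bt), 5.0)
        np.testing.assert_allclose(uni.map_mmHg, 5.0)

    def test_slow_sinusoid_within_one_percent(self):
        bt = np.arange(0, 60, 0.8)
        vals = np.sin(2 * np.pi * 0.1 * bt[:-1])
        uni = pp.resample_uniform(self.make_beats(vals, bt), 5.0)
        expected = np.sin(2 * np.pi * 0.1 * uni.time_s)
        assert np.abs(uni.map_mmHg - expected).max() < 0.01

    def test_duplicate_beats_rejected(self):
        bt = np.array([0.0, 0.8, 0.8, 1.6, 2.4, 3.2])
        with pytest.raises(ValueError):
            pp.resample_uniform(self.make_beats(np.ones(len(bt) - 1), bt), 5.0)


class TestNormalizeAndCalibrate:
    def test_constant_velocity_gives_zeros(self):
        out = pp.normalize_percent(np.full(600, 60.0), 5.0, 0.0, 60.0)
        np.testing.assert_allclose(out, 0.0)
        assert np.abs(out[150:300].mean()) < 1e-9

    def test_plateau_percent_arithmetic(self):
        x = np.full(600, 60.0)
        x[300:] = 66.0
        out = pp.normalize_percent(x, 5.0, 0.0, 60.0)
        np.testing.assert_allclose(out[300:], 10.0)
        assert abs(out[150:300].mean()) < 1e-9  # zero mean over the window

    def test_insufficient_baseline_rejected(self):
        with pytest.raises(ValueError):
            pp.normalize_percent(np.ones(600), 5.0, 0.0, 20.0)

    def test_calibration_identity_and_rescale(self):
        t = np.arange(int(40 * FS)) / FS
        x = 80.0 + 20.0 * (1 + np.sin(2 * np.pi * 1.2 * t)) / 1.0  # range [80, 120]
        same = pp.calibrate_bp(x, FS, (x[: int(30 * FS)].max(), x[: int(30 * FS)].min()))
        np.testing.assert_allclose(same, x, rtol=1e-12)
        y = pp.calibrate_bp((x - 80) / 40 * 40 + 60, FS, (120.0, 80.0))
        win = y[: int(30 * FS)]
        assert win.max() == pytest.approx(120.0) and win.min() == pytest.approx(80.0)

    def test_constant_waveform_rejected(self):
        with pytest.raises(ValueError):
            pp.calibrate_bp(np.full(int(40 * FS), 90.0), FS, (120.0, 80.0))


def test_pipeline_idempotent_on_clean_signal():
    """Spike removal + filtering leaves an already-clean, in-band signal
    essentially unchanged (passband ripple only)."""
    t = np.arange(int(30 * FS)) / FS
    x = 90 + 2 * np.sin(2 * np.pi * 0.1 * t) + 0.5 * np.sin(2 * np.pi * 1.0 * t)
    despiked, _ = pp.remove_spikes(x, FS)
    filtered = pp.lowpass_filter(despiked, FS)
    np.testing.assert_allclose(filtered[2500:-2500], x[2500:-2500], atol=5e-3)
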