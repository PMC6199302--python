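"""Filtering, interpolation, spike detection and waveform metrology."""

import numpy as np
import pytest
from scipy.signal import welch

import nervechip as nc
from nervechip.sigproc import (
    bandpass,
    detect_spikes,
    measure_spike,
    robust_noise_scale,
    snr_after_averaging,
    upsample_spline,
)

from conftest import single_fiber_recording


class TestBandpass:
    def test_dc_removed(self):
        x = np.full(5000, 42.0)
        y = bandpass(x, 50_000.0)
        assert np.max(np.abs(y)) < 1e-6

    def test_passband_tone_preserved_within_1db(self):
        fs = 50_000.0
        t = np.arange(int(fs)) / fs
        x = np.sin(2 * np.pi * 1_000.0 * t)
        y = bandpass(x, fs)
        # compare RMS over the central part, away from filter edges
        sl = slice(5000, -5000)
        gain_db = 20 * np.log10(np.std(y[sl]) / np.std(x[sl]))
        assert abs(gain_db) < 1.0

    def test_stopband_noise_attenuated(self):
        rng = np.random.default_rng(0)
        fs = 50_000.0
        x = rng.normal(size=200_000)
        y = bandpass(x, fs)
        f, p = welch(y, fs=fs, nperseg=4096)
        p1k = p[np.argmin(np.abs(f - 1_000.0))]
        p10k = p[np.argmin(np.abs(f - 10_000.0))]
        assert 10 * np.log10(p1k / p10k) >= 20.0

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(np.zeros(100), fs=5_000.0, hi=3_000.0)


class TestUpsample:
    def test_constant_stays_constant(self):
        y = upsample_spline(np.full(100, 3.5), 50_000.0, 500_000.0)
        assert np.allclose(y, 3.5)
        assert y.size == 1000

    def test_input_samples_recovered_exactly(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=200)
        y = upsample_spline(x, 50_000.0, 500_000.0)
        assert np.allclose(y[::10], x, atol=1e-12)

    def test_bandlimited_sinusoid_error_below_1pct(self):
        fs_in, fs_out = 50_000.0, 500_000.0
        t_in = np.arange(500) / fs_in
        x = np.sin(2 * np.pi * 1_000.0 * t_in)
        y = upsample_spline(x, fs_in, fs_out)
        t_out = np.arange(y.size) / fs_out
        ref = np.sin(2 * np.pi * 1_000.0 * t_out)
        # ignore the extrapolated tail beyond the last input sample
        n_ok = (x.size - 1) * 10
        assert np.max(np.abs(y[:n_ok] - ref[:n_ok])) < 0.01

    def test_non_integer_ratio_rejected(self):
        with pytest.raises(ValueError, match="integer multiple"):
            upsample_spline(np.zeros(10), 50_000.0, 125_000.0)


def _epoch_of(rec, pre=2e-3):
    t_p = rec.stim.pulse_times[0]
    i0 = int(round((t_p - pre) * rec.fs))
    i1 = int(round((t_p + rec.meta["epoch_length"]) * rec.fs))
    return rec.traces[:, i0:i1], -pre


class TestDetection:
    def test_noiseless_single_sfap_one_event_per_electrode(self, design8):
        rec = single_fiber_recording(design8, seed=0, include_artifacts=False)
        epoch, t0 = _epoch_of(rec)
        events = detect_spikes(epoch, rec.fs, t0=t0)
        assert [len(row) for row in events] == [1] * design8.n_electrodes

    def test_artifact_only_epoch_yields_no_events(self, design8):
        # artifacts present, biological amplitude negligible; artifact
        # windows blanked as in the analysis chain
        stim = nc.StimulusProtocol.periodic(1, 0.02, start=0.01)
        fiber = nc.FiberSpec(velocity=10.0, amplitude=0.0, width=0.22)
        rec = nc.simulate_recording(design8, [fiber], stim, noise_snr_db=None,
                                    seed=0, include_artifacts=True)
        epoch = rec.traces[:, int(0.008 * rec.fs): int(0.018 * rec.fs)]
        # blank covers the stimulation artifact (incl. its decay tail) and
        # the onset artifact at stim_to_entrance / v = 1 ms
        blank = [(-0.5e-3, 2e-3)]
        events = detect_spikes(epoch, rec.fs, t0=-2e-3, blank_windows=blank,
                               noise_window=(-2e-3, -0.5e-3))
        assert all(len(row) == 0 for row in events)

    def test_two_fibers_two_events_with_distinct_lags(self, design8):
        # 44 and 12 m/s fibres in one epoch, as recruited by low currents
        stim = nc.StimulusProtocol.periodic(1, 0.05, start=0.01)
        fibers = [
            nc.FiberSpec(velocity=44.0, amplitude=55.0, width=0.15),
            nc.FiberSpec(velocity=12.0, amplitude=40.0, width=0.22),
        ]
        rec = nc.simulate_recording(design8, fibers, stim, noise_snr_db=None,
                                    seed=0, include_artifacts=False,
                                    fs=500_000.0)
        epoch, t0 = _epoch_of(rec)
        events = detect_spikes(epoch, rec.fs, t0=t0)
        assert all(len(row) == 2 for row in events)
        lag_fast = events[-1][0].peak_time - events[0][0].peak_time
        lag_slow = events[-1][1].peak_time - events[0][1].peak_time
        span = (design8.n_electrodes - 1) * design8.pitch * 1e-3
        assert lag_fast == pytest.approx(span / 44.0, abs=2 / rec.fs)
        assert lag_slow == pytest.approx(span / 12.0, abs=2 / rec.fs)


class TestMetrology:
    @pytest.mark.parametrize(
        "width,velocity", [(0.03, 2.0), (0.1, 10.0), (0.22, 13.3), (0.3, 60.0)]
    )
    def test_round_trip_noiseless(self, design8, width, velocity):
        """Measured width/amplitude match generation values within 2%."""
        rec = single_fiber_recording(
            design8, velocity=velocity, width=width, seed=0,
            include_artifacts=False, fs=500_000.0,
        )
        epoch, t0 = _epoch_of(rec)
        events = detect_spikes(epoch, rec.fs, t0=t0)
        ev = [row[0] if row else None for row in events]
        m = measure_spike(epoch, rec.fs, ev, t0=t0)
        gains = nc.amplification_profile(
            np.asarray(design8.electrode_positions) / design8.channel_length
        )
        expected_amp = 55.0 * gains.max()
        assert m.width == pytest.approx(width, rel=0.02)
        assert m.amplitude == pytest.approx(expected_amp, rel=0.02)

    def test_reference_waveform_recovered_under_noise(self, design8):
        """55 uV / 0.22 ms / 30 dB inputs recovered within (5%, 5%, 1 dB)."""
        amps, widths, snrs = [], [], []
        for seed in range(8):
            rec = single_fiber_recording(
                design8, snr_db=30.0, seed=seed, include_artifacts=False
            )
            epoch, t0 = _epoch_of(rec)
            events = detect_spikes(epoch, rec.fs, t0=t0)
            ev = [row[0] if row else None for row in events]
            m = measure_spike(epoch, rec.fs, ev, t0=t0)
            gains = nc.amplification_profile(
                np.asarray(design8.electrode_positions) / design8.channel_length
            )
            amps.append(m.amplitude / gains.max())
            widths.append(m.width)
            snrs.append(m.snr_db)
        assert np.mean(amps) == pytest.approx(55.0, rel=0.05)
        assert np.mean(widths) == pytest.approx(0.22, rel=0.05)
        assert np.mean(snrs) == pytest.approx(30.0, abs=1.0)

    def test_best_electrode_sits_at_two_thirds(self, design8):
        rec = single_fiber_recording(design8, seed=0, include_artifacts=False)
        epoch, t0 = _epoch_of(rec)
        events = detect_spikes(epoch, rec.fs, t0=t0)
        ev = [row[0] if row else None for row in events]
        m = measure_spike(epoch, rec.fs, ev, t0=t0)
        z_best = design8.electrode_positions[m.best_electrode]
        assert abs(z_best / design8.channel_length - 0.67) <= (
            design8.pitch / 2.0 / design8.channel_length + 1e-9
        )

    def test_zero_trace_has_no_measurable_event(self):
        epoch = np.zeros((2, 1000))
        with pytest.raises(ValueError, match="no measurable event"):
            measure_spike(epoch, 50_000.0, [None, None], t0=-1e-3)

    def test_robust_scale_matches_gaussian_sigma(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 2.0, size=100_000)
        assert robust_noise_scale(x) == pytest.approx(2.0, rel=0.02)


class TestAveragingGain:
    def test_identity_and_closed_form(self):
        # coherent signal, incoherent noise: +10*log10(n) dB
        assert snr_after_averaging(20.0, 1) == 20.0
        assert snr_after_averaging(20.0, 10) == pytest.approx(30.0)
        assert snr_after_averaging(20.0, 100) == pytest.approx(40.0)

    def test_invalid_count_rejected(self):
        with pytest.raises(ValueError):
            snr_after_averaging(20.0, 0)

    def test_empirical_gain_matches_prediction(self, design8):
        """Averaging 50 repetitions raises measured SNR by ~10*log10(50)."""
        n_rep = 50
        rec = single_fiber_recording(
            design8, snr_db=15.0, seed=0, n_pulses=n_rep, include_artifacts=False
        )
        pre = 2e-3
        epochs = []
        n_len = int(round((pre + rec.meta["epoch_length"] - 1e-3) * rec.fs))
        for t_p in rec.stim.pulse_times:
            i0 = int(round((t_p - pre) * rec.fs))
            epochs.append(rec.traces[:, i0 : i0 + n_len])
        mean_epoch = np.mean(epochs, axis=0)
        events = detect_spikes(mean_epoch, rec.fs, t0=-pre)
        ev = [row[0] if row else None for row in events]
        m = measure_spike(mean_epoch, rec.fs, ev, t0=-pre)
        predicted = snr_after_averaging(15.0, n_rep)
        assert m.snr_db == pytest.approx(predicted, abs=1.5)
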