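"""Thermal model, NSD computation, kinetics fitting and statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.optimize import curve_fit

import nervechip as nc
from nervechip.neuroinhibition import (
    fit_kinetics,
    inhibition_anova,
    integration_windows,
    nsd_series,
    signal_density,
    snr_length_comparison,
    thermal_response,
)
from nervechip.simulate import ThermalCoupling, sfap_template, _RICKER_HALF

from conftest import NULL_COUPLING, small_session, single_fiber_recording


def make_illum(**kw):
    defaults = dict(pulse_onsets=(0.0,), pulse_duration=15.0, tau_polymer=3.22)
    defaults.update(kw)
    return nc.IlluminationProtocol(**defaults)


class TestThermalResponse:
    def test_zero_at_pulse_onset(self):
        tr = thermal_response(make_illum(), np.array([0.0]))
        assert tr.delta_T[0] == 0.0

    def test_one_time_constant_reaches_632_pct(self):
        illum = make_illum(delta_T_max=10.0)
        tr = thermal_response(illum, np.array([3.22]))
        assert tr.delta_T[0] == pytest.approx(10.0 * (1 - np.exp(-1)), rel=1e-9)

    def test_round_trip_fit_recovers_tau(self):
        """Fitting a noiseless 15-s pulse trace recovers tau to 3 decimals."""
        illum = make_illum()
        t = np.arange(0.0, 15.0, 0.1)
        tr = thermal_response(illum, t)

        def f(t, dT, tau):
            return dT * (1 - np.exp(-t / tau))

        (dT, tau), _ = curve_fit(f, t, tr.delta_T, p0=(5.0, 1.0))
        assert tau == pytest.approx(3.22, abs=1e-3)

    def test_pulse_train_rises_and_decays_monotonically(self):
        illum = nc.IlluminationProtocol.periodic(2, period=45.0, start=30.0)
        t = np.arange(0.0, 120.0, 0.05)
        tr = thermal_response(illum, t)
        assert np.all(tr.delta_T >= -1e-12)
        on = (t >= 30.0) & (t < 45.0)
        off = (t >= 45.0) & (t < 75.0)
        assert np.all(np.diff(tr.delta_T[on]) > 0)
        assert np.all(np.diff(tr.delta_T[off]) < 0)


class TestIntegrationWindows:
    def test_boundary_is_distance_over_threshold(self):
        # electrode 10 mm from the cathode -> 2 ms boundary at 5 m/s
        design = nc.MicrochannelDesign(
            channel_length=10.0, n_electrodes=2, pitch=4.0,
            electrode_positions=(2.0, 6.0), stim_to_entrance=4.0,
        )
        win = integration_windows(design, 1, epoch_end=0.05)
        assert win.fast_window[1] == pytest.approx(2e-3)
        assert win.slow_window[0] == pytest.approx(2e-3)

    @pytest.mark.parametrize("v,expected", [(12.0, "fast"), (2.0, "slow")])
    def test_arrivals_fall_in_their_class_window(self, design8, v, expected):
        e = 6
        d_m = design8.electrode_distances()[e] * 1e-3
        win = integration_windows(design8, e, epoch_end=0.05)
        arrival = d_m / v
        window = win.fast_window if expected == "fast" else win.slow_window
        assert window[0] <= arrival < window[1]

    def test_empty_slow_window_flagged(self, design8):
        with pytest.warns(UserWarning, match="slow window is empty"):
            win = integration_windows(design8, 7, epoch_end=1e-3)
        assert win.slow_empty


class TestSignalDensity:
    def test_zero_trace_zero_density(self):
        assert signal_density(np.zeros(1000), 25_000.0, (0.0, 0.01)) == 0.0

    def test_scaling_is_linear(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=1000)
        d1 = signal_density(x, 25_000.0, (0.0, 0.04))
        d2 = signal_density(0.5 * x, 25_000.0, (0.0, 0.04))
        assert d2 == pytest.approx(0.5 * d1)

    def test_template_density_matches_quadrature(self):
        """Rectified area of the template agrees with analytic quadrature."""
        width, amp, fs = 0.22, 55.0, 500_000.0
        tpl = sfap_template(width, amp, fs)
        density = signal_density(tpl, fs, (0.0, len(tpl) / fs))
        sigma = width * 1e-3 / (2 * _RICKER_HALF)
        oracle = quad(
            lambda t: abs(amp * (1 - (t / sigma) ** 2) * np.exp(-((t / sigma) ** 2) / 2)),
            -4 * sigma, 4 * sigma, points=[-sigma, sigma],
        )[0]
        assert density == pytest.approx(oracle, rel=0.10)

    def test_empty_window_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="empty"):
            assert signal_density(np.ones(100), 25_000.0, (0.01, 0.01)) == 0.0


class TestNSD:
    def test_control_mean_exactly_one(self, inhibition_session):
        df = nsd_series(inhibition_session, mask_electrodes=[3, 4, 5])
        ctrl = df[df["pulse_index"] < 10]
        means = ctrl.groupby(["electrode", "fiber_class"])["nsd"].mean()
        assert np.allclose(means.to_numpy(), 1.0, atol=1e-12)

    def test_slow_fibres_more_suppressed_than_fast(self, inhibition_session):
        df = nsd_series(inhibition_session, mask_electrodes=[3, 4, 5])
        lit = df[df["light_on"]]
        per_el = lit.groupby(["electrode", "fiber_class"])["nsd"].min().unstack()
        assert (per_el["slow"] < per_el["fast"]).all()

    def test_fast_nsd_recovers_after_light_off(self, inhibition_session):
        df = nsd_series(inhibition_session, mask_electrodes=[3, 4, 5])
        downstream = df[df["electrode"].isin([6, 7])]
        last = downstream["pulse_index"].max()
        tail = downstream[
            (~downstream["light_on"]) & (downstream["pulse_index"] > last - 3)
        ]
        fast_tail = tail[tail["fiber_class"] == "fast"]["nsd"]
        assert fast_tail.mean() == pytest.approx(1.0, abs=0.1)

    def test_slow_blocked_downstream_in_steady_state(self, design8, session_fibers):
        """Long steady illumination: slow contribution -> 0 downstream."""
        stim = nc.StimulusProtocol.periodic(25, 3.0, start=1.5)
        illum = nc.IlluminationProtocol(
            pulse_onsets=(30.0,), pulse_duration=40.0, spot_center=4.5
        )
        rec = nc.simulate_inhibition_session(
            design8, session_fibers, stim, illum, noise_snr_db=None, seed=2,
            fs=25_000.0,
        )
        df = nsd_series(rec, mask_electrodes=[3, 4, 5])
        late = df[(df["time_s"] > 30.0 + 5 * 6.44) & df["light_on"]]
        down = late[late["electrode"].isin([6, 7])]
        slow = down[down["fiber_class"] == "slow"]["nsd"]
        fast = down[down["fiber_class"] == "fast"]["nsd"]
        assert slow.mean() < 0.05
        assert fast.mean() > 0.5

    def test_zero_coupling_session_identical_to_dark(self, design8, session_fibers):
        stim = nc.StimulusProtocol.periodic(12, 3.0, start=1.5)
        illum = nc.IlluminationProtocol.periodic(1, start=15.0)
        lit = nc.simulate_inhibition_session(
            design8, session_fibers, stim, illum, coupling=NULL_COUPLING,
            noise_snr_db=20.0, seed=3, fs=25_000.0,
        )
        dark = nc.simulate_recording(
            design8, session_fibers, stim, noise_snr_db=20.0, seed=3,
            fs=25_000.0, duration=lit.duration,
        )
        assert np.array_equal(lit.traces, dark.traces)

    def test_control_overlapping_light_rejected(self, design8, session_fibers):
        stim = nc.StimulusProtocol.periodic(12, 3.0, start=1.5)
        illum = nc.IlluminationProtocol.periodic(1, start=6.0)
        rec = nc.simulate_inhibition_session(
            design8, session_fibers, stim, illum, noise_snr_db=None, seed=0,
            fs=25_000.0,
        )
        with pytest.raises(ValueError, match="precede the first light pulse"):
            nsd_series(rec)


class TestKinetics:
    def test_synthetic_kinetics_recovered_to_one_percent(self):
        """Noiseless NSD generated from the model round-trips tau and P."""
        illum = nc.IlluminationProtocol.periodic(2, period=45.0, start=0.0)
        tau, plateau = 4.0, 0.45
        times, nsd = [], []
        for cycle in (0.0, 45.0):
            t_rel = np.arange(0.5, 15.0, 1.5)
            times.extend(cycle + t_rel)
            nsd.extend(plateau + (1 - plateau) * np.exp(-t_rel / tau))
        df = pd.DataFrame(
            {
                "pulse_index": np.arange(len(times)),
                "time_s": times,
                "fiber_class": "fast",
                "nsd": nsd,
                "light_on": True,
                "electrode": 0,
            }
        )
        fit = fit_kinetics(df, illum, phase="inhibition")["fast"]
        assert fit.tau == pytest.approx(tau, rel=0.01)
        assert fit.plateau == pytest.approx(plateau, rel=0.01)
        assert fit.r_squared > 0.999

    def test_session_fast_tau_half_of_slow(self, inhibition_session):
        """Default coupling: tau_fast/tau_slow ~ 1/2, end NSD ratio ~ 2."""
        df = nsd_series(inhibition_session, mask_electrodes=[3, 4, 5])
        fits = fit_kinetics(df, inhibition_session.illumination, "inhibition")
        ratio = fits["fast"].tau / fits["slow"].tau
        assert 0.35 <= ratio <= 0.65
        lit = df[df["light_on"]]
        per_pulse = lit.groupby(["fiber_class", "pulse_index"])["nsd"].mean()
        end_fast = per_pulse["fast"].groupby(
            per_pulse["fast"].index // 5
        ).last().mean() if False else None
        # end-of-pulse NSD: last light-on pulse of each cycle
        last_on = lit.groupby("fiber_class").apply(
            lambda g: g[g["pulse_index"].isin(
                g.groupby((g["pulse_index"].diff() > 1).cumsum())["pulse_index"].max()
            )]["nsd"].mean(),
            include_groups=False,
        )
        assert 1.5 <= last_on["fast"] / last_on["slow"] <= 2.7

    def test_recovery_phase_returns_to_baseline(self, inhibition_session):
        df = nsd_series(inhibition_session, mask_electrodes=[3, 4, 5])
        fits = fit_kinetics(df, inhibition_session.illumination, "recovery")
        for cls in ("fast", "slow"):
            assert fits[cls].converged
            assert fits[cls].r_squared > 0.9

    def test_too_few_pulses_rejected(self):
        illum = make_illum()
        df = pd.DataFrame(
            {
                "pulse_index": [0, 1], "time_s": [1.0, 2.0],
                "fiber_class": "fast", "nsd": [0.9, 0.8],
                "light_on": True, "electrode": 0,
            }
        )
        with pytest.raises(ValueError, match=">= 5 pulses"):
            fit_kinetics(df, illum, "inhibition")


class TestInhibitionAnova:
    def test_default_coupling_significant_light_and_interaction(self):
        tables = []
        for s, seed in enumerate((11, 12)):
            rec = small_session(
                seed, snr_db=25.0, light_duration=15.0, light_period=45.0
            )
            df = nsd_series(rec, n_control=3)
            df["session"] = s
            tables.append(df)
        res = inhibition_anova(pd.concat(tables))
        anova = res["anova"]
        assert anova.loc["C(light_on)", "PR(>F)"] < 0.05
        assert anova.loc["C(light_on):C(fiber_class)", "PR(>F)"] < 0.05

    def test_posthoc_weak_fast_coupling_not_significant(self):
        weak = ThermalCoupling(
            c_fast=0.0, c_slow=0.06, velocity_temp_coeff=0.0,
            block_threshold=np.inf,
        )
        tables = []
        for s, seed in enumerate((21, 22)):
            rec = small_session(
                seed, coupling=weak, snr_db=18.0,
                light_duration=15.0, light_period=45.0,
            )
            df = nsd_series(rec, n_control=3)
            df["session"] = s
            tables.append(df)
        res = inhibition_anova(pd.concat(tables))
        assert res["posthoc"]["slow"] < 0.05
        assert res["posthoc"]["fast"] > 0.05

    def test_missing_factor_level_rejected(self):
        df = pd.DataFrame(
            {
                "nsd": [1.0, 0.9, 1.1, 0.8],
                "light_on": [True, True, False, False],
                "fiber_class": ["fast"] * 4,  # single level
                "electrode": [0, 1, 0, 1],
                "session": [0, 0, 1, 1],
            }
        )
        with pytest.raises(ValueError, match="fiber_class"):
            inhibition_anova(df)


class TestSNRLengthComparison:
    def test_identical_groups_omnibus_p_near_one(self):
        g = {4.0: [10.0, 11.0, 12.0, 13.0], 10.0: [10.0, 11.0, 12.0, 13.0]}
        res = snr_length_comparison(g)
        assert res["omnibus_p"] > 0.95

    def test_bonferroni_threshold_for_six_pairs(self):
        groups = {L: np.arange(5) + L for L in (4.0, 5.0, 6.0, 10.0)}
        res = snr_length_comparison(groups)
        assert len(res["pairwise"]) == 6
        assert res["adjusted_alpha"] == pytest.approx(0.05 / 6)

    def test_simulated_4_vs_10_mm_significant(self):
        """Longer channels amplify more: SNR groups separate significantly."""
        from nervechip.sigproc import detect_spikes, measure_spike

        groups = {}
        for L in (4.0, 10.0):
            vals = []
            for seed in range(10):
                design = nc.MicrochannelDesign.uniform(L, 2, 1.0)
                rec = single_fiber_recording(
                    design, velocity=10.0, seed=seed, include_artifacts=False,
                    snr_db=None,
                )
                # fixed-sigma noise: SNR then scales with channel gain
                rng = np.random.default_rng(100 + seed)
                rec.traces = rec.traces + rng.normal(0, 1.0, rec.traces.shape)
                pre = 2e-3
                t_p = rec.stim.pulse_times[0]
                i0 = int(round((t_p - pre) * rec.fs))
                i1 = int(round((t_p + rec.meta["epoch_length"]) * rec.fs))
                epoch = rec.traces[:, i0:i1]
                events = detect_spikes(epoch, rec.fs, t0=-pre)
                ev = [row[0] if row else None for row in events]
                m = measure_spike(epoch, rec.fs, ev, t0=-pre)
                vals.append(m.snr_db)
            groups[L] = vals
        res = snr_length_comparison(groups)
        assert res["pairwise"].loc[0, "significant"]
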