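"""Synthetic microchannel recordings.

Generates multichannel extracellular sessions with the structure the
downstream analyses assume: a stimulation artifact (simultaneous on all
electrodes), an onset artifact when the spike enters the channel (also
simultaneous), propagating fibre templates delayed by distance/velocity and
scaled by the along-channel amplification profile, calibrated Gaussian
noise, and - for illumination sessions - opto-thermal amplitude modulation
with class-specific first-order kinetics.

The template is a Ricker (second derivative of a Gaussian) wave,
triphasic and zero-mean like AC-coupled extracellular spikes, and is
parameterised directly by its full width at half amplitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from itertools import product
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .types import (
    FiberSpec,
    IlluminationProtocol,
    MicrochannelDesign,
    Recording,
    StimulusProtocol,
)

__all__ = [
    "amplification_profile",
    "channel_gain_scale",
    "sfap_template",
    "simulate_recording",
    "simulate_sr_sweep",
    "simulate_inhibition_session",
    "SweepRecord",
    "RecordingSet",
    "ThermalCoupling",
]

# Half-width constant of the Ricker wave: x such that (1-x^2)exp(-x^2/2)=1/2.
_RICKER_HALF: float = brentq(
    lambda x: (1.0 - x * x) * np.exp(-x * x / 2.0) - 0.5, 0.0, 1.0
)


def amplification_profile(u, exponent: float = 0.5):
    """Relative microchannel gain at fractional position ``u`` in [0, 1].

    The default closed form ``g(u) = u * (1-u)**exponent`` (normalised to 1
    at its maximum) vanishes at the entrance, peaks at ``u = 1/(1+exponent)``
    - 2/3 of the channel length for the default exponent - and falls off
    asymmetrically toward the exit, matching the measured along-channel
    amplification of sealed microchannels.

    Parameters
    ----------
    u : float or array
        Position as a fraction of channel length.
    exponent : float
        Shape parameter ``q > 0``; the peak sits at ``1/(1+q)``.
    """
    u_arr = np.asarray(u, dtype=float)
    if np.any(u_arr < 0) or np.any(u_arr > 1):
        raise ValueError("fractional position u must lie in [0, 1]")
    if exponent <= 0:
        raise ValueError("profile exponent must be positive")
    u_peak = 1.0 / (1.0 + exponent)
    norm = u_peak * (1.0 - u_peak) ** exponent
    g = u_arr * (1.0 - u_arr) ** exponent / norm
    return g if isinstance(u, np.ndarray) else float(g)


def channel_gain_scale(
    channel_length: float,
    calibration: Optional[Sequence[tuple[float, float]]] = None,
    reference_length: float = 10.0,
    allow_extrapolation: bool = False,
) -> float:
    """Peak-gain scale of a channel of the given length.

    Longer microchannels seal more of the fibre and amplify more.  The
    default calibration is linear in length (scale = L / reference_length);
    a measured calibration can be supplied as ``[(length_mm, scale), ...]``
    pairs and is linearly interpolated.
    """
    if channel_length <= 0:
        raise ValueError("channel_length must be positive")
    if calibration is None:
        return channel_length / reference_length
    table = sorted(calibration)
    lengths = np.array([p[0] for p in table], dtype=float)
    scales = np.array([p[1] for p in table], dtype=float)
    if not allow_extrapolation and (
        channel_length < lengths[0] or channel_length > lengths[-1]
    ):
        raise ValueError(
            f"channel_length {channel_length:g} mm outside calibration range "
            f"[{lengths[0]:g}, {lengths[-1]:g}] mm and extrapolation is disabled"
        )
    return float(np.interp(channel_length, lengths, scales))


def sfap_template(
    width: float,
    amplitude: float,
    fs: float,
    support_sigmas: float = 4.0,
) -> np.ndarray:
    """Sampled extracellular spike template.

    Parameters
    ----------
    width : float
        Full width of the main lobe at half amplitude, ms.
    amplitude : float
        Baseline-to-peak amplitude, uV.
    fs : float
        Sampling rate, Hz.  Must satisfy ``fs >= 10 / width`` so the main
        lobe carries enough samples for metrology.

    Returns
    -------
    ndarray
        Odd-length waveform centred on its peak; zero-mean to within the
        Gaussian truncation at ``support_sigmas``.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    width_s = width * 1e-3
    fs_required = 10.0 / width_s
    if fs < fs_required:
        raise ValueError(
            f"fs = {fs:g} Hz undersamples a {width:g} ms spike; "
            f"fs >= {fs_required:.0f} Hz required"
        )
    sigma = width_s / (2.0 * _RICKER_HALF)
    half_n = int(round(support_sigmas * sigma * fs))
    t = np.arange(-half_n, half_n + 1) / fs
    x = t / sigma
    return amplitude * (1.0 - x * x) * np.exp(-x * x / 2.0)


def _add_waveform(trace: np.ndarray, wave: np.ndarray, center_time: float, fs: float) -> None:
    """Add ``wave`` (peak at its centre sample) at ``center_time`` in place."""
    start = int(round(center_time * fs)) - len(wave) // 2
    stop = start + len(wave)
    if stop > trace.shape[-1]:
        raise ValueError(
            f"waveform at t = {center_time:.6f} s extends beyond the trace end "
            f"({trace.shape[-1] / fs:.6f} s); lengthen the recording"
        )
    lo = max(start, 0)
    trace[..., lo:stop] += wave[lo - start :]


def _stim_artifact(stim: StimulusProtocol, fs: float) -> np.ndarray:
    """Decaying-exponential stimulation artifact, sign set by polarity."""
    n = max(int(round(stim.artifact_duration_ms * 1e-3 * fs)), 2)
    t = np.arange(n) / fs
    tau = stim.artifact_duration_ms * 1e-3 / 4.0
    sign = -1.0 if stim.polarity == "cathodic" else 1.0
    return sign * stim.artifact_amplitude * np.exp(-t / tau)


# signature: (pulse_time, fiber) -> (per-electrode amplitude scale, velocity factor)
ModulationFn = Callable[[float, FiberSpec], tuple[np.ndarray, float]]


def simulate_recording(
    design: MicrochannelDesign,
    fibers: Sequence[FiberSpec],
    stim: StimulusProtocol,
    noise_snr_db: Optional[float] = None,
    seed: int = 0,
    fs: float = 50_000.0,
    duration: Optional[float] = None,
    epoch_margin: float = 2e-3,
    include_artifacts: bool = True,
    onset_amplitude: float = 30.0,
    onset_width_ms: float = 0.1,
    gain_exponent: float = 0.5,
    gain_calibration: Optional[Sequence[tuple[float, float]]] = None,
    reference_length: float = 10.0,
    illumination: Optional[IlluminationProtocol] = None,
    modulation: Optional[ModulationFn] = None,
) -> Recording:
    """Simulate one multichannel microchannel session.

    Per stimulus pulse each electrode receives: the stimulation artifact at
    the pulse time (identical and simultaneous on all electrodes), one onset
    artifact per fibre when it crosses the channel entrance (simultaneous),
    and the fibre template delayed by ``(stim_to_entrance + z_e) / v`` and
    scaled by ``amplification_profile(z_e / L) * channel_gain_scale(L)``.

    ``noise_snr_db`` calibrates additive white Gaussian noise so that the
    best-electrode SNR - 20*log10(peak biological amplitude / noise RMS) -
    equals the request.  ``None`` disables noise.  Identical
    ``(arguments, seed)`` give identical traces.
    """
    if not fibers:
        raise ValueError("at least one fiber is required")
    if noise_snr_db is not None and noise_snr_db < 0:
        warnings.warn("negative target SNR requested; signals will be buried")

    z = np.asarray(design.electrode_positions, dtype=float)
    gains = amplification_profile(z / design.channel_length, gain_exponent)
    gains = gains * channel_gain_scale(
        design.channel_length, gain_calibration, reference_length
    )

    slowest = min(f.velocity for f in fibers)
    widest = max(f.width for f in fibers)
    d_max_m = (design.stim_to_entrance + z[-1]) * 1e-3
    epoch_len = d_max_m / slowest + 6.0 * widest * 1e-3 + epoch_margin
    if duration is None:
        duration = stim.pulse_times[-1] + epoch_len
    n_samples = int(round(duration * fs))

    traces = np.zeros((design.n_electrodes, n_samples))
    peak_bio = np.zeros(design.n_electrodes)
    ground_truth: list[list[FiberSpec]] = []

    root = np.random.SeedSequence(seed)
    pulse_seeds = root.spawn(len(stim.pulse_times) + 1)
    noise_rng = np.random.default_rng(pulse_seeds[-1])

    stim_wave = _stim_artifact(stim, fs) if include_artifacts else None
    onset_times: list[list[float]] = []

    for p, t_p in enumerate(stim.pulse_times):
        rng_p = np.random.default_rng(pulse_seeds[p])
        if stim_wave is not None:
            stop = min(int(round(t_p * fs)) + len(stim_wave), n_samples)
            start = int(round(t_p * fs))
            traces[:, start:stop] += stim_wave[: stop - start]
        effective: list[FiberSpec] = []
        pulse_onsets: list[float] = []
        for fiber in fibers:
            if modulation is not None:
                scale_e, v_factor = modulation(t_p, fiber)
            else:
                scale_e, v_factor = np.ones(design.n_electrodes), 1.0
            scale_e = np.asarray(scale_e, dtype=float)
            if np.any(scale_e < 0):
                warnings.warn("thermal coupling produced a negative scale; clipping at 0")
                scale_e = np.clip(scale_e, 0.0, None)
            v = fiber.velocity * v_factor
            jitter = (
                rng_p.normal(0.0, fiber.latency_jitter_sd * 1e-3)
                if fiber.latency_jitter_sd > 0
                else 0.0
            )
            template = sfap_template(fiber.width, 1.0, fs)
            if include_artifacts and onset_amplitude > 0:
                onset_t = t_p + design.stim_to_entrance * 1e-3 / v + jitter
                onset_wave = _onset_artifact(onset_amplitude, onset_width_ms, fs)
                _add_waveform(traces, onset_wave, onset_t, fs)
                pulse_onsets.append(onset_t)
            for e in range(design.n_electrodes):
                amp = fiber.amplitude * gains[e] * scale_e[e]
                if amp == 0.0:
                    continue
                t_arr = t_p + (design.stim_to_entrance + z[e]) * 1e-3 / v + jitter
                _add_waveform(traces[e], amp * template, t_arr, fs)
                peak_bio[e] = max(peak_bio[e], amp)
            effective.append(replace(fiber, velocity=v))
        ground_truth.append(effective)
        onset_times.append(pulse_onsets)

    if noise_snr_db is not None:
        best_peak = peak_bio.max()
        if best_peak <= 0:
            raise ValueError("cannot calibrate noise: no biological signal present")
        sigma = best_peak / 10.0 ** (noise_snr_db / 20.0)
        traces += noise_rng.normal(0.0, sigma, size=traces.shape)

    return Recording(
        traces=traces,
        fs=fs,
        design=design,
        stim=stim,
        illumination=illumination,
        seed=seed,
        ground_truth=ground_truth,
        meta={
            "noise_snr_db": noise_snr_db,
            "epoch_length": epoch_len,
            "include_artifacts": include_artifacts,
            "onset_amplitude": onset_amplitude,
            "onset_width_ms": onset_width_ms,
            "onset_times": onset_times,
            "gain_exponent": gain_exponent,
        },
    )


def _onset_artifact(amplitude: float, width_ms: float, fs: float) -> np.ndarray:
    """Onset-artifact waveform; widened to the sampling limit if needed."""
    if fs >= 10.0 / (width_ms * 1e-3):
        return sfap_template(width_ms, amplitude, fs)
    return sfap_template(10.0 / fs * 1e3, amplitude, fs)


def reconstruct_artifacts(recording: Recording) -> np.ndarray:
    """Artifact-only traces rebuilt from a simulated recording's metadata.

    Both artifacts are deterministic given the protocol (stimulation
    artifact at each pulse time, onset artifact at each fibre's recorded
    entrance-crossing time), so they can be regenerated exactly and
    subtracted - the simulation counterpart of the supervised artifact
    rejection applied to bench recordings.
    """
    meta = recording.meta
    if not meta.get("include_artifacts", False):
        return np.zeros_like(recording.traces, dtype=float)
    fs = recording.fs
    out = np.zeros(recording.traces.shape, dtype=float)
    stim_wave = _stim_artifact(recording.stim, fs)
    for p, t_p in enumerate(recording.stim.pulse_times):
        start = int(round(t_p * fs))
        stop = min(start + len(stim_wave), out.shape[1])
        out[:, start:stop] += stim_wave[: stop - start]
        for onset_t in meta.get("onset_times", [[]] * (p + 1))[p]:
            wave = _onset_artifact(
                meta.get("onset_amplitude", 0.0), meta.get("onset_width_ms", 0.1), fs
            )
            _add_waveform(out, wave, onset_t, fs)
    return out


@dataclass
class SweepRecord:
    """One design x waveform grid point of a success-rate sweep."""

    design_id: int
    width: float
    velocity: float
    snr_db: float
    recording: Recording


@dataclass
class RecordingSet:
    """Collection of sweep recordings plus the seed that generated them."""

    records: list[SweepRecord]
    seed: int

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def simulate_sr_sweep(
    designs: Sequence[MicrochannelDesign],
    widths: Sequence[float],
    velocities: Sequence[float],
    snrs_db: Sequence[float],
    n_repetitions: int = 10,
    seed: int = 0,
    amplitude: float = 55.0,
    fs: Optional[float] = None,
    epoch_period: Optional[float] = None,
    **sim_kwargs,
) -> RecordingSet:
    """Simulate the factorial sweep feeding the success-rate model.

    One recording per ``design x (width, velocity, snr)`` grid point, each
    holding ``n_repetitions`` identical stimulus pulses of a single fibre.
    The sampling rate is raised automatically for narrow templates so every
    grid point is adequately sampled.
    """
    if not designs or not widths or not velocities or not snrs_db:
        raise ValueError("designs and waveform grids must be non-empty")
    if n_repetitions < 2:
        raise ValueError(
            "n_repetitions must be >= 2: the success-rate statistic is "
            "degenerate for a single repetition"
        )
    root = np.random.SeedSequence(seed)
    grid = list(product(widths, velocities, snrs_db))
    seeds = root.generate_state(len(designs) * len(grid))
    records: list[SweepRecord] = []
    k = 0
    for d_id, design in enumerate(designs):
        for width, velocity, snr in grid:
            fs_pt = fs if fs is not None else (
                500_000.0 if width < 0.2 else 50_000.0
            )
            fiber = FiberSpec(velocity=velocity, amplitude=amplitude, width=width)
            d_max = (design.stim_to_entrance + design.electrode_positions[-1]) * 1e-3
            period = epoch_period if epoch_period is not None else (
                d_max / velocity + 6.0 * width * 1e-3 + 4e-3
            )
            stim = StimulusProtocol.periodic(n_repetitions, period, start=period / 2)
            rec = simulate_recording(
                design,
                [fiber],
                stim,
                noise_snr_db=snr,
                seed=int(seeds[k]),
                fs=fs_pt,
                **sim_kwargs,
            )
            records.append(SweepRecord(d_id, width, velocity, snr, rec))
            k += 1
    return RecordingSet(records=records, seed=seed)


@dataclass(frozen=True)
class ThermalCoupling:
    """Phenomenological temperature -> fibre-amplitude coupling.

    During illumination the fibre amplitude at electrode position ``z`` is
    scaled by ``1 - r(t) * c_class * dT_ss(z)`` where ``dT_ss`` is the
    steady-state Gaussian heating footprint and ``r(t)`` a first-order
    activation with a class-specific time constant.  Slow (thin) fibres
    couple more strongly and about twice as slowly as fast fibres.  When
    the steady-state spot heating reaches ``block_threshold`` the slow
    fibres are additionally conduction-blocked downstream of the spot:
    their downstream scale relaxes toward 0 with the same slow kinetics
    (``scale = 1 - r(t)``), reaching zero contribution in the illuminated
    steady state and recovering fully after light off.  Fast-fibre
    conduction velocity rises slightly with temperature.  Units: couplings
    per degC, taus in s, threshold in degC.
    """

    c_fast: float = 0.031
    c_slow: float = 0.075
    tau_fast: float = 3.22
    tau_slow: float = 6.44
    block_threshold: float = 8.0
    velocity_temp_coeff: float = 0.003


def _square_response(t: float, transitions: list[tuple[float, bool]], tau: float) -> float:
    """First-order response r(t) in [0,1] to the light on/off square wave."""
    r = 0.0
    t_prev = None
    state = False
    for t_ev, new_state in transitions:
        if t_ev >= t:
            break
        if t_prev is not None:
            target = 1.0 if state else 0.0
            r = target + (r - target) * np.exp(-(t_ev - t_prev) / tau)
        t_prev = t_ev
        state = new_state
    if t_prev is None:
        return 0.0
    target = 1.0 if state else 0.0
    return float(target + (r - target) * np.exp(-(t - t_prev) / tau))


def simulate_inhibition_session(
    design: MicrochannelDesign,
    fibers: Sequence[FiberSpec],
    stim: StimulusProtocol,
    illumination: IlluminationProtocol,
    coupling: Optional[ThermalCoupling] = None,
    noise_snr_db: Optional[float] = None,
    seed: int = 0,
    fs: float = 25_000.0,
    **sim_kwargs,
) -> Recording:
    """Simulate an opto-thermal neuroinhibition session.

    Requires at least one slow (< 5 m/s) and one fast fibre.  During light
    pulses fibre amplitudes are suppressed according to the local heating
    footprint with class-specific kinetics (see :class:`ThermalCoupling`);
    all modulation reverses after light off.
    """
    classes = {f.fiber_class for f in fibers}
    if classes != {"slow", "fast"}:
        raise ValueError(
            "an inhibition session needs at least one slow (< 5 m/s) and one "
            f"fast fibre; got classes {sorted(classes)}"
        )
    coupling = coupling or ThermalCoupling()
    z = np.asarray(design.electrode_positions, dtype=float)
    dT_ss = illumination.delta_T_max * np.exp(
        -((z - illumination.spot_center) ** 2) / (2.0 * illumination.spot_sigma**2)
    )
    transitions = illumination.transitions()
    downstream = z > illumination.spot_center

    def modulation(t_pulse: float, fiber: FiberSpec) -> tuple[np.ndarray, float]:
        if fiber.fiber_class == "slow":
            tau, c = coupling.tau_slow, coupling.c_slow
        else:
            tau, c = coupling.tau_fast, coupling.c_fast
        r = _square_response(t_pulse, transitions, tau)
        scale = 1.0 - r * c * dT_ss
        v_factor = 1.0
        if fiber.fiber_class == "slow":
            if illumination.delta_T_max >= coupling.block_threshold:
                scale = scale.copy()
                scale[downstream] = 1.0 - r
        else:
            v_factor = 1.0 + coupling.velocity_temp_coeff * r * illumination.delta_T_max
        return scale, v_factor

    return simulate_recording(
        design,
        fibers,
        stim,
        noise_snr_db=noise_snr_db,
        seed=seed,
        fs=fs,
        illumination=illumination,
        modulation=modulation,
        **sim_kwargs,
    )
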