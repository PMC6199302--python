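"""Shared fixtures: reference designs, fibres and simulated sessions."""

from __future__ import annotations

import numpy as np
import pytest

import nervechip as nc
from nervechip.simulate import ThermalCoupling


@pytest.fixture(scope="session")
def design8() -> nc.MicrochannelDesign:
    """Standard 10 mm channel with 8 electrodes at 1 mm pitch."""
    return nc.MicrochannelDesign.uniform(10.0, 8, 1.0)


@pytest.fixture(scope="session")
def fig_fiber() -> nc.FiberSpec:
    """Reference single fibre: 55 uV, 0.22 ms, 13.3 m/s."""
    return nc.FiberSpec(velocity=13.3, amplitude=55.0, width=0.22)


def single_fiber_recording(
    design,
    velocity=13.3,
    amplitude=55.0,
    width=0.22,
    snr_db=None,
    seed=0,
    n_pulses=1,
    fs=50_000.0,
    **kwargs,
):
    """One-fibre recording with a compact periodic stimulus train."""
    d_max = (design.stim_to_entrance + design.electrode_positions[-1]) * 1e-3
    period = d_max / velocity + 6.0 * width * 1e-3 + 6e-3
    stim = nc.StimulusProtocol.periodic(n_pulses, period, start=period / 2)
    fiber = nc.FiberSpec(velocity=velocity, amplitude=amplitude, width=width)
    return nc.simulate_recording(
        design, [fiber], stim, noise_snr_db=snr_db, seed=seed, fs=fs, **kwargs
    )


@pytest.fixture(scope="session")
def session_fibers():
    """One fast and one slow fibre at the 25 kHz session rate."""
    return [nc.FiberSpec(10.0, 55.0, 0.4), nc.FiberSpec(2.0, 30.0, 0.6)]


@pytest.fixture(scope="session")
def inhibition_session(design8, session_fibers) -> nc.Recording:
    """Noiseless default-coupling illumination session (2 light cycles)."""
    stim = nc.StimulusProtocol.periodic(40, 3.0, start=1.5)
    illum = nc.IlluminationProtocol.periodic(2, period=45.0, start=30.0)
    return nc.simulate_inhibition_session(
        design8, session_fibers, stim, illum, noise_snr_db=None, seed=5, fs=25_000.0
    )


def small_session(
    seed,
    coupling=None,
    snr_db=25.0,
    n_electrodes=4,
    fs=25_000.0,
    light_duration=6.0,
    light_period=20.0,
    n_light=2,
    stim_period=1.0,
    start_light=4.0,
):
    """Compact illumination session for Monte-Carlo statistics."""
    design = nc.MicrochannelDesign.uniform(10.0, n_electrodes, 1.0)
    duration = start_light + n_light * light_period + 1.0
    n_pulses = int(duration / stim_period) - 1
    stim = nc.StimulusProtocol.periodic(n_pulses, stim_period, start=stim_period / 2)
    illum = nc.IlluminationProtocol.periodic(
        n_light,
        period=light_period,
        start=start_light,
        pulse_duration=light_duration,
        spot_center=float(np.mean(design.electrode_positions)),
    )
    fibers = [nc.FiberSpec(10.0, 55.0, 0.4), nc.FiberSpec(2.0, 30.0, 0.6)]
    return nc.simulate_inhibition_session(
        design,
        fibers,
        stim,
        illum,
        coupling=coupling,
        noise_snr_db=snr_db,
        seed=seed,
        fs=fs,
    )


NULL_COUPLING = ThermalCoupling(
    c_fast=0.0, c_slow=0.0, velocity_temp_coeff=0.0, block_threshold=np.inf
)
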