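"""Domain containers for microchannel nerve-on-a-chip recordings.

Unit conventions (used consistently across the package):

* positions and channel lengths in millimetres,
* spike widths in milliseconds,
* amplitudes in microvolts,
* session times in seconds from session start,
* sampling rates in Hz,
* conduction velocities in metres per second.

All windows are half-open ``[start, end)``; electrodes are indexed 0-based
from the recording-channel entrance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "MicrochannelDesign",
    "FiberSpec",
    "StimulusProtocol",
    "IlluminationProtocol",
    "Recording",
    "SLOW_FAST_THRESHOLD",
]

#: Conduction-velocity boundary between "slow" (thin) and "fast" (large
#: myelinated) fibre classes, m/s.
SLOW_FAST_THRESHOLD = 5.0


@dataclass(frozen=True)
class MicrochannelDesign:
    """Geometry of one recording microchannel electrode array.

    Parameters
    ----------
    channel_length : float
        Length of the insulating microchannel, mm.
    n_electrodes : int
        Number of recording electrodes inside the channel (>= 2).
    pitch : float
        Centre-to-centre electrode spacing, mm.
    electrode_positions : tuple of float
        Electrode centres measured from the channel entrance, mm; strictly
        increasing and strictly inside ``(0, channel_length)``.
    stim_to_entrance : float
        Distance from the stimulation cathode to the recording-channel
        entrance, mm.  Sets the artifact-to-signal latency budget.
    cross_section : tuple of float
        Channel cross-section, um x um (metadata only; the amplification
        model is phenomenological).
    """

    channel_length: float
    n_electrodes: int
    pitch: float
    electrode_positions: tuple[float, ...]
    stim_to_entrance: float = 10.0
    cross_section: tuple[float, float] = (100.0, 100.0)

    def __post_init__(self) -> None:
        if self.n_electrodes < 2:
            raise ValueError("a microchannel design needs at least 2 electrodes")
        if self.pitch <= 0:
            raise ValueError("electrode pitch must be positive")
        if self.channel_length <= 0:
            raise ValueError("channel_length must be positive")
        pos = np.asarray(self.electrode_positions, dtype=float)
        if pos.size != self.n_electrodes:
            raise ValueError(
                f"{self.n_electrodes} electrodes declared but "
                f"{pos.size} positions given"
            )
        if np.any(np.diff(pos) <= 0):
            raise ValueError("electrode_positions must be strictly increasing")
        if pos[0] <= 0 or pos[-1] >= self.channel_length:
            raise ValueError(
                "electrode positions must lie strictly inside (0, channel_length)"
            )
        if self.stim_to_entrance < 0:
            raise ValueError("stim_to_entrance must be non-negative")
        # uniform arrays must be consistent with the declared pitch
        gaps = np.diff(pos)
        if gaps.size and np.allclose(gaps, gaps[0]) and not np.isclose(
            gaps[0], self.pitch, rtol=1e-6
        ):
            raise ValueError(
                f"uniform electrode spacing {gaps[0]:g} mm inconsistent with "
                f"declared pitch {self.pitch:g} mm"
            )

    @classmethod
    def uniform(
        cls,
        channel_length: float,
        n_electrodes: int,
        pitch: float,
        stim_to_entrance: float = 10.0,
        cross_section: tuple[float, float] = (100.0, 100.0),
    ) -> "MicrochannelDesign":
        """Build a design with electrodes centred inside the channel."""
        span = (n_electrodes - 1) * pitch
        if span >= channel_length:
            raise ValueError(
                f"electrode array span {span:g} mm does not fit in a "
                f"{channel_length:g} mm channel"
            )
        first = (channel_length - span) / 2.0
        positions = tuple(first + i * pitch for i in range(n_electrodes))
        return cls(
            channel_length=channel_length,
            n_electrodes=n_electrodes,
            pitch=pitch,
            electrode_positions=positions,
            stim_to_entrance=stim_to_entrance,
            cross_section=cross_section,
        )

    def electrode_distances(self) -> np.ndarray:
        """Distance of every electrode from the stimulation cathode, mm."""
        return self.stim_to_entrance + np.asarray(self.electrode_positions)


@dataclass(frozen=True)
class FiberSpec:
    """One nerve fibre contributing a propagating extracellular spike.

    ``amplitude`` is the baseline-to-peak amplitude in uV *before* the
    microchannel amplification profile is applied; ``width`` is the full
    width of the main lobe at half amplitude, ms.
    """

    velocity: float
    amplitude: float
    width: float
    latency_jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.velocity <= 0:
            raise ValueError("fiber velocity must be positive")
        if self.amplitude < 0:
            raise ValueError("fiber amplitude must be non-negative")
        if self.width <= 0:
            raise ValueError("fiber width must be positive")
        if self.latency_jitter_sd < 0:
            raise ValueError("latency_jitter_sd must be non-negative")

    @property
    def fiber_class(self) -> str:
        """``"slow"`` below the 5 m/s threshold, ``"fast"`` otherwise."""
        return "slow" if self.velocity < SLOW_FAST_THRESHOLD else "fast"

    def with_velocity(self, velocity: float) -> "FiberSpec":
        return replace(self, velocity=velocity)


@dataclass(frozen=True)
class StimulusProtocol:
    """Electrical stimulation schedule for one session.

    ``artifact_amplitude``/``artifact_duration`` parameterise the
    stimulation artifact injected simultaneously on all electrodes.
    """

    pulse_times: tuple[float, ...]
    polarity: str = "cathodic"
    phase_width_us: float = 50.0
    artifact_amplitude: float = 200.0
    artifact_duration_ms: float = 0.2

    def __post_init__(self) -> None:
        if len(self.pulse_times) < 1:
            raise ValueError("at least one stimulus pulse is required")
        t = np.asarray(self.pulse_times, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("pulse_times must be strictly increasing")
        if self.polarity not in ("cathodic", "anodic"):
            raise ValueError("polarity must be 'cathodic' or 'anodic'")
        if self.artifact_duration_ms <= 0:
            raise ValueError("artifact_duration_ms must be positive")

    @property
    def repetitions(self) -> int:
        return len(self.pulse_times)

    @classmethod
    def periodic(
        cls,
        n_pulses: int,
        period: float,
        start: float = 0.0,
        **kwargs,
    ) -> "StimulusProtocol":
        """Regular train: ``n_pulses`` pulses ``period`` seconds apart."""
        times = tuple(start + i * period for i in range(n_pulses))
        return cls(pulse_times=times, **kwargs)


@dataclass(frozen=True)
class IlluminationProtocol:
    """Light-pulse schedule driving the photothermal film.

    Defaults follow the study conditions: a 15-s pulse every 45 s focused
    on one electrode, first-order surface heating with a 3.22-s time
    constant and a Gaussian spatial footprint a few millimetres wide.
    """

    pulse_onsets: tuple[float, ...]
    pulse_duration: float = 15.0
    spot_center: float = 4.5
    spot_sigma: float = 1.5
    delta_T_max: float = 10.0
    tau_polymer: float = 3.22

    def __post_init__(self) -> None:
        if self.pulse_duration <= 0:
            raise ValueError("pulse_duration must be positive")
        if self.tau_polymer <= 0:
            raise ValueError("tau_polymer must be positive")
        if self.spot_sigma <= 0:
            raise ValueError("spot_sigma must be positive")
        if self.delta_T_max < 0:
            raise ValueError("delta_T_max must be non-negative")
        on = np.asarray(self.pulse_onsets, dtype=float)
        if on.size and np.any(np.diff(on) < self.pulse_duration):
            raise ValueError("illumination pulses must not overlap")

    def light_on(self, t: float) -> bool:
        """Whether the light is on at session time ``t`` (half-open pulses)."""
        for onset in self.pulse_onsets:
            if onset <= t < onset + self.pulse_duration:
                return True
        return False

    def transitions(self) -> list[tuple[float, bool]]:
        """Sorted (time, light_state_after) events."""
        ev: list[tuple[float, bool]] = []
        for onset in self.pulse_onsets:
            ev.append((onset, True))
            ev.append((onset + self.pulse_duration, False))
        return sorted(ev)

    @classmethod
    def periodic(
        cls,
        n_pulses: int,
        period: float = 45.0,
        start: float = 30.0,
        pulse_duration: float = 15.0,
        **kwargs,
    ) -> "IlluminationProtocol":
        onsets = tuple(start + i * period for i in range(n_pulses))
        return cls(pulse_onsets=onsets, pulse_duration=pulse_duration, **kwargs)


@dataclass
class Recording:
    """Multichannel extracellular recording plus its provenance.

    ``traces`` is shaped ``(n_electrodes, n_samples)`` in uV.  For
    simulated recordings ``ground_truth`` holds, per stimulus pulse, the
    effective :class:`FiberSpec` list (after any thermal modulation of
    velocity) so that analyses can be validated against generation values.
    """

    traces: np.ndarray
    fs: float
    design: MicrochannelDesign
    stim: StimulusProtocol
    illumination: Optional[IlluminationProtocol] = None
    seed: Optional[int] = None
    ground_truth: Optional[list[list[FiberSpec]]] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.traces.ndim != 2:
            raise ValueError("traces must be 2-D (electrodes x samples)")
        if self.traces.shape[0] != self.design.n_electrodes:
            raise ValueError(
                f"traces have {self.traces.shape[0]} rows but design declares "
                f"{self.design.n_electrodes} electrodes"
            )
        if not np.all(np.isfinite(self.traces)):
            raise ValueError("traces must be finite")
        last = self.stim.pulse_times[-1]
        if last * self.fs > self.traces.shape[1]:
            raise ValueError("trace shorter than the stimulus protocol")

    @property
    def n_electrodes(self) -> int:
        return self.traces.shape[0]

    @property
    def n_samples(self) -> int:
        return self.traces.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs
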