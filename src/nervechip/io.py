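"""Recording container, configuration and result-table plumbing.

The binary container is HDF5: ``/traces`` (float32, electrodes x samples),
``/meta`` (JSON-encoded design, protocols and seed) and ``/ground_truth``
(JSON).  Small fixtures can round-trip through a long-format CSV
(``time, electrode, value``).  Configuration is strict YAML - unknown keys
are fatal - and every pipeline run writes a manifest carrying the config
hash and seed so any table can be regenerated.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Union

import h5py
import numpy as np
import pandas as pd
import yaml

from .types import (
    FiberSpec,
    IlluminationProtocol,
    MicrochannelDesign,
    Recording,
    StimulusProtocol,
)

__all__ = [
    "read_recording",
    "write_recording",
    "recording_to_csv",
    "recording_from_csv",
    "default_config",
    "load_config",
    "dump_config",
    "config_hash",
    "SessionManifest",
]

PathLike = Union[str, Path]


def _meta_payload(rec: Recording) -> dict:
    payload = {
        "fs": rec.fs,
        "seed": rec.seed,
        "design": asdict(rec.design),
        "stim": asdict(rec.stim),
        "illumination": asdict(rec.illumination) if rec.illumination else None,
        "meta": rec.meta,
    }
    return payload


def write_recording(recording: Recording, path: PathLike) -> None:
    """Write a recording to the documented HDF5 layout."""
    with h5py.File(path, "w") as f:
        f.create_dataset("traces", data=recording.traces.astype(np.float32))
        f.create_dataset("meta", data=json.dumps(_meta_payload(recording)))
        gt = None
        if recording.ground_truth is not None:
            gt = [[asdict(fib) for fib in pulse] for pulse in recording.ground_truth]
        f.create_dataset("ground_truth", data=json.dumps(gt))


def read_recording(path: PathLike) -> Recording:
    """Read a recording container, validating layout and invariants."""
    with h5py.File(path, "r") as f:
        for name in ("traces", "meta"):
            if name not in f:
                raise ValueError(f"{path}: missing dataset '/{name}'")
        traces = np.asarray(f["traces"], dtype=np.float32)
        meta = json.loads(f["meta"][()])
        gt_raw = json.loads(f["ground_truth"][()]) if "ground_truth" in f else None
    fs = meta.get("fs", 0)
    if not fs or fs <= 0:
        raise ValueError(f"{path}: invalid sampling rate fs = {fs!r}")
    design = MicrochannelDesign(
        channel_length=meta["design"]["channel_length"],
        n_electrodes=meta["design"]["n_electrodes"],
        pitch=meta["design"]["pitch"],
        electrode_positions=tuple(meta["design"]["electrode_positions"]),
        stim_to_entrance=meta["design"]["stim_to_entrance"],
        cross_section=tuple(meta["design"]["cross_section"]),
    )
    stim_d = dict(meta["stim"])
    stim_d["pulse_times"] = tuple(stim_d["pulse_times"])
    stim = StimulusProtocol(**stim_d)
    illum = None
    if meta.get("illumination"):
        ild = dict(meta["illumination"])
        ild["pulse_onsets"] = tuple(ild["pulse_onsets"])
        illum = IlluminationProtocol(**ild)
    ground_truth = None
    if gt_raw is not None:
        ground_truth = [
            [FiberSpec(**fib) for fib in pulse] for pulse in gt_raw
        ]
    return Recording(
        traces=traces,
        fs=float(fs),
        design=design,
        stim=stim,
        illumination=illum,
        seed=meta.get("seed"),
        ground_truth=ground_truth,
        meta=meta.get("meta", {}),
    )


def recording_to_csv(recording: Recording, path: PathLike) -> None:
    """Long-format text export (``time, electrode, value``) for fixtures."""
    n_el, n = recording.traces.shape
    t = np.repeat(np.arange(n) / recording.fs, n_el)
    el = np.tile(np.arange(n_el), n)
    vals = recording.traces.astype(np.float32).T.ravel()
    df = pd.DataFrame({"time": t, "electrode": el, "value": vals})
    df.to_csv(path, index=False)


def recording_from_csv(
    path: PathLike, template: Recording
) -> Recording:
    """Re-import a CSV export; protocol metadata comes from ``template``."""
    df = pd.read_csv(path)
    n_el = int(df["electrode"].max()) + 1
    n = len(df) // n_el
    traces = (
        df.sort_values(["time", "electrode"])["value"]
        .to_numpy(dtype=np.float32)
        .reshape(n, n_el)
        .T
    )
    return Recording(
        traces=traces,
        fs=template.fs,
        design=template.design,
        stim=template.stim,
        illumination=template.illumination,
        seed=template.seed,
        ground_truth=template.ground_truth,
        meta=dict(template.meta),
    )


# ---------------------------------------------------------------------------
# configuration


def default_config() -> dict:
    """Full default configuration (the values `--dump-config` prints)."""
    return {
        "seed": 0,
        "mode": "sr_sweep",
        "design": {
            "channel_length": 10.0,
            "n_electrodes": 8,
            "pitch": 1.0,
            "stim_to_entrance": 10.0,
        },
        "designs": None,  # optional list of design dicts for sweeps
        "fibers": [
            {"velocity": 10.0, "amplitude": 55.0, "width": 0.4},
            {"velocity": 2.0, "amplitude": 30.0, "width": 0.6},
        ],
        "stimulus": {
            "n_pulses": 10,
            "period": 3.0,
            "polarity": "cathodic",
            "phase_width_us": 50.0,
            "artifact_amplitude": 200.0,
            "artifact_duration_ms": 0.2,
        },
        "illumination": {
            "n_pulses": 3,
            "period": 45.0,
            "start": 30.0,
            "pulse_duration": 15.0,
            "spot_center": 4.5,
            "spot_sigma": 1.5,
            "delta_T_max": 10.0,
            "tau_polymer": 3.22,
        },
        "noise": {"snr_db": 30.0},
        "sweep": {
            "widths": [0.22],
            "velocities": [5.0, 13.3, 30.0],
            "snrs_db": [10.0, 20.0, 30.0],
            "n_repetitions": 10,
        },
        "vsr": {"v_min": 1.0, "v_max": 60.0, "fs_analysis": 500000.0},
        "processing": {"lo": 100.0, "hi": 3000.0, "filter_order": 1},
    }


def _check_keys(config: dict, defaults: dict, path: str = "") -> None:
    for key, value in config.items():
        if key not in defaults:
            valid = sorted(defaults)
            raise ValueError(
                f"unknown config key '{path}{key}'; valid keys here: {valid}"
            )
        if isinstance(value, dict) and isinstance(defaults[key], dict):
            _check_keys(value, defaults[key], path=f"{path}{key}.")


def load_config(source: Union[PathLike, str, dict, None]) -> dict:
    """Merge a YAML file / string / dict over the defaults (strict keys)."""
    base = default_config()
    if source is None:
        return base
    if isinstance(source, dict):
        user = source
    else:
        p = Path(str(source))
        try:
            is_file = p.exists()
        except OSError:
            is_file = False
        text = p.read_text() if is_file else str(source)
        user = yaml.safe_load(text) or {}
    if not isinstance(user, dict):
        raise ValueError("config must be a mapping")
    _check_keys(user, base)

    def merge(dst: dict, src: dict) -> dict:
        for k, v in src.items():
            if isinstance(v, dict) and isinstance(dst.get(k), dict):
                dst[k] = merge(dict(dst[k]), v)
            else:
                dst[k] = v
        return dst

    return merge(base, user)


def dump_config(config: Optional[dict] = None) -> str:
    return yaml.safe_dump(config or default_config(), sort_keys=True)


def config_hash(config: dict) -> str:
    """Stable content hash of a configuration."""
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


@dataclass
class SessionManifest:
    """Provenance record written alongside every pipeline run."""

    config_hash: str
    seed: int
    package_version: str
    outputs: list[str]
    timestamp: str = ""

    @classmethod
    def create(cls, config: dict, outputs: list[str]) -> "SessionManifest":
        from . import __version__

        return cls(
            config_hash=config_hash(config),
            seed=int(config.get("seed", 0)),
            package_version=__version__,
            outputs=sorted(str(o) for o in outputs),
            timestamp=datetime.now(timezone.utc).isoformat(),
        )

    def write(self, path: PathLike) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")
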