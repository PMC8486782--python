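"""File I/O: HDF5 recordings, WAV export, tidy CSV result tables.

HDF5 layout (one file per run):

    /ecp, /rw, /remote   waveform datasets, each with ``sample_rate`` and
                         ``units`` attributes (plus calibration where
                         applicable)
    /stimulus            JSON blob of the StimulusSpec (schema versioned)
    /model, /damage      parameter groups

WAV export writes one float WAV per channel; it preserves the waveform
and sample rate only (metadata is lossy), so HDF5 is the canonical
container.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy.io import wavfile

from .model import CochlearModel, DamageMap
from .simulate import MultiChannelRecording
from .stimulus import StimulusSpec

IO_SCHEMA_VERSION = 1
_CHANNELS = ("ecp", "rw", "remote")


class RecordingIOError(ValueError):
    pass


def save_recording(path: str | Path, rec: MultiChannelRecording) -> None:
    """Write a recording to one HDF5 file (canonical container)."""
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = IO_SCHEMA_VERSION
        if rec.seed is not None:
            f.attrs["seed"] = rec.seed
        for ch in _CHANNELS:
            ds = f.create_dataset(ch, data=rec.waveform(ch))
            for key, val in rec.channel_meta[ch].items():
                ds.attrs[key] = val
        f.create_dataset("stimulus", data=rec.spec.to_json())
        for name, params in (("model", rec.model_params),
                             ("damage", rec.damage_params)):
            grp = f.create_group(name)
            for key, val in params.items():
                grp.attrs[key] = (np.asarray(val) if isinstance(val, list)
                                  else val)


def load_recording(path: str | Path) -> MultiChannelRecording:
    """Read a recording written by :func:`save_recording`."""
    try:
        with h5py.File(path, "r") as f:
            for ch in ("ecp", "rw", "remote", "stimulus"):
                if ch not in f:
                    raise RecordingIOError(
                        f"{path}: missing dataset {ch!r}; not a valid "
                        "recording file")
            spec = StimulusSpec.from_json(f["stimulus"][()].decode()
                                          if isinstance(f["stimulus"][()], bytes)
                                          else str(f["stimulus"][()]))
            meta = {}
            waves = {}
            for ch in _CHANNELS:
                waves[ch] = f[ch][:]
                meta[ch] = dict(f[ch].attrs)
            model_params = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                            for k, v in f["model"].attrs.items()}
            damage_params = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                             for k, v in f["damage"].attrs.items()}
            seed = int(f.attrs["seed"]) if "seed" in f.attrs else None
    except OSError as exc:
        raise RecordingIOError(f"{path}: cannot read HDF5 file ({exc})") from exc
    rec = MultiChannelRecording(waves["ecp"], waves["rw"], waves["remote"],
                                spec, meta, model_params, damage_params, seed)
    _validate(rec)
    return rec


def _validate(rec: MultiChannelRecording) -> None:
    spec = rec.spec
    for ch in _CHANNELS:
        expected = spec.frames_presented * rec.frame_length(ch)
        if rec.waveform(ch).size != expected:
            raise RecordingIOError(
                f"channel {ch!r}: {rec.waveform(ch).size} samples, expected "
                f"{expected} ({spec.frames_presented} frames)")


def export_wav(path_stem: str | Path, rec: MultiChannelRecording) -> list[Path]:
    """Write one float32 WAV per channel (lossy: metadata not preserved)."""
    out = []
    for ch in _CHANNELS:
        p = Path(f"{path_stem}_{ch}.wav")
        wavfile.write(p, int(rec.sample_rate(ch)),
                      rec.waveform(ch).astype(np.float32))
        out.append(p)
    return out


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration dictionary."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def results_frame(rows: list[dict], config: dict | None = None,
                  seed: int | None = None) -> pd.DataFrame:
    """Tidy long-format results table carrying config hash and seed."""
    df = pd.DataFrame(rows)
    df["schema_version"] = IO_SCHEMA_VERSION
    if config is not None:
        df["config_hash"] = config_hash(config)
    if seed is not None:
        df["seed"] = seed
    return df


def model_from_params(params: dict) -> CochlearModel:
    return CochlearModel.from_dict(params)


def damage_from_params(params: dict) -> DamageMap:
    return DamageMap.from_dict(params)
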