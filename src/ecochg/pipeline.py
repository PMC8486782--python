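"""High-level runs: sensitivity sweeps, I/O curves, DP sweeps, replicates.

These helpers tie the simulator to the analysis exactly the way the
recording protocol does: one recording per tone/level combination, frame
averaging over the center frames, bin-exact component extraction with
noise floors, and sensitivity/phase referenced to the simultaneously
"recorded" ear-canal pressure.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .model import CochlearModel, DamageMap
from .stimulus import single_tone, two_tone, snap_frequency
from .simulate import MultiChannelRecording, simulate
from .spectral import (ResponseCurve, average_frames, estimate_component,
                       sensitivity_and_phase, mean_group_delay)
from .characterize import IOCurve
from .dpgram import DPGram, dpgram

ECOCHG_CHANNELS = ("rw", "remote")


def snapped_grid(f_lo: float, f_hi: float, points_per_octave: int = 6,
                 sample_rate: float = 200_000.0, frame_length: int = 4096
                 ) -> np.ndarray:
    """Log-spaced frequency grid snapped to the bin grid, duplicates dropped."""
    n = int(np.ceil(np.log2(f_hi / f_lo) * points_per_octave)) + 1
    nominal = f_lo * 2.0 ** (np.arange(n) / points_per_octave)
    nominal = nominal[nominal <= f_hi * 1.0001]
    snapped = [snap_frequency(f, sample_rate, frame_length) for f in nominal]
    return np.unique(snapped)


def analyze_tone(rec: MultiChannelRecording, frequency: float | None = None
                 ) -> dict[str, dict]:
    """Component estimates and sensitivity/phase for one tone recording.

    Returns ``{channel: {"estimate", "sensitivity_db", "phase_rel", "valid"}}``
    for the eCochG channels plus ``{"ecp": {"estimate"}}``.
    """
    spec = rec.spec
    if frequency is None:
        frequency = spec.components[0].frequency_snapped
    out = {}
    ests = {}
    for ch in ("ecp",) + ECOCHG_CHANNELS:
        rate = rec.sample_rate(ch)
        if frequency >= rate / 2:
            ests[ch] = None
            continue
        mean, _, _ = average_frames(rec.waveform(ch), rec.frame_length(ch),
                                    spec.frames_presented)
        ests[ch] = estimate_component(mean, frequency, rate, spec, ch)
    out["ecp"] = {"estimate": ests["ecp"]}
    for ch in ECOCHG_CHANNELS:
        if ests[ch] is None:
            out[ch] = {"estimate": None, "sensitivity_db": np.nan,
                       "phase_rel": np.nan, "valid": False}
            continue
        sens, phase, valid = sensitivity_and_phase(ests[ch], ests["ecp"])
        out[ch] = {"estimate": ests[ch], "sensitivity_db": sens,
                   "phase_rel": phase, "valid": valid}
    return out


def sensitivity_sweep(model: CochlearModel, damage: DamageMap,
                      frequencies: np.ndarray, level_db_spl: float,
                      seed: int | None = None) -> dict[str, ResponseCurve]:
    """Sensitivity/phase-vs-frequency curves at one level, both channels."""
    rows = {ch: {"sens": [], "phase": [], "valid": [], "amp": []}
            for ch in ECOCHG_CHANNELS}
    freqs = np.asarray(sorted(frequencies), dtype=float)
    for i, f in enumerate(freqs):
        run_seed = None if seed is None else seed + i
        rec = simulate(single_tone(f, level_db_spl,
                                   sample_rate=model.sample_rate),
                       model, damage, run_seed)
        res = analyze_tone(rec)
        for ch in ECOCHG_CHANNELS:
            rows[ch]["sens"].append(res[ch]["sensitivity_db"])
            rows[ch]["phase"].append(res[ch]["phase_rel"])
            rows[ch]["valid"].append(res[ch]["valid"])
            est = res[ch]["estimate"]
            rows[ch]["amp"].append(np.nan if est is None else est.amplitude)
    return {ch: ResponseCurve(freqs, level_db_spl,
                              rows[ch]["sens"], rows[ch]["phase"],
                              rows[ch]["valid"], channel=ch,
                              amplitude=np.asarray(rows[ch]["amp"]))
            for ch in ECOCHG_CHANNELS}


def band_group_delay(model: CochlearModel, damage: DamageMap,
                     f_lo: float, f_hi: float, level_db_spl: float,
                     channel: str = "rw", points_per_octave: int = 8,
                     seed: int | None = None) -> float:
    """Least-squares group delay (ms) over a frequency band at one level."""
    freqs = snapped_grid(f_lo, f_hi, points_per_octave,
                         model.sample_rate)
    curves = sensitivity_sweep(model, damage, freqs, level_db_spl, seed)
    return mean_group_delay(curves[channel])


def io_curve(model: CochlearModel, damage: DamageMap, frequency: float,
             levels_db_spl: np.ndarray, channel: str = "rw",
             seed: int | None = None) -> IOCurve:
    """I/O curve: response amplitude (dB re 1 V RMS) versus stimulus level."""
    amps, valids = [], []
    f = snap_frequency(frequency, model.sample_rate)
    for i, level in enumerate(levels_db_spl):
        run_seed = None if seed is None else seed + 1000 * i
        rec = simulate(single_tone(f, level, sample_rate=model.sample_rate),
                       model, damage, run_seed)
        res = analyze_tone(rec)
        est = res[channel]["estimate"]
        amps.append(-np.inf if est is None or est.amplitude <= 0
                    else 20.0 * np.log10(est.amplitude))
        valids.append(res[channel]["valid"])
    return IOCurve(f, np.asarray(levels_db_spl, dtype=float),
                   np.asarray(amps), np.asarray(valids), channel)


def dp_sweep(model: CochlearModel, damage: DamageMap,
             f2_grid: np.ndarray | None = None, l1: float = 60.0,
             l2: float = 60.0, ratio: float = 1.25,
             seed: int | None = None) -> DPGram:
    """DP-gram over an f2 sweep (default 1.6-12.8 kHz, 6 points/octave)."""
    if f2_grid is None:
        f2_grid = snapped_grid(1600.0, 12_800.0, 6, model.sample_rate)
    recs = []
    for i, f2 in enumerate(f2_grid):
        run_seed = None if seed is None else seed + 10_000 * i
        spec = two_tone(f2, l1, l2, ratio, sample_rate=model.sample_rate)
        recs.append(simulate(spec, model, damage, run_seed))
    return dpgram(recs)


def replicate_model(model: CochlearModel, rng: np.random.Generator,
                    gain_jitter_db: float = 2.0,
                    neural_jitter_db: float = 3.0,
                    sat_jitter_db: float = 1.0) -> CochlearModel:
    """Simulated inter-animal variability: jittered gains and saturation.

    Draws log-normal (Gaussian in dB) perturbations of the overall
    electrode gains, the neural gain, and the MET saturation point.
    """
    g = 10.0 ** (rng.normal(0.0, gain_jitter_db) / 20.0)
    ng = 10.0 ** (rng.normal(0.0, neural_jitter_db) / 20.0)
    ms = 10.0 ** (rng.normal(0.0, sat_jitter_db) / 20.0)
    return replace(model,
                   rw_gain=model.rw_gain * g,
                   remote_gain=model.remote_gain * g,
                   neural_gain=model.neural_gain * ng,
                   met_saturation_pa=model.met_saturation_pa * ms)
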