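"""Forward simulation: stimulus -> per-place drives -> eCochG/DPOAE channels.

The protocol's stimuli are exactly periodic with one 4096-sample frame,
and every model stage (steady-state LTI filtering, static nonlinearity,
pure delay) preserves that periodicity.  The simulator therefore computes
the steady-state response of a single frame in the frequency domain and
tiles it to the full protocol length; ramps, recording-chain filters,
decimation of the remote channel, and seeded per-sample noise are applied
on the way out.  This makes frame periodicity of the noise-free response
exact by construction and keeps full 402-frame protocols cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import CochlearModel, DamageMap
from .stimulus import (StimulusSpec, BuiltStimulus, build_stimulus,
                       frequency_bin, raised_cosine_envelope)


class SimulationError(ValueError):
    pass


# default intermodulation orders (m, n) -> m*f1 + n*f2 radiated as DPOAEs
DEFAULT_DP_ORDERS = ((2, -1), (3, -2), (-1, 1), (-1, 2))


def traveling_wave(frame: np.ndarray, model: CochlearModel,
                   damage: DamageMap) -> np.ndarray:
    """Per-place drive waveforms (one steady-state frame each).

    Each place sees the stimulus through its zero-phase gain profile,
    scaled by the place's OHC damage factor and delayed by the place's
    accumulated wave delay.  Returns an array of shape (n_places, n).
    """
    frame = np.asarray(frame, dtype=float)
    n = frame.size
    spectrum = np.fft.rfft(frame)
    freqs = np.fft.rfftfreq(n, d=1.0 / model.sample_rate)
    cf = model.place_cf()
    gain = model.filter_gain(freqs, cf) * damage.ohc_gain[:, None]
    delay = model.wave_delay_s(cf)[:, None]
    h = gain * np.exp(-2j * np.pi * freqs[None, :] * delay)
    return np.fft.irfft(spectrum[None, :] * h, n=n, axis=1)


def met_currents(drives: np.ndarray, model: CochlearModel) -> np.ndarray:
    """Transduction currents: the Boltzmann stage, the sole DP source."""
    return model.boltzmann(drives)


def cm_waveform(drives: np.ndarray, model: CochlearModel) -> dict[str, np.ndarray]:
    """Sensory (cochlear microphonic) potential per electrode.

    The CM is the weighted sum of MET currents over all places; phase
    topology of the drives decides which region survives the sum.
    """
    currents = met_currents(drives, model)
    weights = model.electrode_weights()
    n = model.n_places
    return {ch: w @ currents / n for ch, w in weights.items()}


def _phase_lock_gain(model: CochlearModel, freqs: np.ndarray) -> np.ndarray:
    """Low-pass of nerve-fiber phase locking: unity to ~1 kHz, steep
    rolloff above, zero beyond the 5-kHz phase-locking limit."""
    with np.errstate(divide="ignore"):
        rel = np.where(freqs > 0, freqs / model.phase_lock_corner_hz, 1.0)
        g = np.minimum(1.0, rel ** (-model.phase_lock_order))
    g[freqs > model.phase_lock_limit_hz] = 0.0
    return g


def _neural_window(model: CochlearModel, spec: StimulusSpec) -> np.ndarray:
    """Per-place weight of the neurophonic-contributing region.

    Fibers innervating places ~``neural_offset_octaves`` basal of a tone's
    CL dominate the phase-locked response (near-CL contributions cancel,
    extreme-base drives are too weak); modeled as a log-Gaussian window
    centered one octave basal of each component's CL.
    """
    cf = model.place_cf()
    w = np.zeros(model.n_places)
    for comp in spec.components:
        center = comp.frequency_snapped * 2.0 ** model.neural_offset_octaves
        w = np.maximum(w, np.exp(
            -0.5 * (np.log2(cf / center) / model.neural_window_oct) ** 2))
    return w


def neurophonic_waveform(drives: np.ndarray, model: CochlearModel,
                         damage: DamageMap, spec: StimulusSpec
                         ) -> dict[str, np.ndarray]:
    """Phase-locked neural potential per electrode.

    Per place: half-wave rectification of the drive, compressive power law
    (exponent ``neural_exponent``) with a soft rate-saturation cap, then
    the (shared, hence commuting) phase-locking low-pass and synaptic
    delay after the weighted sum over the contributing region.
    """
    n = model.n_places
    if damage.neural_scale == 0.0 or model.neural_gain == 0.0:
        zero = np.zeros(drives.shape[1])
        return {ch: zero.copy() for ch in ("rw", "remote")}
    rect = np.maximum(drives, 0.0)
    y = rect ** model.neural_exponent
    if np.isfinite(model.neural_sat):
        y = model.neural_sat * np.tanh(y / model.neural_sat)
    window = _neural_window(model, spec)
    weights = model.electrode_weights()
    scale = model.neural_gain * damage.neural_scale
    freqs = np.fft.rfftfreq(drives.shape[1], d=1.0 / model.sample_rate)
    h = _phase_lock_gain(model, freqs) * np.exp(
        -2j * np.pi * freqs * model.synaptic_delay_s)
    h[0] = 0.0  # DC (summating-potential-like) component is out of scope
    out = {}
    for ch, w in weights.items():
        summed = (w * window) @ y / n * scale
        out[ch] = np.fft.irfft(np.fft.rfft(summed) * h, n=drives.shape[1])
    return out


def dpoae_waveform(drives: np.ndarray, model: CochlearModel,
                   damage: DamageMap, spec: StimulusSpec,
                   dp_orders=DEFAULT_DP_ORDERS) -> np.ndarray:
    """Ear-canal distortion-product pressure (one steady frame).

    Each place's Boltzmann output is read at the requested intermodulation
    bins, weighted by the f2 drive envelope at that place, given the
    place's wave delay a second time (reverse propagation to the ear
    canal), summed, and scaled by a fixed emission constant.  Single-tone
    stimuli contribute zero.
    """
    n_samp = drives.shape[1]
    if len(spec.components) != 2:
        return np.zeros(n_samp)
    currents = met_currents(drives, model)
    spectra = np.fft.rfft(currents, axis=1)
    cf = model.place_cf()
    f1, f2 = sorted(c.frequency_snapped for c in spec.components)
    env_f2 = (model.filter_gain(np.array([f2]), cf)[:, 0] * damage.ohc_gain) ** 2
    if env_f2.max() > 0:
        env_f2 = env_f2 / env_f2.max()
    delay = model.wave_delay_s(cf)
    t = np.arange(n_samp) / model.sample_rate
    out = np.zeros(n_samp)
    for m, nn in dp_orders:
        f_dp = m * f1 + nn * f2
        if f_dp <= 0 or f_dp >= model.sample_rate / 2:
            continue
        k = frequency_bin(f_dp, model.sample_rate, n_samp)
        if k < 1:
            continue
        coeff = 2.0 * spectra[:, k] / n_samp          # peak-amplitude convention
        source = coeff * env_f2 * np.exp(-2j * np.pi * f_dp * delay)
        s = model.emission_const * source.mean()
        out += np.real(s * np.exp(2j * np.pi * f_dp * t))
    return out


def dp_place_response(drives: np.ndarray, model: CochlearModel,
                      damage: DamageMap, spec: StimulusSpec,
                      dp_orders=DEFAULT_DP_ORDERS) -> dict[str, np.ndarray]:
    """OHC currents evoked by the re-entrant distortion-product wave.

    The intracochlear DP launched by the Boltzmann stage propagates
    forward at its own frequency and peaks at its own characteristic
    place.  Because that wave is tens of dB below the stimulus tones it
    rides the low-level cochlear-amplifier gain near its CL — gain that
    the loud stimulus waves, being deep in the compressive regime, do not
    see.  The resulting transduction currents are the place-specific part
    of the eCochG-DP: damage at the DP frequency's place removes them.

    Returns one steady frame per electrode; zero for single-tone stimuli
    or a linear (met_saturation = inf) transduction stage.
    """
    n_samp = drives.shape[1]
    zero = {ch: np.zeros(n_samp) for ch in ("rw", "remote")}
    if len(spec.components) != 2 or model.dp_relay_gain == 0.0:
        return zero
    currents = met_currents(drives, model)
    spectra = np.fft.rfft(currents, axis=1)
    cf = model.place_cf()
    delay = model.wave_delay_s(cf)
    weights = model.electrode_weights()
    f1, f2 = sorted(c.frequency_snapped for c in spec.components)
    t = np.arange(n_samp) / model.sample_rate
    out = {ch: np.zeros(n_samp) for ch in ("rw", "remote")}
    for m, nn in dp_orders:
        f_dp = m * f1 + nn * f2
        if f_dp <= 0 or f_dp >= model.sample_rate / 2:
            continue
        k = frequency_bin(f_dp, model.sample_rate, n_samp)
        if k < 1:
            continue
        coeff = 2.0 * spectra[:, k] / n_samp
        # net launched wave, referenced back to the base
        s = np.mean(coeff * np.exp(2j * np.pi * f_dp * delay))
        # forward place response at f_dp with low-level gain at its CL
        amp = 1.0 + (model.dp_relay_amp - 1.0) * np.exp(
            -0.5 * (np.log2(cf / f_dp) / model.dp_relay_sigma_oct) ** 2)
        g = model.filter_gain(np.array([f_dp]), cf)[:, 0]
        relay = (model.dp_relay_gain * s * g * amp * damage.ohc_gain *
                 np.exp(-2j * np.pi * f_dp * delay))
        for ch, w in weights.items():
            a = (w @ relay) / model.n_places
            out[ch] += np.real(a * np.exp(2j * np.pi * f_dp * t))
    return out


@dataclass
class MultiChannelRecording:
    """Time-aligned ECP / RW-eCochG / remote-eCochG waveforms for one run."""

    ecp: np.ndarray              # Pa, 200 kHz
    rw: np.ndarray               # V, 200 kHz
    remote: np.ndarray           # V, 25 kHz
    spec: StimulusSpec
    channel_meta: dict = field(default_factory=dict)
    model_params: dict = field(default_factory=dict)
    damage_params: dict = field(default_factory=dict)
    seed: int | None = None

    def frame_length(self, channel: str) -> int:
        if channel == "remote":
            return int(round(self.spec.frame_length *
                             self.channel_meta["remote"]["sample_rate"] /
                             self.spec.sample_rate))
        return self.spec.frame_length

    def waveform(self, channel: str) -> np.ndarray:
        return {"ecp": self.ecp, "rw": self.rw, "remote": self.remote}[channel]

    def sample_rate(self, channel: str) -> float:
        return self.channel_meta[channel]["sample_rate"]


def _decimate_frame(frame: np.ndarray, factor: int) -> np.ndarray:
    """Exact band-limited decimation of a periodic frame (shared bin grid)."""
    n = frame.size
    n_out = n // factor
    spectrum = np.fft.rfft(frame)[: n_out // 2 + 1] * (n_out / n)
    spectrum[-1] = 0.0  # remote Nyquist bin
    return np.fft.irfft(spectrum, n=n_out)


def _apply_chain(frame: np.ndarray, response: np.ndarray) -> np.ndarray:
    return np.fft.irfft(np.fft.rfft(frame) * response, n=frame.size)


def record(built: BuiltStimulus, cm: dict[str, np.ndarray],
           neuro: dict[str, np.ndarray], dp_frame: np.ndarray,
           model: CochlearModel, damage: DamageMap,
           seed: int | None = None) -> MultiChannelRecording:
    """Assemble calibrated multi-channel waveforms with chains and noise.

    RW channel: band-passed (0.1-30 kHz) sensory+neural sum at the RW
    electrode.  Remote channel: first-order 7.5-kHz low-pass, then exact
    decimation to 25 kHz.  ECP: stimulus pressure plus emitted DPs.
    Noise is white Gaussian per channel, seeded.
    """
    spec = built.spec
    n_frame = spec.frame_length
    freqs = np.fft.rfftfreq(n_frame, d=1.0 / model.sample_rate)

    rw_frame = _apply_chain(cm["rw"] + neuro["rw"], model.rw_chain_response(freqs))
    rem_full = _apply_chain(cm["remote"] + neuro["remote"],
                            model.remote_chain_response(freqs))
    factor = int(round(model.sample_rate / model.remote_rate))
    rem_frame = _decimate_frame(rem_full, factor)

    n_ramp = int(round(spec.ramp_duration * model.sample_rate))
    env = raised_cosine_envelope(spec.n_samples, n_ramp)
    n_ramp_rem = int(round(spec.ramp_duration * model.remote_rate))
    n_rem_total = spec.frames_presented * rem_frame.size
    env_rem = raised_cosine_envelope(n_rem_total, n_ramp_rem)

    rng = np.random.default_rng(seed)
    ecp = built.pressure + np.tile(dp_frame, spec.frames_presented) * env
    if model.ecp_noise_pa > 0:
        ecp = ecp + rng.normal(0.0, model.ecp_noise_pa, ecp.size)
    rw = np.tile(rw_frame, spec.frames_presented) * env
    if model.rw_noise_v > 0:
        rw = rw + rng.normal(0.0, model.rw_noise_v, rw.size)
    remote = np.tile(rem_frame, spec.frames_presented) * env_rem
    if model.remote_noise_v > 0:
        remote = remote + rng.normal(0.0, model.remote_noise_v, remote.size)

    meta = {
        "ecp": {"sample_rate": model.sample_rate, "units": "Pa",
                "calibration_v_per_pa": 1.0, "filter": "none"},
        "rw": {"sample_rate": model.sample_rate, "units": "V",
               "filter": f"bandpass {model.rw_highpass_hz}-{model.rw_lowpass_hz} Hz"},
        "remote": {"sample_rate": model.remote_rate, "units": "V",
                   "filter": f"first-order lowpass {model.remote_corner_hz} Hz"},
    }
    return MultiChannelRecording(ecp, rw, remote, spec, meta,
                                 model.to_dict(), damage.to_dict(), seed)


def simulate(spec: StimulusSpec, model: CochlearModel, damage: DamageMap,
             seed: int | None = None) -> MultiChannelRecording:
    """Full forward run: build stimulus, drive the cochlea, record."""
    built = build_stimulus(spec)
    drives = traveling_wave(built.steady_frame, model, damage)
    cm = cm_waveform(drives, model)
    relay = dp_place_response(drives, model, damage, spec)
    for ch in cm:
        cm[ch] = cm[ch] + relay[ch]
    neuro = neurophonic_waveform(drives, model, damage, spec)
    dp = dpoae_waveform(drives, model, damage, spec)
    return record(built, cm, neuro, dp, model, damage, seed)
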