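"""Frame-synchronous one- and two-tone stimulus construction.

The recording protocol presents tones in frames of 4096 samples at 200 kHz
(20.48 ms per frame).  Every tone frequency is snapped to an integer number
of cycles per frame, which places it exactly on the 48.828125-Hz DFT bin
grid shared by the 200-kHz/4096-sample and 25-kHz/512-sample channels.
Waveforms are presented for 52 frames (levels above 70 dB SPL) or 402
frames (70 dB SPL and below); raised-cosine on/off ramps of 5 ms occupy
the first/last frame, which the analysis discards.

Sound pressure level is RMS re 20 uPa, so a tone of level L dB SPL has
peak amplitude sqrt(2) * 20e-6 * 10**(L/20) Pa.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

P_REF = 20e-6  # Pa, SPL reference
DEFAULT_SAMPLE_RATE = 200_000.0
DEFAULT_FRAME_LENGTH = 4096
DEFAULT_RAMP = 0.005
SPEC_SCHEMA_VERSION = 1


class StimulusError(ValueError):
    """Raised for stimulus specifications that violate the protocol."""


def snap_frequency(f_nominal: float, sample_rate: float = DEFAULT_SAMPLE_RATE,
                   frame_length: int = DEFAULT_FRAME_LENGTH) -> float:
    """Snap a frequency to the nearest integer-cycles-per-frame value.

    Returns the frequency ``k * sample_rate / frame_length`` with
    ``k = round(f_nominal * frame_length / sample_rate)``.  Rejects
    frequencies that would round to zero cycles or land at/above Nyquist.
    """
    if not np.isfinite(f_nominal) or f_nominal <= 0:
        raise StimulusError(f"frequency must be positive and finite, got {f_nominal!r}")
    if f_nominal >= sample_rate / 2:
        raise StimulusError(
            f"frequency {f_nominal} Hz is at/above Nyquist ({sample_rate / 2} Hz)")
    k = round(f_nominal * frame_length / sample_rate)
    if k < 1:
        raise StimulusError(
            f"frequency {f_nominal} Hz is below half a bin "
            f"({0.5 * sample_rate / frame_length} Hz); cannot snap to >= 1 cycle/frame")
    f_snapped = k * sample_rate / frame_length
    if f_snapped >= sample_rate / 2:
        raise StimulusError(
            f"frequency {f_nominal} Hz snaps to Nyquist; rejected")
    return f_snapped


def frequency_bin(frequency: float, sample_rate: float = DEFAULT_SAMPLE_RATE,
                  frame_length: int = DEFAULT_FRAME_LENGTH) -> int:
    """Integer DFT bin (cycles per frame) of an on-grid frequency."""
    k = frequency * frame_length / sample_rate
    k_int = round(k)
    if abs(k - k_int) > 1e-6:
        raise StimulusError(f"frequency {frequency} Hz is not on the bin grid "
                            f"(k = {k})")
    return k_int


def protocol_frames(level_db_spl: float) -> tuple[int, int]:
    """Number of frames presented/analyzed for a given stimulus level.

    Levels above 70 dB SPL use the short protocol (52 presented, 50
    analyzed); 70 dB SPL and below use the long protocol (402/400).  The
    boundary level 70 dB is assigned to the long protocol (more averaging).
    """
    if not np.isfinite(level_db_spl):
        raise StimulusError("level must be finite")
    if level_db_spl > 70.0:
        return 52, 50
    return 402, 400


def spl_to_peak_pa(level_db_spl: float) -> float:
    """Peak pressure (Pa) of a pure tone with the given RMS SPL."""
    return np.sqrt(2.0) * P_REF * 10.0 ** (level_db_spl / 20.0)


@dataclass(frozen=True)
class ToneComponent:
    """One tone of a frame-synchronous stimulus."""

    frequency_nominal: float        # Hz, requested
    frequency_snapped: float        # Hz, integer cycles per frame
    level_db_spl: float             # dB SPL, RMS re 20 uPa
    start_phase: float = 0.0        # cycles

    def cycles_per_frame(self, sample_rate: float = DEFAULT_SAMPLE_RATE,
                         frame_length: int = DEFAULT_FRAME_LENGTH) -> int:
        return frequency_bin(self.frequency_snapped, sample_rate, frame_length)

    @property
    def peak_pa(self) -> float:
        return spl_to_peak_pa(self.level_db_spl)


def make_tone(f_nominal: float, level_db_spl: float, start_phase: float = 0.0,
              sample_rate: float = DEFAULT_SAMPLE_RATE,
              frame_length: int = DEFAULT_FRAME_LENGTH) -> ToneComponent:
    f_snapped = snap_frequency(f_nominal, sample_rate, frame_length)
    return ToneComponent(f_nominal, f_snapped, level_db_spl, start_phase)


@dataclass
class StimulusSpec:
    """Complete description of a one- or two-tone frame-synchronous stimulus."""

    components: list[ToneComponent]
    sample_rate: float = DEFAULT_SAMPLE_RATE
    frame_length: int = DEFAULT_FRAME_LENGTH
    frames_presented: int = 0
    frames_analyzed: int = 0
    ramp_duration: float = DEFAULT_RAMP
    ratio: float | None = None      # realized f2/f1 for two-tone specs

    def __post_init__(self) -> None:
        if not 1 <= len(self.components) <= 2:
            raise StimulusError("a stimulus has one or two tone components")
        if self.frames_presented == 0:
            level = max(c.level_db_spl for c in self.components)
            self.frames_presented, self.frames_analyzed = protocol_frames(level)
        if self.frames_analyzed != self.frames_presented - 2:
            raise StimulusError("frames_analyzed must equal frames_presented - 2")
        for c in self.components:
            # integer-cycle check; raises if off-grid
            frequency_bin(c.frequency_snapped, self.sample_rate, self.frame_length)
            half_bin = 0.5 * self.sample_rate / self.frame_length
            if abs(c.frequency_snapped - c.frequency_nominal) > half_bin + 1e-9:
                raise StimulusError("snapped frequency deviates by more than half a bin")
        if len(self.components) == 2 and self.ratio is None:
            f = sorted(c.frequency_snapped for c in self.components)
            self.ratio = f[1] / f[0]
        n_ramp = int(round(self.ramp_duration * self.sample_rate))
        if 2 * n_ramp > self.frames_presented * self.frame_length:
            raise StimulusError("ramps longer than half the waveform")

    @property
    def duration(self) -> float:
        """Total presented duration in seconds."""
        return self.frames_presented * self.frame_length / self.sample_rate

    @property
    def frame_duration(self) -> float:
        return self.frame_length / self.sample_rate

    @property
    def bin_width(self) -> float:
        return self.sample_rate / self.frame_length

    @property
    def n_samples(self) -> int:
        return self.frames_presented * self.frame_length

    def frequencies(self) -> list[float]:
        return [c.frequency_snapped for c in self.components]

    # --- DP bookkeeping -------------------------------------------------
    def dp_frequency(self, m: int = 2, n: int = -1) -> float:
        """Frequency of the intermodulation product m*f1 + n*f2 (f1 < f2)."""
        if len(self.components) != 2:
            raise StimulusError("DP frequencies require a two-tone stimulus")
        f1, f2 = sorted(c.frequency_snapped for c in self.components)
        f = m * f1 + n * f2
        if f <= 0:
            raise StimulusError(f"DP order ({m},{n}) has non-positive frequency")
        return f

    # --- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["schema_version"] = SPEC_SCHEMA_VERSION
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusSpec":
        d = dict(d)
        d.pop("schema_version", None)
        d["components"] = [ToneComponent(**c) for c in d["components"]]
        return cls(**d)

    @classmethod
    def from_json(cls, s: str) -> "StimulusSpec":
        return cls.from_dict(json.loads(s))


def single_tone(frequency: float, level_db_spl: float, start_phase: float = 0.0,
                sample_rate: float = DEFAULT_SAMPLE_RATE,
                frame_length: int = DEFAULT_FRAME_LENGTH) -> StimulusSpec:
    """One-tone spec with protocol geometry chosen from the level."""
    tone = make_tone(frequency, level_db_spl, start_phase, sample_rate, frame_length)
    return StimulusSpec([tone], sample_rate=sample_rate, frame_length=frame_length)


def two_tone(f2: float, l1: float, l2: float, ratio: float = 1.25,
             sample_rate: float = DEFAULT_SAMPLE_RATE,
             frame_length: int = DEFAULT_FRAME_LENGTH) -> StimulusSpec:
    """Two-tone spec with f2/f1 near ``ratio``.

    f2 is snapped first, then f1 = snap(f2/ratio); the realized ratio is
    recorded on the returned StimulusSpec.  Both tones therefore sit on the shared bin grid
    and so does 2*f1 - f2.
    """
    t2 = make_tone(f2, l2, 0.0, sample_rate, frame_length)
    t1 = make_tone(t2.frequency_snapped / ratio, l1, 0.0, sample_rate, frame_length)
    if t1.frequency_snapped >= t2.frequency_snapped:
        raise StimulusError("f1 must snap strictly below f2")
    spec = StimulusSpec([t1, t2], sample_rate=sample_rate, frame_length=frame_length)
    return spec


def raised_cosine_envelope(n_samples: int, n_ramp: int) -> np.ndarray:
    """Unity envelope with raised-cosine on/off ramps of ``n_ramp`` samples."""
    env = np.ones(n_samples)
    if n_ramp > 0:
        t = np.arange(n_ramp) / n_ramp
        ramp = 0.5 * (1.0 - np.cos(np.pi * t))
        env[:n_ramp] = ramp
        env[-n_ramp:] = ramp[::-1]
    return env


@dataclass
class BuiltStimulus:
    """Synthesized stimulus: full ramped waveform plus the steady frame."""

    spec: StimulusSpec
    pressure: np.ndarray                 # Pa, full ramped waveform (sum)
    component_pressures: list[np.ndarray] = field(repr=False, default_factory=list)
    steady_frame: np.ndarray = None      # Pa, one un-ramped frame (sum)
    component_frames: list[np.ndarray] = field(repr=False, default_factory=list)


def build_stimulus(spec: StimulusSpec) -> BuiltStimulus:
    """Synthesize the pressure waveform of a stimulus spec.

    Components are generated separately and summed (mirroring separate D/A
    channels and speakers), so the stimulus itself contains no
    intermodulation.  Ramps are applied per component over the full
    waveform; the analyzed center section is exactly frame-periodic.
    """
    n_ramp = int(round(spec.ramp_duration * spec.sample_rate))
    n_total = spec.n_samples
    t_frame = np.arange(spec.frame_length) / spec.sample_rate
    env = raised_cosine_envelope(n_total, n_ramp)

    component_frames = []
    component_pressures = []
    for c in spec.components:
        frame = c.peak_pa * np.sin(
            2 * np.pi * (c.frequency_snapped * t_frame + c.start_phase))
        component_frames.append(frame)
        component_pressures.append(np.tile(frame, spec.frames_presented) * env)

    steady_frame = np.sum(component_frames, axis=0)
    pressure = np.sum(component_pressures, axis=0)
    return BuiltStimulus(spec, pressure, component_pressures,
                         steady_frame, component_frames)
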