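"""Synchronous frame averaging and bin-exact Fourier component extraction.

All stimulus and distortion-product frequencies lie on the DFT bin grid of
one analysis frame, so amplitude and phase come from a single DFT bin with
no window and no leakage.  Amplitudes use the RMS convention; phases are in
cycles in (-0.5, 0.5] with a cosine reference, and the reported response
phase is relative to the ear-canal pressure at the same frequency.

The noise floor of a component is the median amplitude of the six nearest
bins (three each side) that are not themselves stimulus or intermodulation
bins; an estimate is SNR-valid when its amplitude exceeds the floor by
6 dB.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .stimulus import frequency_bin, StimulusSpec, StimulusError

SNR_VALID_DB = 6.0


class AnalysisError(ValueError):
    pass


def average_frames(waveform: np.ndarray, frame_length: int,
                   frames_presented: int | None = None
                   ) -> tuple[np.ndarray, np.ndarray, int]:
    """Synchronous average over the center frames of a recording.

    Drops the first and last frame (they carry the on/off ramps) and
    returns ``(mean_frame, sem_frame, n_averaged)`` where ``sem_frame`` is
    the per-sample standard error across the averaged frames.
    """
    waveform = np.asarray(waveform)
    if waveform.ndim != 1:
        raise AnalysisError("waveform must be one-dimensional")
    if frames_presented is None:
        if waveform.size % frame_length:
            raise AnalysisError(
                f"waveform length {waveform.size} is not a multiple of the "
                f"frame length {frame_length}")
        frames_presented = waveform.size // frame_length
    if waveform.size != frames_presented * frame_length:
        raise AnalysisError(
            f"expected {frames_presented} x {frame_length} samples, "
            f"got {waveform.size}")
    if frames_presented < 3:
        raise AnalysisError("need at least 3 frames (2 are dropped)")
    frames = waveform.reshape(frames_presented, frame_length)[1:-1]
    n = frames.shape[0]
    mean = frames.mean(axis=0)
    sem = frames.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(frame_length)
    return mean, sem, n


@dataclass(frozen=True)
class SpectralEstimate:
    """Amplitude/phase/noise floor of one frequency component in one channel."""

    frequency: float            # Hz
    amplitude: float            # channel units, RMS
    phase: float                # cycles in (-0.5, 0.5], cosine reference
    noise_floor: float | None = None   # same units as amplitude
    channel: str = ""           # 'ecp' | 'rw' | 'remote'

    @property
    def snr_db(self) -> float:
        if self.noise_floor is None:
            return np.nan
        if self.noise_floor == 0.0:
            return np.inf if self.amplitude > 0 else np.nan
        if self.amplitude == 0.0:
            return -np.inf
        return 20.0 * np.log10(self.amplitude / self.noise_floor)

    @property
    def valid(self) -> bool:
        """True when the component clears the noise floor by 6 dB."""
        if self.noise_floor is None:
            return bool(self.amplitude > 0)
        return bool(self.snr_db >= SNR_VALID_DB)


def wrap_cycles(phi: np.ndarray | float) -> np.ndarray | float:
    """Wrap a phase in cycles to (-0.5, 0.5]."""
    wrapped = np.mod(np.asarray(phi) + 0.5, 1.0) - 0.5
    wrapped = np.where(wrapped == -0.5, 0.5, wrapped)
    if np.isscalar(phi):
        return float(wrapped)
    return wrapped


def extract_component(mean_frame: np.ndarray, frequency: float,
                      sample_rate: float, channel: str = "") -> SpectralEstimate:
    """Amplitude (RMS) and phase (cycles) from the single on-grid DFT bin."""
    mean_frame = np.asarray(mean_frame)
    n = mean_frame.size
    k = frequency_bin(frequency, sample_rate, n)   # raises if off-grid
    if k >= n // 2:
        raise AnalysisError(f"{frequency} Hz at/above Nyquist of this frame")
    # single-bin projection; equivalent to rfft(mean_frame)[k]
    coeff = np.dot(mean_frame,
                   np.exp(-2j * np.pi * k * np.arange(n) / n))
    amplitude = np.sqrt(2.0) * np.abs(coeff) / n
    phase = wrap_cycles(np.angle(coeff) / (2 * np.pi)) if amplitude > 0 else 0.0
    return SpectralEstimate(frequency, float(amplitude), float(phase),
                            channel=channel)


def intermod_bins(spec: StimulusSpec, max_order: int = 4) -> set[int]:
    """All bins of m*f1 + n*f2 combinations with |m| + |n| <= max_order.

    For a single tone this is the set of harmonic bins.  DC (bin 0) is
    always included.
    """
    ks = [c.cycles_per_frame(spec.sample_rate, spec.frame_length)
          for c in spec.components]
    n_bins = spec.frame_length // 2
    out = {0}
    if len(ks) == 1:
        for m in range(1, max_order + 1):
            if m * ks[0] < n_bins:
                out.add(m * ks[0])
        return out
    k1, k2 = sorted(ks)
    for m in range(-max_order, max_order + 1):
        for nn in range(-max_order, max_order + 1):
            if abs(m) + abs(nn) > max_order or (m == 0 and nn == 0):
                continue
            k = m * k1 + nn * k2
            if 0 < k < n_bins:
                out.add(k)
    return out


def noise_floor(mean_frame: np.ndarray, target_bin: int,
                exclusion_bins: set[int], n_neighbors: int = 6) -> float:
    """Median amplitude of the nearest admissible bins around a target.

    Takes ``n_neighbors // 2`` bins from each side, skipping excluded
    (stimulus/DP/DC) bins; raises when the frame does not contain enough
    admissible neighbors.
    """
    mean_frame = np.asarray(mean_frame)
    n = mean_frame.size
    spectrum = np.fft.rfft(mean_frame)
    amps = np.sqrt(2.0) * np.abs(spectrum) / n
    n_side = n_neighbors // 2
    picked = []
    for direction in (-1, +1):
        found = 0
        k = target_bin
        while found < n_side:
            k += direction
            if k < 1 or k >= n // 2:
                raise AnalysisError(
                    f"fewer than {n_side} admissible neighbor bins on one side "
                    f"of bin {target_bin}")
            if k in exclusion_bins or k == target_bin:
                continue
            picked.append(amps[k])
            found += 1
    return float(np.median(picked))


def estimate_component(mean_frame: np.ndarray, frequency: float,
                       sample_rate: float, spec: StimulusSpec,
                       channel: str = "") -> SpectralEstimate:
    """Component extraction with the neighboring-bin noise floor attached."""
    est = extract_component(mean_frame, frequency, sample_rate, channel)
    k = frequency_bin(frequency, sample_rate, mean_frame.size)
    excl = intermod_bins(spec)
    floor = noise_floor(mean_frame, k, excl)
    return replace(est, noise_floor=floor)


def sensitivity_and_phase(ecochg_est: SpectralEstimate,
                          ecp_est: SpectralEstimate
                          ) -> tuple[float, float, bool]:
    """Sensitivity (dB, eCochG re ECP) and relative phase (cycles).

    Returns ``(sensitivity_db, phase_rel, valid)``.  The pair is flagged
    invalid when the ECP component does not itself clear its noise floor
    or the eCochG component fails the 6-dB SNR rule.
    """
    if ecochg_est.frequency != ecp_est.frequency:
        raise AnalysisError("sensitivity requires estimates at the same frequency")
    valid = ecp_est.valid and ecochg_est.valid and ecp_est.amplitude > 0
    if ecochg_est.amplitude <= 0 or ecp_est.amplitude <= 0:
        return -np.inf, 0.0, False
    sens = 20.0 * np.log10(ecochg_est.amplitude / ecp_est.amplitude)
    phase_rel = wrap_cycles(ecochg_est.phase - ecp_est.phase)
    return float(sens), float(phase_rel), bool(valid)


@dataclass
class ResponseCurve:
    """Sensitivity/phase versus frequency at one stimulus level, one channel."""

    frequencies: np.ndarray     # Hz, strictly increasing
    level_db_spl: float
    sensitivity_db: np.ndarray  # eCochG re ECP
    phase_rel: np.ndarray       # cycles, wrapped
    valid: np.ndarray           # bool per point
    channel: str = ""
    amplitude: np.ndarray | None = None   # raw channel units, RMS

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if np.any(np.diff(self.frequencies) <= 0):
            raise AnalysisError("frequencies must be strictly increasing")
        self.sensitivity_db = np.asarray(self.sensitivity_db, dtype=float)
        self.phase_rel = np.asarray(self.phase_rel, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)

    def unwrapped_phase(self) -> np.ndarray:
        """Unwrapped relative phase (cycles) over the valid points."""
        phi = self.phase_rel[self.valid]
        return np.unwrap(phi * 2 * np.pi) / (2 * np.pi)


@dataclass(frozen=True)
class GroupDelayEstimate:
    """Least-squares group delay over one frequency window."""

    frequency: float     # Hz, window center
    tau_ms: float        # -dphi/df in ms
    band: tuple[float, float]
    n_points: int


def group_delay(curve: ResponseCurve, window: int | None = 5
                ) -> list[GroupDelayEstimate]:
    """Group delay tau = -dphi/df from the unwrapped phase-vs-frequency curve.

    Phase is unwrapped over the SNR-valid points and a least-squares line
    is fitted in each sliding window of ``window`` consecutive valid
    points (``window=None`` fits the whole curve at once).  With phase in
    cycles and frequency in Hz the negative slope is seconds; reported in
    ms.
    """
    f = curve.frequencies[curve.valid]
    if f.size < 2:
        return []
    phi = curve.unwrapped_phase()
    if window is None or window >= f.size:
        window = f.size
    if window < 2:
        raise AnalysisError("group-delay window needs at least 2 points")
    out = []
    for i in range(f.size - window + 1):
        fw, pw = f[i:i + window], phi[i:i + window]
        slope = np.polyfit(fw, pw, 1)[0]
        out.append(GroupDelayEstimate(
            frequency=float(fw.mean()), tau_ms=float(-slope * 1e3),
            band=(float(fw[0]), float(fw[-1])), n_points=window))
    return out


def mean_group_delay(curve: ResponseCurve) -> float:
    """Single least-squares tau (ms) over all valid points of a curve."""
    ests = group_delay(curve, window=None)
    if not ests:
        raise AnalysisError("no SNR-valid points for group delay")
    return ests[0].tau_ms
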