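"""DP-grams, pre/post damage change profiles, and notch localization.

A DP-gram sweeps the two-tone stimulus (f2/f1 fixed near 1.25, equal
levels) over f2 and plots the 2f1-f2 distortion product amplitude in all
three channels against frequency.  Because outer-hair-cell distortion is
generated in a spatially restricted region tied to the stimulus place,
the pre/post change of the DP-gram localizes place-restricted sensory
damage: the frequency of the largest DP reduction marks the damaged
characteristic location.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectral import (AnalysisError, average_frames, estimate_component,
                       SpectralEstimate)
from .simulate import MultiChannelRecording
from .stimulus import frequency_bin

CHANNELS = ("ecp", "rw", "remote")


@dataclass
class DPGram:
    """DP amplitudes across an f2 sweep, all channels, one level pair."""

    f1: np.ndarray
    f2: np.ndarray
    f_dp: np.ndarray                       # 2 f1 - f2, on the bin grid
    levels: tuple[float, float]            # L1, L2 dB SPL
    ratio: float
    amplitude: dict[str, np.ndarray] = field(default_factory=dict)
    noise_floor: dict[str, np.ndarray] = field(default_factory=dict)
    valid: dict[str, np.ndarray] = field(default_factory=dict)
    # stimulus-tone components, for response-change profiles
    stim_amplitude: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)

    def __len__(self) -> int:
        return self.f2.size


def _channel_estimate(rec: MultiChannelRecording, channel: str,
                      frequency: float) -> SpectralEstimate | None:
    wave = rec.waveform(channel)
    rate = rec.sample_rate(channel)
    n_frame = rec.frame_length(channel)
    if frequency >= rate / 2:
        return None
    mean, _, _ = average_frames(wave, n_frame, rec.spec.frames_presented)
    return estimate_component(mean, frequency, rate, rec.spec, channel)


def dpgram(recordings: list[MultiChannelRecording],
           dp_order: tuple[int, int] = (2, -1)) -> DPGram:
    """Build a DP-gram from two-tone recordings sharing one protocol.

    Extracts the requested intermodulation product (default 2f1-f2) with
    its noise floor in every channel, plus the f1/f2 stimulus components.
    Points whose DP bin collides with a stimulus bin are rejected.
    """
    if not recordings:
        raise AnalysisError("no recordings")
    rows: dict[str, list] = {ch: [] for ch in CHANNELS}
    floors: dict[str, list] = {ch: [] for ch in CHANNELS}
    valids: dict[str, list] = {ch: [] for ch in CHANNELS}
    stim: dict[str, dict[str, list]] = {ch: {"f1": [], "f2": []} for ch in CHANNELS}
    f1s, f2s, fdps = [], [], []
    m, n = dp_order
    for rec in recordings:
        spec = rec.spec
        if len(spec.components) != 2:
            raise AnalysisError("DP-grams require two-tone recordings")
        f1, f2 = sorted(c.frequency_snapped for c in spec.components)
        f_dp = m * f1 + n * f2
        k_dp = frequency_bin(f_dp, spec.sample_rate, spec.frame_length)
        k_stim = {frequency_bin(f, spec.sample_rate, spec.frame_length)
                  for f in (f1, f2)}
        if k_dp in k_stim or k_dp < 1:
            continue  # DP bin collides with a stimulus bin: point rejected
        f1s.append(f1)
        f2s.append(f2)
        fdps.append(f_dp)
        for ch in CHANNELS:
            est = _channel_estimate(rec, ch, f_dp)
            if est is None:      # beyond this channel's Nyquist
                rows[ch].append(np.nan)
                floors[ch].append(np.nan)
                valids[ch].append(False)
            else:
                rows[ch].append(est.amplitude)
                floors[ch].append(est.noise_floor)
                valids[ch].append(est.valid)
            for name, f in (("f1", f1), ("f2", f2)):
                se = _channel_estimate(rec, ch, f)
                stim[ch][name].append(np.nan if se is None else se.amplitude)
    levels = tuple(sorted((c.level_db_spl for c in recordings[0].spec.components),
                          reverse=False))
    ratio = recordings[0].spec.ratio
    order = np.argsort(f2s)
    gram = DPGram(
        f1=np.asarray(f1s)[order], f2=np.asarray(f2s)[order],
        f_dp=np.asarray(fdps)[order],
        levels=(levels[0], levels[-1]), ratio=ratio)
    for ch in CHANNELS:
        gram.amplitude[ch] = np.asarray(rows[ch])[order]
        gram.noise_floor[ch] = np.asarray(floors[ch])[order]
        gram.valid[ch] = np.asarray(valids[ch])[order]
        gram.stim_amplitude[ch] = {k: np.asarray(v)[order]
                                   for k, v in stim[ch].items()}
    return gram


@dataclass
class DPChangeProfile:
    """Pointwise post-minus-pre DP amplitude change (dB) per channel."""

    f2: np.ndarray
    f_dp: np.ndarray
    change_db: dict[str, np.ndarray]       # NaN where either side invalid
    valid: dict[str, np.ndarray]
    smoothing: str = "none"


def dp_change(pre: DPGram, post: DPGram) -> DPChangeProfile:
    """Pointwise dB change of DP amplitude, defined where both are valid."""
    if pre.f2.size != post.f2.size or not np.allclose(pre.f2, post.f2):
        raise AnalysisError("pre/post DP-grams must share the sweep grid")
    change, valid = {}, {}
    for ch in CHANNELS:
        both = pre.valid[ch] & post.valid[ch]
        with np.errstate(divide="ignore", invalid="ignore"):
            delta = 20.0 * np.log10(post.amplitude[ch] / pre.amplitude[ch])
        delta = np.where(both, delta, np.nan)
        change[ch] = delta
        valid[ch] = both
    return DPChangeProfile(pre.f2.copy(), pre.f_dp.copy(), change, valid)


@dataclass(frozen=True)
class NotchLocalization:
    center_dp_hz: float       # on the 2f1-f2 axis
    center_f2_hz: float
    depth_db: float           # profile value at the center (<= -6)
    width_oct: float          # span where change <= depth/2
    channel: str


def _median_smooth(x: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return x.copy()
    half = width // 2
    out = np.empty_like(x)
    for i in range(x.size):
        lo, hi = max(0, i - half), min(x.size, i + half + 1)
        seg = x[lo:hi]
        seg = seg[np.isfinite(seg)]
        out[i] = np.median(seg) if seg.size else np.nan
    return out


def localize_notch(profile: DPChangeProfile, channel: str,
                   smooth: int = 3, detection_db: float = -6.0
                   ) -> NotchLocalization:
    """Locate place-restricted damage from a DP change profile.

    The center is the minimum of the (median-smoothed) change profile,
    reported on both the 2f1-f2 and f2 axes; ties break toward the lower
    frequency.  Raises when no point falls below the -6 dB detection
    criterion.
    """
    change = profile.change_db[channel]
    ok = np.isfinite(change)
    if ok.sum() < 5:
        raise AnalysisError("need >= 5 valid profile points")
    smoothed = _median_smooth(change, smooth)
    smoothed[~np.isfinite(smoothed)] = np.inf
    if np.min(smoothed) > detection_db:
        raise AnalysisError("no notch detected (no change below "
                            f"{detection_db} dB in channel {channel!r})")
    idx = int(np.argmin(smoothed))     # first minimum = lower frequency
    depth = float(smoothed[idx])
    # contiguous half-depth span around the center, in octaves on the DP axis
    at_half = smoothed <= depth / 2.0
    lo = idx
    while lo > 0 and at_half[lo - 1]:
        lo -= 1
    hi = idx
    while hi < at_half.size - 1 and at_half[hi + 1]:
        hi += 1
    width = float(np.log2(profile.f_dp[hi] / profile.f_dp[lo]))
    return NotchLocalization(float(profile.f_dp[idx]), float(profile.f2[idx]),
                             depth, width, channel)


def stimulus_response_change(pre: DPGram, post: DPGram,
                             tone: str = "f2") -> dict[str, np.ndarray]:
    """Per-channel dB change of the f1/f2 stimulus-tone components vs f2."""
    if not np.allclose(pre.f2, post.f2):
        raise AnalysisError("pre/post sweeps must match")
    out = {}
    for ch in CHANNELS:
        with np.errstate(divide="ignore", invalid="ignore"):
            out[ch] = 20.0 * np.log10(post.stim_amplitude[ch][tone] /
                                      pre.stim_amplitude[ch][tone])
    return out
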