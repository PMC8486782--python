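"""Phenomenological gerbil cochlea model: parameters, damage maps, presets.

The model is deliberately not micromechanical.  It is a tonotopic
filterbank (Greenwood-form place-frequency map over 0.2-50 kHz) in which
each place responds to a tone through a zero-phase gain profile plus a
pure place-specific wave delay, followed by a saturating second-order
Boltzmann transduction stage (the only source of intermodulation
distortion) and a compressive, delayed, low-pass neural stage.  Its free
constants are calibrated against the printed observables of round-window
electrocochleography: ~0.05-ms sensory and 2.3-2.5-ms neural group
delays, 1 dB/dB sensory growth with compression appearing near 90 dB SPL,
a ~20-dB round-window/vertex channel offset, and distortion products that
localize place-restricted outer-hair-cell damage.

Phase topology.  The wave delay increases monotonically from base to
apex.  For a tone, places well basal of the characteristic location (CL)
share small, nearly equal delays and add coherently at the electrode,
while delays grow quickly toward CL so near-CL contributions rotate in
phase and largely cancel: the summed sensory potential is dominated by
the cochlear base, as required for the short measured group delay.  The
apical branch of the delay profile is ``tau_a + tau_b / CF``; the 1/CF
term contributes a constant phase offset but no group delay, so the
measured neural delay is ``synaptic_delay + tau_a`` (~2.45 ms) while the
physical delay at the 1-kHz place remains ~2.2 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np


@dataclass
class CochlearModel:
    """Parameterization of the simulator.  All delays in seconds, gains linear."""

    n_places: int = 128
    sample_rate: float = 200_000.0

    # Greenwood-form map CF(x) = A * (10**(a*(1-x)) - k), x in [0, 1] base->apex
    cf_min_hz: float = 200.0
    cf_max_hz: float = 50_000.0
    greenwood_k: float = 0.85

    # wave delay tau(CF) [s]; apical branch tau_a + tau_b/CF blending to
    # tau_min at the base over a knee at tau_knee_hz
    tau_min_s: float = 3.7e-5
    tau_a_s: float = 1.45e-3
    tau_b_s_hz: float = 0.75          # s*kHz == 750 s*Hz ... stored as ms*kHz? no: s*Hz
    tau_knee_hz: float = 8000.0
    tau_knee_order: float = 6.0

    # place gain profile (zero-phase): flat basal tail with a modest peak
    # at CL, steep apical cutoff, and a global high-pass tilt (the sensory
    # potential is high-pass in frequency)
    sigma_basal_oct: float = 0.25
    sigma_apical_oct: float = 0.45
    peak_gain: float = 2.0
    tilt_corner_hz: float = 2000.0
    tilt_slope: float = 1.0

    # mechano-electrical transduction: second-order Boltzmann, scale in Pa
    met_saturation_pa: float = 0.25
    boltzmann_a1: float = 0.0
    boltzmann_s1: float = 1.0
    boltzmann_a2: float = -3.0
    boltzmann_s2: float = 0.7

    # re-entrant distortion-product wave: the emitted DP travels forward
    # again and, being weak, enjoys the low-level cochlear-amplifier gain
    # at its own characteristic place (loud stimulus waves are compressed
    # out of this gain), which is what makes eCochG-DPs place-specific
    dp_relay_gain: float = 6.0
    dp_relay_amp: float = 20.0        # low-level amplifier gain at the DP CL
    dp_relay_sigma_oct: float = 0.25  # spatial extent of that gain

    # neural (phase-locked auditory-nerve) stage
    neural_exponent: float = 0.4
    neural_gain: float = 2.0
    neural_sat: float = 0.12          # cap on the compressed drive (rate saturation)
    phase_lock_corner_hz: float = 1000.0
    phase_lock_limit_hz: float = 5000.0
    phase_lock_order: float = 4.0
    synaptic_delay_s: float = 1.0e-3
    neural_offset_octaves: float = 1.0
    neural_window_oct: float = 0.3

    # electrodes and recording chains
    rw_gain: float = 1.0
    remote_gain: float = 0.1272
    rw_proximity: float = 1.0         # basal emphasis of the RW electrode
    rw_proximity_scale: float = 0.25  # e-folding in place coordinate
    rw_highpass_hz: float = 100.0
    rw_lowpass_hz: float = 30_000.0
    remote_corner_hz: float = 7500.0
    remote_rate: float = 25_000.0

    # ear-canal emission of intracochlear distortion
    emission_const: float = 0.4

    # per-channel additive white noise (standard deviation per sample)
    ecp_noise_pa: float = 1.0e-4
    rw_noise_v: float = 2.0e-3
    remote_noise_v: float = 5.0e-5

    # ------------------------------------------------------------------
    def place_positions(self) -> np.ndarray:
        """Normalized place coordinate x in [0, 1], base (x=0) to apex."""
        return np.linspace(0.0, 1.0, self.n_places)

    def place_cf(self) -> np.ndarray:
        """Characteristic frequencies (Hz), strictly decreasing base->apex."""
        x = self.place_positions()
        k = self.greenwood_k
        scale = self.cf_min_hz / (1.0 - k)
        a = np.log10(self.cf_max_hz / scale + k)
        return scale * (10.0 ** (a * (1.0 - x)) - k)

    def wave_delay_s(self, cf_hz: np.ndarray) -> np.ndarray:
        """Traveling-wave delay at each place (s); monotone toward the apex."""
        cf = np.asarray(cf_hz, dtype=float)
        apical = self.tau_a_s + self.tau_b_s_hz / cf
        knee = 1.0 / (1.0 + (cf / self.tau_knee_hz) ** self.tau_knee_order)
        return self.tau_min_s + (apical - self.tau_min_s) * knee

    def filter_gain(self, f_hz: np.ndarray, cf_hz: np.ndarray) -> np.ndarray:
        """Zero-phase drive gain of places (rows) at frequencies (cols)."""
        f = np.atleast_1d(np.asarray(f_hz, dtype=float))
        cf = np.atleast_1d(np.asarray(cf_hz, dtype=float))[:, None]
        with np.errstate(divide="ignore"):
            oct_re_cf = np.log2(np.where(f > 0, f, np.nan) / cf)
        basal = 1.0 + (self.peak_gain - 1.0) * np.exp(
            -0.5 * (oct_re_cf / self.sigma_basal_oct) ** 2)
        apical = self.peak_gain * np.exp(
            -0.5 * (oct_re_cf / self.sigma_apical_oct) ** 2)
        shape = np.where(oct_re_cf <= 0, basal, apical)
        tilt = np.minimum(1.0, (f / self.tilt_corner_hz) ** self.tilt_slope)
        g = np.where(f > 0, shape * tilt, 0.0)
        return np.nan_to_num(g)

    # --- transduction ---------------------------------------------------
    def boltzmann(self, x: np.ndarray) -> np.ndarray:
        """Second-order Boltzmann MET current, unit small-signal gain.

        Odd-symmetric to first order with a mild configurable asymmetry so
        even-order distortion exists while 2f1-f2 dominates among the
        low-order products.  ``met_saturation_pa = inf`` is the exactly
        linear (identity) limit.
        """
        m = self.met_saturation_pa
        if np.isinf(m):
            return np.asarray(x, dtype=float)
        u = np.asarray(x, dtype=float) / m

        def popen(u):
            return 1.0 / (1.0 + np.exp(-(u - self.boltzmann_a1) / self.boltzmann_s1)
                          * (1.0 + np.exp(-(u - self.boltzmann_a2) / self.boltzmann_s2)))

        p0 = popen(np.float64(0.0))
        eps = 1e-6
        gain0 = (popen(np.float64(eps)) - popen(np.float64(-eps))) / (2 * eps)
        return m * (popen(u) - p0) / gain0

    # --- recording chains ------------------------------------------------
    def rw_chain_response(self, f_hz: np.ndarray) -> np.ndarray:
        """Differential-amplifier bandpass of the round-window channel."""
        f = np.asarray(f_hz, dtype=float)
        jf = 1j * f
        hp = (jf / self.rw_highpass_hz) / (1.0 + jf / self.rw_highpass_hz)
        lp = 1.0 / (1.0 + jf / self.rw_lowpass_hz)
        return hp * lp

    def remote_chain_response(self, f_hz: np.ndarray) -> np.ndarray:
        """First-order 7.5-kHz low-pass (6 dB/oct) of the remote channel."""
        f = np.asarray(f_hz, dtype=float)
        return 1.0 / (1.0 + 1j * f / self.remote_corner_hz)

    def electrode_weights(self) -> dict[str, np.ndarray]:
        """Per-place pickup weights for each electrode, mean-normalized.

        The RW electrode sits at the base of the cochlea and mildly favors
        nearby (basal) hair cells; the vertex electrode is far-field and
        weighs all places equally, 20 dB down.
        """
        x = self.place_positions()
        w_rw = 1.0 + self.rw_proximity * np.exp(-x / self.rw_proximity_scale)
        w_rw = self.rw_gain * w_rw / w_rw.mean()
        w_remote = self.remote_gain * np.ones(self.n_places)
        return {"rw": w_rw, "remote": w_remote}

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CochlearModel":
        return cls(**d)


@dataclass
class DamageMap:
    """Per-place sensory (OHC) gain and a global neural scale, all in [0, 1]."""

    ohc_gain: np.ndarray
    neural_scale: float = 1.0

    def __post_init__(self) -> None:
        self.ohc_gain = np.asarray(self.ohc_gain, dtype=float)
        if np.any(self.ohc_gain < 0) or np.any(self.ohc_gain > 1):
            raise ValueError("ohc_gain factors must lie in [0, 1]")
        if not 0.0 <= self.neural_scale <= 1.0:
            raise ValueError("neural_scale must lie in [0, 1]")

    @classmethod
    def healthy(cls, model: CochlearModel) -> "DamageMap":
        return cls(np.ones(model.n_places), 1.0)

    def to_dict(self) -> dict:
        return {"ohc_gain": self.ohc_gain.tolist(),
                "neural_scale": self.neural_scale}

    @classmethod
    def from_dict(cls, d: dict) -> "DamageMap":
        return cls(np.asarray(d["ohc_gain"]), d["neural_scale"])


PRESET_NAMES = ("healthy", "ka", "broadband_trauma", "notch_4khz")


def notch_damage(model: CochlearModel, center_hz: float = 4000.0,
                 depth_db: float = 25.0, sigma_oct: float = 0.25) -> DamageMap:
    """Log-Gaussian OHC gain dip centered at the CL of ``center_hz``.

    ``sigma_oct = 0.25`` gives a full width at half (dB) depth of ~0.5
    octave, emulating damage from sustained exposure to an intense tone.
    """
    cf = model.place_cf()
    dip_db = -depth_db * np.exp(-0.5 * (np.log2(cf / center_hz) / sigma_oct) ** 2)
    return DamageMap(10.0 ** (dip_db / 20.0), 1.0)


def preset(name: str, model: CochlearModel | None = None
           ) -> tuple[CochlearModel, DamageMap]:
    """Named (model, damage) pairs for the study's experimental conditions.

    healthy            identity damage map
    ka                 kainic-acid neurotoxin: auditory-nerve activity
                       abolished (neural_scale = 0), sensory intact
    broadband_trauma   intense broadband overexposure: uniform 20-dB OHC
                       gain reduction
    notch_4khz         intense 4-kHz tone exposure: 25-dB-deep, ~0.5-octave
                       log-Gaussian OHC dip at the 4-kHz place
    """
    model = model if model is not None else CochlearModel()
    if name == "healthy":
        return model, DamageMap.healthy(model)
    if name == "ka":
        return model, DamageMap(np.ones(model.n_places), 0.0)
    if name == "broadband_trauma":
        return model, DamageMap(np.full(model.n_places, 10.0 ** (-20.0 / 20.0)), 1.0)
    if name == "notch_4khz":
        return model, notch_damage(model)
    raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")


def linearized(model: CochlearModel | None = None) -> CochlearModel:
    """Copy of a model with linear transduction, no neural stage, no noise."""
    model = model if model is not None else CochlearModel()
    return replace(model, met_saturation_pa=np.inf, neural_gain=0.0,
                   ecp_noise_pa=0.0, rw_noise_v=0.0, remote_noise_v=0.0)
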