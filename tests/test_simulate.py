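"""Forward model: drives, transduction, neural stage, channels, determinism."""

import numpy as np
import pytest
from dataclasses import replace

from ecochg import (DamageMap, linearized, preset, simulate, single_tone,
                    two_tone, traveling_wave, analyze_tone)
from ecochg.simulate import (cm_waveform, dpoae_waveform, met_currents,
                             neurophonic_waveform, _decimate_frame)
from ecochg.stimulus import build_stimulus, frequency_bin

FS = 200_000.0
N = 4096


def steady_frame(spec):
    return build_stimulus(spec).steady_frame


class TestTravelingWave:
    def test_tone_drive_maximal_near_cl(self, quiet_model, healthy):
        spec = single_tone(4000.0, 60.0)
        drives = traveling_wave(steady_frame(spec), quiet_model, healthy)
        rms = np.sqrt(np.mean(drives ** 2, axis=1))
        cf = quiet_model.place_cf()
        best = cf[np.argmax(rms)]
        assert abs(np.log2(best / 4000.0)) < 0.2

    def test_zero_ohc_gain_silences_drives(self, quiet_model):
        spec = single_tone(2000.0, 60.0)
        dmg = DamageMap(np.zeros(128))
        drives = traveling_wave(steady_frame(spec), quiet_model, dmg)
        assert np.max(np.abs(drives)) == 0.0

    def test_phase_difference_equals_delay_difference(self, quiet_model, healthy):
        # closed form: two places' drive phases differ by 2*pi*f*(tau_b - tau_a)
        spec = single_tone(1000.0, 60.0)
        f = spec.components[0].frequency_snapped
        k = frequency_bin(f, FS, N)
        drives = traveling_wave(steady_frame(spec), quiet_model, healthy)
        spectra = np.fft.rfft(drives, axis=1)[:, k]
        cf = quiet_model.place_cf()
        delays = quiet_model.wave_delay_s(cf)
        p, q = 40, 60
        measured = np.angle(spectra[p] / spectra[q])
        expected = -2 * np.pi * f * (delays[p] - delays[q])
        expected = np.angle(np.exp(1j * expected))
        assert measured == pytest.approx(expected, abs=1e-9)


class TestLinearizedModel:
    def test_superposition(self, healthy):
        m = linearized()
        s1 = single_tone(1000.0, 60.0)
        s2 = single_tone(4003.90625, 60.0)
        pair = two_tone(4003.90625, 60.0, 60.0, ratio=4003.90625 / 976.5625)
        d1 = traveling_wave(steady_frame(s1), m, healthy)
        d2 = traveling_wave(steady_frame(s2), m, healthy)
        dp = traveling_wave(steady_frame(pair), m, healthy)
        cm1 = cm_waveform(d1, m)["rw"]
        cm2 = cm_waveform(d2, m)["rw"]
        cmp_ = cm_waveform(dp, m)["rw"]
        scale = np.max(np.abs(cmp_))
        assert np.max(np.abs(cmp_ - cm1 - cm2)) < 1e-9 * scale

    def test_exact_1db_per_db_growth(self, healthy):
        m = linearized()
        amps = []
        for level in (40.0, 60.0, 80.0):
            rec = simulate(single_tone(2000.0, level), m, healthy)
            amps.append(analyze_tone(rec)["rw"]["estimate"].amplitude)
        growth = 20 * np.diff(np.log10(amps))
        assert np.allclose(growth, 20.0, atol=1e-9)

    def test_no_distortion_products(self, healthy):
        m = linearized()
        spec = two_tone(4000.0, 60.0, 60.0)
        drives = traveling_wave(steady_frame(spec), m, healthy)
        cm = cm_waveform(drives, m)["rw"]
        f1, f2 = sorted(c.frequency_snapped for c in spec.components)
        k_dp = frequency_bin(2 * f1 - f2, FS, N)
        spectrum = np.abs(np.fft.rfft(cm))
        k2 = frequency_bin(f2, FS, N)
        assert spectrum[k_dp] < 1e-10 * spectrum[k2]

    def test_uniform_damage_monotone(self, healthy):
        # global OHC scaling can never increase the linear CM amplitude
        m = linearized()
        spec = single_tone(2000.0, 60.0)
        frame = steady_frame(spec)
        amps = []
        for g in (1.0, 0.5, 0.25):
            dmg = DamageMap(np.full(128, g))
            cm = cm_waveform(traveling_wave(frame, m, dmg), m)["rw"]
            amps.append(np.max(np.abs(cm)))
        assert amps[0] > amps[1] > amps[2]


class TestBoltzmannDP:
    def test_place_dp_matches_brute_force_oracle(self, quiet_model):
        # one place's 2f1-f2 output against a direct time-domain
        # evaluation of the same Boltzmann followed by least-squares
        # projection at the DP frequency
        spec = two_tone(5004.8828125, 70.0, 70.0)
        f1, f2 = sorted(c.frequency_snapped for c in spec.components)
        t = np.arange(N) / FS
        drive = (0.05 * np.sin(2 * np.pi * f1 * t)
                 + 0.04 * np.sin(2 * np.pi * f2 * t))
        y = met_currents(drive[None, :], quiet_model)[0]
        f_dp = 2 * f1 - f2
        k = frequency_bin(f_dp, FS, N)
        via_fft = 2 * np.abs(np.fft.rfft(y)[k]) / N
        design = np.column_stack([np.cos(2 * np.pi * f_dp * t),
                                  np.sin(2 * np.pi * f_dp * t)])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        assert via_fft == pytest.approx(np.hypot(*coef), rel=1e-9)


class TestNeurophonic:
    def test_neural_scale_zero_is_silent(self, quiet_model, healthy):
        spec = single_tone(1000.0, 40.0)
        drives = traveling_wave(steady_frame(spec), quiet_model, healthy)
        dmg = DamageMap(np.ones(128), neural_scale=0.0)
        out = neurophonic_waveform(drives, quiet_model, dmg, spec)
        assert np.all(out["rw"] == 0.0) and np.all(out["remote"] == 0.0)

    def test_absent_beyond_phase_locking_limit(self, quiet_model, healthy):
        spec = single_tone(8000.0, 60.0)
        f = spec.components[0].frequency_snapped
        drives = traveling_wave(steady_frame(spec), quiet_model, healthy)
        out = neurophonic_waveform(drives, quiet_model, healthy, spec)["rw"]
        k = frequency_bin(f, FS, N)
        assert np.abs(np.fft.rfft(out)[k]) < 1e-12

    def test_compressive_power_law_below_saturation(self, quiet_model, healthy):
        # +10 dB of drive grows the neural output by ~exponent * 10 dB
        m = replace(quiet_model, neural_sat=np.inf)
        amps = []
        for level in (40.0, 50.0):
            spec = single_tone(976.5625, level)
            drives = traveling_wave(steady_frame(spec), m, healthy)
            out = neurophonic_waveform(drives, m, healthy, spec)["rw"]
            k = frequency_bin(976.5625, FS, N)
            amps.append(np.abs(np.fft.rfft(out)[k]))
        growth_db = 20 * np.log10(amps[1] / amps[0])
        assert growth_db == pytest.approx(10 * m.neural_exponent, abs=0.6)

    def test_healthy_low_frequency_low_level_compression(self, quiet_model,
                                                         healthy):
        # pipeline-level: 1-kHz growth 40->50 dB SPL is compressive
        a = [analyze_tone(simulate(single_tone(1000.0, lv), quiet_model,
                                   healthy))["rw"]["estimate"].amplitude
             for lv in (40.0, 50.0)]
        slope = 2 * np.log10(a[1] / a[0])
        assert slope < 0.8

    def test_high_level_compression_of_cm(self, quiet_model, healthy):
        # MET saturation: some compression at 90 dB SPL, 4 kHz
        a = [analyze_tone(simulate(single_tone(4000.0, lv), quiet_model,
                                   healthy))["rw"]["estimate"].amplitude
             for lv in (80.0, 90.0)]
        slope = 2 * np.log10(a[1] / a[0])
        assert slope < 0.9


class TestDPOAE:
    def test_single_tone_contributes_zero(self, quiet_model, healthy):
        spec = single_tone(2000.0, 60.0)
        drives = traveling_wave(steady_frame(spec), quiet_model, healthy)
        assert np.all(dpoae_waveform(drives, quiet_model, healthy, spec) == 0.0)

    def test_linearized_model_emits_nothing(self, healthy):
        m = linearized()
        spec = two_tone(4000.0, 60.0, 60.0)
        drives = traveling_wave(steady_frame(spec), m, healthy)
        out = dpoae_waveform(drives, m, healthy, spec)
        assert np.max(np.abs(out)) < 1e-12

    def test_emission_constant_scales_dpoae_only(self, quiet_model, healthy):
        spec = two_tone(4000.0, 60.0, 60.0)
        drives = traveling_wave(steady_frame(spec), quiet_model, healthy)
        out1 = dpoae_waveform(drives, quiet_model, healthy, spec)
        doubled = replace(quiet_model, emission_const=2 * quiet_model.emission_const)
        out2 = dpoae_waveform(drives, doubled, healthy, spec)
        assert np.allclose(out2, 2 * out1)
        # eCochG side unaffected by the emission constant
        cm1 = cm_waveform(drives, quiet_model)["rw"]
        cm2 = cm_waveform(drives, doubled)["rw"]
        assert np.array_equal(cm1, cm2)


class TestRecordingAssembly:
    def test_fixed_seed_is_bit_identical(self, model, healthy):
        r1 = simulate(single_tone(2000.0, 60.0), model, healthy, seed=7)
        r2 = simulate(single_tone(2000.0, 60.0), model, healthy, seed=7)
        for ch in ("ecp", "rw", "remote"):
            assert np.array_equal(r1.waveform(ch), r2.waveform(ch))

    def test_remote_channel_20db_down_at_2khz(self, quiet_model, healthy):
        rec = simulate(single_tone(2000.0, 70.0), quiet_model, healthy)
        res = analyze_tone(rec)
        diff = 20 * np.log10(res["rw"]["estimate"].amplitude /
                             res["remote"]["estimate"].amplitude)
        assert diff == pytest.approx(20.0, abs=1.0)

    def test_channel_sample_counts_are_frame_synchronous(self, quiet_model,
                                                         healthy):
        rec = simulate(single_tone(1000.0, 80.0), quiet_model, healthy)
        assert rec.ecp.size == 52 * 4096
        assert rec.rw.size == 52 * 4096
        assert rec.remote.size == 52 * 512

    def test_decimation_is_exact_for_on_grid_tone(self):
        t = np.arange(N) / FS
        f = 40 * FS / N
        frame = np.cos(2 * np.pi * f * t)
        small = _decimate_frame(frame, 8)
        t_small = np.arange(512) / 25_000.0
        assert np.allclose(small, np.cos(2 * np.pi * f * t_small), atol=1e-9)

    def test_ecp_is_calibrated_pressure(self, quiet_model, healthy):
        rec = simulate(single_tone(1000.0, 94.0), quiet_model, healthy)
        est = analyze_tone(rec)["ecp"]["estimate"]
        assert est.amplitude == pytest.approx(1.0, rel=1e-2)  # 94 dB ~ 1 Pa RMS
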