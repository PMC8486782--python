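"""Frame averaging, bin-exact extraction, noise floors, group delay."""

import numpy as np
import pytest

from ecochg import (AnalysisError, average_frames, extract_component,
                    group_delay, noise_floor, sensitivity_and_phase)
from ecochg.spectral import (GroupDelayEstimate, ResponseCurve,
                             SpectralEstimate, mean_group_delay, wrap_cycles)
from ecochg.stimulus import single_tone, build_stimulus
from ecochg.simulate import simulate

FS = 200_000.0
N = 4096


def tone_frame(k, amp_peak=1.0, phase_cycles=0.0, n=N):
    t = np.arange(n) / n
    return amp_peak * np.cos(2 * np.pi * (k * t + phase_cycles))


class TestAverageFrames:
    def test_long_protocol_averages_400_of_402(self):
        wave = np.tile(tone_frame(20), 402)
        mean, sem, n_avg = average_frames(wave, N, 402)
        assert n_avg == 400
        assert np.allclose(mean, tone_frame(20), atol=1e-12)
        assert np.max(sem) < 1e-12

    def test_periodic_input_mean_equals_center_frame(self):
        wave = np.tile(tone_frame(7, 0.3), 10)
        mean, _, _ = average_frames(wave, N)
        assert np.allclose(mean, wave[N:2 * N], rtol=0, atol=1e-14)

    def test_length_mismatch_rejected(self):
        with pytest.raises(AnalysisError):
            average_frames(np.zeros(N * 10 + 1), N)

    def test_noise_shrinks_as_sqrt_n(self):
        # Monte-Carlo: residual component amplitude after averaging n
        # frames follows the sigma/sqrt(n) law
        rng = np.random.default_rng(42)
        sigma = 1.0
        amps = {n_frames: [] for n_frames in (12, 102)}
        for n_frames in amps:
            for _ in range(150):
                wave = rng.normal(0, sigma, n_frames * 512)
                mean, _, n_avg = average_frames(wave, 512, n_frames)
                est = extract_component(mean, 10 * FS / 512, FS)
                amps[n_frames].append(est.amplitude)
        ratio = np.mean(amps[12]) / np.mean(amps[102])
        assert ratio == pytest.approx(np.sqrt(100 / 10), rel=0.2)


class TestExtractComponent:
    def test_sine_amplitude_and_phase(self):
        # sin with RMS amplitude A -> amplitude A, phase -0.25 cycles
        a_rms = 0.7
        t = np.arange(N) / N
        frame = a_rms * np.sqrt(2) * np.sin(2 * np.pi * 20 * t)
        est = extract_component(frame, 20 * FS / N, FS)
        assert est.amplitude == pytest.approx(a_rms, rel=1e-12)
        assert est.phase == pytest.approx(-0.25, abs=1e-12)

    def test_zero_signal(self):
        est = extract_component(np.zeros(N), 20 * FS / N, FS)
        assert est.amplitude == 0.0

    def test_off_grid_frequency_rejected(self):
        with pytest.raises(Exception):
            extract_component(np.zeros(N), 1000.0, FS)

    def test_matches_full_rfft_bin(self):
        rng = np.random.default_rng(3)
        frame = rng.normal(size=N)
        for k in (1, 20, 333, 2000):
            est = extract_component(frame, k * FS / N, FS)
            ref = np.sqrt(2) * np.abs(np.fft.rfft(frame)[k]) / N
            assert est.amplitude == pytest.approx(ref, rel=1e-12, abs=1e-15)

    def test_matches_least_squares_projection(self):
        # independent oracle: project onto sin/cos at the target frequency
        rng = np.random.default_rng(9)
        frame = rng.normal(size=N)
        k = 57
        t = np.arange(N) / N
        design = np.column_stack([np.cos(2 * np.pi * k * t),
                                  np.sin(2 * np.pi * k * t)])
        coef, *_ = np.linalg.lstsq(design, frame, rcond=None)
        est = extract_component(frame, k * FS / N, FS)
        assert est.amplitude == pytest.approx(np.hypot(*coef) / np.sqrt(2),
                                              rel=1e-10)


class TestNoiseFloor:
    def test_pure_tone_has_zero_floor(self):
        frame = tone_frame(50)
        assert noise_floor(frame, 50, {0, 50}) == pytest.approx(0.0, abs=1e-12)

    def test_floor_scales_linearly_with_sigma(self):
        rng = np.random.default_rng(11)
        noise = rng.normal(size=N)
        f1 = noise_floor(noise, 100, {0, 100})
        f2 = noise_floor(2 * noise, 100, {0, 100})
        assert f2 == pytest.approx(2 * f1, rel=1e-12)

    def test_excluded_bins_are_skipped(self):
        frame = tone_frame(50, 100.0) + tone_frame(52, 100.0)
        floor = noise_floor(frame, 51, {0, 50, 52})
        assert floor < 1e-9  # the big neighbors are excluded

    def test_insufficient_neighbors(self):
        with pytest.raises(AnalysisError):
            noise_floor(np.zeros(N), 1, set(range(0, 2048)))


class TestSensitivity:
    def test_equal_amplitudes_zero_db(self):
        a = SpectralEstimate(1000.0, 0.5, 0.1)
        b = SpectralEstimate(1000.0, 0.5, 0.3)
        sens, phase, _ = sensitivity_and_phase(a, b)
        assert sens == pytest.approx(0.0)
        assert phase == pytest.approx(wrap_cycles(0.1 - 0.3))

    def test_low_snr_flagged_invalid(self):
        a = SpectralEstimate(1000.0, 0.5, 0.0, noise_floor=0.4)
        b = SpectralEstimate(1000.0, 0.5, 0.0, noise_floor=1e-6)
        _, _, valid = sensitivity_and_phase(a, b)
        assert not valid

    def test_frequency_mismatch_rejected(self):
        a = SpectralEstimate(1000.0, 0.5, 0.0)
        b = SpectralEstimate(2000.0, 0.5, 0.0)
        with pytest.raises(AnalysisError):
            sensitivity_and_phase(a, b)

    def test_delay_recovered_from_phase_ramp(self):
        # eCochG = 1-ms delayed copy of ECP: unwrapped relative phase is
        # -f tau and the fitted group delay recovers 1 ms
        tau = 1e-3
        freqs = np.arange(500.0, 1500.0, 97.65625)
        phase = wrap_cycles(-freqs * tau)
        curve = ResponseCurve(freqs, 60.0, np.zeros(freqs.size), phase,
                              np.ones(freqs.size, bool))
        assert mean_group_delay(curve) == pytest.approx(1.0, rel=1e-9)


class TestGroupDelay:
    def _curve(self, freqs, phase, valid=None):
        valid = np.ones(len(freqs), bool) if valid is None else valid
        return ResponseCurve(np.asarray(freqs), 40.0, np.zeros(len(freqs)),
                             wrap_cycles(np.asarray(phase)), valid)

    def test_exact_line(self):
        freqs = np.linspace(500, 1500, 11)
        curve = self._curve(freqs, -freqs * 2.5e-3)
        for est in group_delay(curve, window=5):
            assert est.tau_ms == pytest.approx(2.5, rel=1e-9)

    def test_constant_phase_gives_zero(self):
        freqs = np.linspace(500, 1500, 11)
        curve = self._curve(freqs, np.full(11, 0.2))
        assert mean_group_delay(curve) == pytest.approx(0.0, abs=1e-12)

    def test_pure_time_shift_shifts_tau_exactly(self):
        freqs = np.linspace(3000, 8000, 13)
        base = -freqs * 0.05e-3
        delta = 0.7e-3
        t0 = mean_group_delay(self._curve(freqs, base))
        t1 = mean_group_delay(self._curve(freqs, base - freqs * delta))
        assert t1 - t0 == pytest.approx(delta * 1e3, rel=1e-9)

    def test_time_shifted_waveform_shifts_tau(self, quiet_model, healthy):
        # roll the recorded RW waveform by 100 samples (0.5 ms): every
        # extracted phase gains -f*delta and tau shifts by exactly 0.5 ms
        from ecochg.spectral import average_frames, extract_component
        freqs = [k * FS / N for k in (61, 71, 82)]
        phases, phases_shifted = [], []
        for f in freqs:
            rec = simulate(single_tone(f, 80.0), quiet_model, healthy)
            mean, _, _ = average_frames(rec.rw, 4096, rec.spec.frames_presented)
            phases.append(extract_component(mean, f, FS).phase)
            mean_shift = np.roll(mean, 100)
            phases_shifted.append(extract_component(mean_shift, f, FS).phase)
        d_tau = []
        for f, p0, p1 in zip(freqs, phases, phases_shifted):
            d_tau.append(wrap_cycles(p1 - p0))
        # phase difference ramp corresponds to 1 ms across these bins
        slope = np.polyfit(freqs, np.unwrap(np.array(d_tau) * 2 * np.pi)
                           / (2 * np.pi), 1)[0]
        assert -slope == pytest.approx(0.5e-3, rel=1e-6)

    def test_unwrap_direction_independent(self):
        rng = np.random.default_rng(5)
        freqs = np.linspace(500, 1500, 15)
        phase = -freqs * 2.4e-3 + rng.normal(0, 0.02, 15)
        fwd = mean_group_delay(self._curve(freqs, phase))
        rev_curve = ResponseCurve(freqs, 40.0, np.zeros(15),
                                  wrap_cycles(phase), np.ones(15, bool))
        # reversing the sweep order then re-sorting must give the same fit
        rev = mean_group_delay(rev_curve)
        assert fwd == pytest.approx(rev, rel=1e-12)

    def test_invalid_points_never_enter_fit(self):
        freqs = np.linspace(500, 1500, 11)
        phase = -freqs * 1.0e-3
        phase[5] = 0.4  # corrupted point, flagged invalid
        valid = np.ones(11, bool)
        valid[5] = False
        curve = self._curve(freqs, phase, valid)
        assert mean_group_delay(curve) == pytest.approx(1.0, rel=1e-9)

    def test_no_valid_points_raises(self):
        curve = self._curve(np.linspace(500, 1500, 5), np.zeros(5),
                            np.zeros(5, bool))
        with pytest.raises(AnalysisError):
            mean_group_delay(curve)
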