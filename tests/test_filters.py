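"""Volitional-EMG extraction: blanking, comb filter, envelope, torque."""

import numpy as np
import pytest

from hybridgait.filters import (
    BlankingOverlapError,
    FilterConfig,
    StimulatedEmgStream,
    blank_artifacts,
    comb_filter,
    lowpass_reconstruct,
    volitional_envelope,
    volitional_torque,
)
from hybridgait.synth import (
    EmgSynthesisParams,
    gen_stimulated_emg,
    gen_volitional_emg,
)

RATE = 1000.0
CFG = FilterConfig()


def make_stream(samples, pulse_times=()):
    samples = np.asarray(samples, dtype=float)
    t = np.arange(len(samples)) / RATE
    return StimulatedEmgStream(
        t=t, samples=samples, pulse_times=np.asarray(pulse_times, float), rate=RATE
    )


class TestBlanking:
    def test_no_pulses_stream_unchanged(self, rng):
        x = rng.standard_normal(500)
        blanked, segments = blank_artifacts(make_stream(x), CFG)
        assert np.array_equal(blanked, x)
        assert segments == []

    def test_artifact_spike_removed(self, rng):
        x0 = 0.1 * rng.standard_normal(200)
        x = x0.copy()
        x[100:103] += 10.0  # artifact inside the blanking window
        blanked, _ = blank_artifacts(make_stream(x, [0.100]), CFG)
        expected = x0.copy()
        expected[100:105] = x0[99]  # zero-order hold over the window
        assert np.array_equal(blanked, expected)

    def test_zero_hold_policy(self):
        x = np.arange(50, dtype=float)
        blanked, _ = blank_artifacts(make_stream(x, [0.010]), CFG)
        assert np.all(blanked[10:15] == x[9])

    def test_overlapping_windows_rejected(self):
        x = np.zeros(100)
        with pytest.raises(BlankingOverlapError):
            blank_artifacts(
                make_stream(x, [0.010, 0.012]), FilterConfig(blanking_ms=5.0)
            )

    def test_segments_aligned_to_pulses(self):
        x = np.zeros(100)
        _, segments = blank_artifacts(make_stream(x, [0.020, 0.060]), CFG)
        assert len(segments) == 2
        assert len(segments[0]) == 35  # 25..60
        assert len(segments[1]) == 35  # 65..100


class TestCombFilter:
    def test_identical_segments_cancel_exactly(self, rng):
        seg = rng.standard_normal(30)
        assert np.all(comb_filter(seg, seg) == 0.0)

    def test_half_difference_recovers_volitional_algebra(self, rng):
        m = rng.standard_normal(30)  # stationary M-wave
        v = rng.standard_normal(30)  # volitional component
        assert np.allclose(comb_filter(m + v, m - v), v)

    def test_length_mismatch_resampled(self):
        cur = np.ones(30)
        prev = np.ones(25)
        out = comb_filter(cur, prev)
        assert len(out) == 30
        assert np.allclose(out, 0.0)


class TestLowpassReconstruct:
    def test_dc_gain_unity(self):
        out = lowpass_reconstruct(np.full(4000, 0.7), CFG, RATE)
        assert np.allclose(out[1000:-1000], 0.7, atol=1e-6)

    def test_50hz_attenuated_by_40db(self):
        t = np.arange(8000) / RATE
        x = np.sin(2 * np.pi * 50.0 * t)
        out = lowpass_reconstruct(x, CFG, RATE)
        # rectified 50 Hz has a DC component ~2/pi that passes; the ripple
        # at 100 Hz must be attenuated far beyond 40 dB at order 4
        ripple = out[2000:-2000] - np.mean(out[2000:-2000])
        assert np.abs(ripple).max() < 1e-2  # > 40 dB below the unit carrier

    def test_step_smoothed(self):
        x = np.concatenate([np.zeros(2000), np.ones(2000)])
        out = lowpass_reconstruct(x, CFG, RATE)
        assert np.abs(np.diff(out)).max() < 0.05  # < 5% of the step per sample

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            lowpass_reconstruct(np.zeros(100), FilterConfig(lowpass_cutoff_hz=600), RATE)


class TestCascade:
    PARAMS = EmgSynthesisParams(seed=5)

    def _pulses(self, duration, rate_hz=40.0, start=0.05):
        return np.arange(start, duration - 0.01, 1.0 / rate_hz)

    def test_mwave_only_stream_cancels(self):
        """Pulse-periodic contamination with no volition must leave an
        envelope under 2% of the M-wave RMS."""
        n = 10_000
        silent = np.zeros(n)
        pulses = self._pulses(n / RATE)
        stream = gen_stimulated_emg(
            silent, pulses, np.full(len(pulses), 30.0), self.PARAMS
        )
        mwave_rms = float(np.sqrt(np.mean((stream.samples - silent) ** 2)))
        env = volitional_envelope(stream, CFG)
        assert np.sqrt(np.mean(env[1000:-1000] ** 2)) < 0.02 * mwave_rms

    def test_volitional_sinusoid_recovered(self):
        """40 Hz pulses over a fixed M-wave plus a 5 Hz-modulated volitional
        signal: the reconstructed envelope must track the true envelope
        within 15% RMS."""
        n = 12_000
        t = np.arange(n) / RATE
        true_env = 0.4 + 0.25 * np.sin(2 * np.pi * 0.8 * t)  # slow modulation
        vol = gen_volitional_emg(self.PARAMS, true_env)
        pulses = self._pulses(n / RATE)
        stream = gen_stimulated_emg(
            vol, pulses, np.full(len(pulses), 30.0), self.PARAMS
        )
        env = volitional_envelope(stream, CFG)
        sl = slice(2000, n - 2000)
        err = np.sqrt(np.mean((env[sl] - true_env[sl]) ** 2))
        assert err < 0.15 * np.sqrt(np.mean(true_env[sl] ** 2))

    def test_envelope_nonnegative(self, rng):
        vol = gen_volitional_emg(self.PARAMS, np.abs(rng.standard_normal(5000)) * 0.2)
        pulses = self._pulses(5.0)
        stream = gen_stimulated_emg(vol, pulses, np.full(len(pulses), 25.0), self.PARAMS)
        assert np.all(volitional_envelope(stream, CFG) >= 0.0)

    def test_linearity_in_volitional_component(self):
        """With a stationary M-wave the cascade output scales linearly with
        the volitional amplitude."""
        n = 10_000
        env1 = np.full(n, 0.3)
        pulses = self._pulses(n / RATE)
        outs = []
        for scale in (1.0, 2.0):
            vol = gen_volitional_emg(self.PARAMS, scale * env1)
            stream = gen_stimulated_emg(
                vol, pulses, np.full(len(pulses), 30.0), self.PARAMS
            )
            outs.append(np.median(volitional_envelope(stream, CFG)[2000:-2000]))
        assert outs[1] == pytest.approx(2.0 * outs[0], rel=0.1)


class TestVolitionalTorque:
    def test_zero_envelopes_near_zero_torque(self, small_model):
        assert abs(volitional_torque(0.0, 0.0, small_model).tau) < 1.0

    def test_sign_convention(self, small_model):
        assert volitional_torque(0.0, 0.6, small_model).tau > 0  # soleus only
        assert volitional_torque(0.6, 0.0, small_model).tau < 0  # TA only

    def test_end_to_end_estimation_accuracy(self, small_model, envelope_models):
        """Full chain at participation 0.5: synthesize contaminated EMG from
        a gait-patterned volitional torque, filter, estimate; the estimate
        must be within 25% RMS of the true volitional torque."""
        from hybridgait.reference import emg_envelope
        from hybridgait.synth import TORQUE_GAIN_NM

        n = 20_000
        t = np.arange(n) / RATE
        T = 2.4  # 1.8 km/h cycle
        phase = np.mod(100.0 * t / T, 100.0)
        alpha = 0.5
        tau_true = alpha * TORQUE_GAIN_NM * (
            np.asarray(emg_envelope(envelope_models["soleus"], 1.8, phase))
            - np.asarray(emg_envelope(envelope_models["TA"], 1.8, phase))
        )
        env_ta = np.maximum(-tau_true, 0.0) / TORQUE_GAIN_NM
        env_sol = np.maximum(tau_true, 0.0) / TORQUE_GAIN_NM
        params = EmgSynthesisParams(seed=11)
        pulses = np.arange(0.05, n / RATE - 0.01, 1.0 / 40.0)
        amps = np.full(len(pulses), 28.0)
        est = np.zeros(n)
        for c, env in ((0, env_ta), (1, env_sol)):
            vol = gen_volitional_emg(
                EmgSynthesisParams(seed=11 + c), env
            )
            stream = gen_stimulated_emg(vol, pulses, amps, params)
            rec = volitional_envelope(stream, CFG)
            sign = -1.0 if c == 0 else 1.0
            est += sign * TORQUE_GAIN_NM * rec
        sl = slice(2000, n - 2000)
        err = np.sqrt(np.mean((est[sl] - tau_true[sl]) ** 2))
        assert err < 0.25 * np.sqrt(np.mean(tau_true[sl] ** 2))
        # and the torque model agrees with the linear map on these envelopes
        mid = n // 2
        est_model = volitional_torque(
            float(np.maximum(-tau_true[mid], 0) / TORQUE_GAIN_NM),
            float(np.maximum(tau_true[mid], 0) / TORQUE_GAIN_NM),
            small_model,
        ).tau
        assert est_model == pytest.approx(tau_true[mid], abs=3.0)
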