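"""Synthetic signal generators for every input the hybrid stack consumes.

These generators are first-class, seeded, and always return the ground
truth alongside the observation, so every downstream estimator in the
package can be tested without recorded human data:

* volitional surface EMG as amplitude-modulated band-limited Gaussian
  noise (20-450 Hz interference-pattern convention at 1 kHz sampling);
* stimulation contamination: a one-sample artifact spike plus a biphasic
  M-wave template locked to each FES pulse, scaled linearly with the
  stimulation amplitude above the onset threshold;
* foot-switch (FSR) traces with heel contact over 0-40% and toe contact
  over 10-60% of the gait cycle;
* isometric EMG-torque datasets in which the torque target is a monotone
  function of the soleus-minus-TA RMS difference (plantar flexion
  positive), the recoverable mapping used to train and validate the
  torque regressor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .cnn import EmgTorqueDataset
from .filters import StimulatedEmgStream

__all__ = [
    "EmgSynthesisParams",
    "bandlimited_noise",
    "mwave_template",
    "gen_volitional_emg",
    "gen_stimulated_emg",
    "gen_fsr_traces",
    "gen_isometric_dataset",
    "TORQUE_GAIN_NM",
]

# Gain of the synthetic isometric mapping tau = gain * (rms_sol - rms_TA).
# With unit-normalized envelopes this spans roughly +/-30 Nm, the scale of
# the packaged reference torque.
TORQUE_GAIN_NM = 30.0


@dataclass(frozen=True)
class EmgSynthesisParams:
    """Parameters of the surface-EMG synthesis model."""

    rate: float = 1000.0  # Hz
    carrier_band: tuple[float, float] = (20.0, 450.0)  # Hz
    mwave_duration_ms: float = 15.0
    mwave_mv_per_ma: float = 0.1  # M-wave amplitude per mA above onset
    artifact_mv: float = 50.0  # one-sample stimulation artifact spike
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate < 1000.0:
            raise ValueError("rate must be >= 1000 Hz for surface EMG")
        if self.carrier_band[1] >= self.rate / 2:
            raise ValueError("carrier band must lie below Nyquist")


def bandlimited_noise(
    n: int,
    rate: float,
    rng: np.random.Generator,
    band: tuple[float, float] = (20.0, 450.0),
) -> np.ndarray:
    """Unit-RMS Gaussian noise band-passed to the surface-EMG band."""
    white = rng.standard_normal(n + 200)  # pad to absorb filter transients
    sos = butter(4, band, btype="bandpass", fs=rate, output="sos")
    shaped = sosfiltfilt(sos, white)[100 : 100 + n]
    return shaped / np.sqrt(np.mean(shaped**2))


def mwave_template(params: EmgSynthesisParams) -> np.ndarray:
    """Biphasic raised-cosine M-wave of unit amplitude per phase lobe."""
    n = max(int(round(params.mwave_duration_ms * 1e-3 * params.rate)), 4)
    half = n // 2
    lobe = 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(half) / half))
    template = np.zeros(n)
    template[:half] = lobe
    template[half : 2 * half] = -lobe[: n - half]
    return template


def gen_volitional_emg(
    params: EmgSynthesisParams,
    envelope: np.ndarray,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Volitional EMG with the given per-sample RMS-amplitude envelope.

    The output is band-limited Gaussian noise amplitude-modulated by
    ``envelope`` plus a small noise floor (1% of unit RMS), in mV.
    """
    envelope = np.asarray(envelope, dtype=float)
    if np.any(envelope < 0):
        raise ValueError("envelope must be nonnegative")
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    carrier = bandlimited_noise(len(envelope), params.rate, rng, params.carrier_band)
    floor = 0.01 * bandlimited_noise(
        len(envelope), params.rate, rng, params.carrier_band
    )
    return envelope * carrier + floor


def gen_stimulated_emg(
    volitional: np.ndarray,
    pulse_times: np.ndarray,
    amplitudes_ma: np.ndarray,
    params: EmgSynthesisParams,
    onset_ma: float = 10.0,
    rate: float | None = None,
) -> StimulatedEmgStream:
    """Contaminate a volitional stream with FES artifacts and M-waves.

    ``amplitudes_ma`` gives the stimulation amplitude at each pulse; the
    M-wave scales with the amplitude above ``onset_ma`` (zero below onset,
    matching the linear recruitment assumption) and the artifact spike is
    amplitude-independent.  The uncontaminated volitional stream stays
    available to the caller as ground truth.
    """
    rate = rate if rate is not None else params.rate
    volitional = np.asarray(volitional, dtype=float)
    pulse_times = np.asarray(pulse_times, dtype=float)
    amplitudes_ma = np.broadcast_to(
        np.asarray(amplitudes_ma, dtype=float), pulse_times.shape
    )
    n = len(volitional)
    t = np.arange(n) / rate
    samples = volitional.copy()
    template = mwave_template(params)
    for pt, amp in zip(pulse_times, amplitudes_ma, strict=True):
        i = int(round(pt * rate))
        if not 0 <= i < n:
            continue
        samples[i] += params.artifact_mv
        drive = max(amp - onset_ma, 0.0) * params.mwave_mv_per_ma
        if drive > 0:
            stop = min(i + 1 + len(template), n)
            samples[i + 1 : stop] += drive * template[: stop - (i + 1)]
    return StimulatedEmgStream(t=t, samples=samples, pulse_times=pulse_times, rate=rate)


def gen_fsr_traces(
    speed_kmh: float,
    n_cycles: int,
    noise: float = 0.02,
    seed: int = 0,
    rate: float = 1000.0,
    cadence_slope: float = 4.32,
    heel_window: tuple[float, float] = (0.0, 40.0),
    toe_window: tuple[float, float] = (10.0, 60.0),
) -> dict[str, np.ndarray]:
    """Synthetic foot-switch traces for treadmill walking at a given speed.

    The cycle duration follows the affine cadence-speed model
    (``T = cadence_slope / speed``).  Heel channels are loaded over
    ``heel_window`` percent of the cycle and toe channels over
    ``toe_window``, with smooth loading edges and additive Gaussian noise.
    Returns a dict with ``t``, the four channels (heel/toe x
    medial/lateral) and the ground-truth ``phase`` series.
    """
    if not 1.0 <= speed_kmh <= 5.0:
        raise ValueError("speed must be in [1, 5] km/h")
    if n_cycles < 0:
        raise ValueError("n_cycles must be nonnegative")
    rng = np.random.default_rng(seed)
    T = cadence_slope / speed_kmh
    n = int(round(n_cycles * T * rate))
    t = np.arange(n) / rate
    phase = np.mod(100.0 * t / T, 100.0)

    def _loaded(window: tuple[float, float]) -> np.ndarray:
        lo, hi = window
        ramp = 2.0  # % of cycle over which the sensor loads/unloads
        x = np.zeros(n)
        rising = np.clip((phase - lo) / ramp, 0.0, 1.0)
        falling = np.clip((hi - phase) / ramp, 0.0, 1.0)
        x = np.minimum(rising, falling)
        return np.clip(x, 0.0, 1.0)

    heel = _loaded(heel_window)
    toe = _loaded(toe_window)
    out = {"t": t, "phase": phase}
    for name, base, jitter in (
        ("heel_medial", heel, 1.0),
        ("heel_lateral", heel, 0.9),
        ("toe_medial", toe, 1.0),
        ("toe_lateral", toe, 0.85),
    ):
        out[name] = np.clip(
            jitter * base + noise * rng.standard_normal(n), 0.0, None
        )
    return out


def gen_isometric_dataset(
    n_samples: int = 2000,
    gain: float = TORQUE_GAIN_NM,
    noise_sigma: float = 0.5,
    seed: int = 7,
    window_len: int = 288,
    params: EmgSynthesisParams | None = None,
) -> EmgTorqueDataset:
    """Synthetic isometric EMG-torque dataset with a recoverable mapping.

    Each sample holds one activation level per muscle (drawn uniformly,
    with one muscle dominant in most trials, as in directional isometric
    tests); the 2-channel window is band-limited noise scaled by the
    activation, and the torque target is

        tau = gain * (rms(soleus) - rms(TA)) + N(0, noise_sigma)

    using the realized window RMS values, plantar flexion positive.
    Channel order is (TA, soleus).  The 6:2:2 split seed is the dataset
    seed.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    params = params or EmgSynthesisParams()
    rng = np.random.default_rng(seed)
    levels = rng.uniform(0.0, 1.0, size=(n_samples, 2))
    # most isometric trials load one direction at a time: suppress the
    # antagonist in 70% of the trials
    direction = rng.uniform(size=n_samples)
    levels[direction < 0.35, 1] *= 0.1  # dorsiflexion trials: soleus quiet
    levels[direction > 0.65, 0] *= 0.1  # plantar flexion trials: TA quiet
    windows = np.empty((n_samples, 2, window_len), dtype=np.float32)
    torques = np.empty(n_samples, dtype=np.float32)
    for i in range(n_samples):
        ta = levels[i, 0] * bandlimited_noise(
            window_len, params.rate, rng, params.carrier_band
        )
        sol = levels[i, 1] * bandlimited_noise(
            window_len, params.rate, rng, params.carrier_band
        )
        windows[i, 0] = ta
        windows[i, 1] = sol
        rms_ta = np.sqrt(np.mean(ta**2))
        rms_sol = np.sqrt(np.mean(sol**2))
        torques[i] = gain * (rms_sol - rms_ta) + noise_sigma * rng.standard_normal()
    return EmgTorqueDataset(
        windows=windows, torques=torques, split_ratio=(0.6, 0.2, 0.2), split_seed=seed
    )
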