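"""Extraction of volitional EMG from FES-contaminated recordings.

Each stimulation pulse contaminates the electrode signal with a large,
short artifact followed by an M-wave — the stereotyped compound action
potential evoked by the pulse, time-locked to it.  The volitional
component (the subject's own neural drive) rides underneath.  The cascade:

1. **Blanking** — samples inside a short window after each pulse are
   replaced by a zero-order hold of the last pre-pulse sample, removing the
   artifact that would otherwise dominate every later stage.
2. **Comb filtering** — consecutive inter-pulse segments are subtracted and
   halved, ``y = (x_i - x_{i-1}) / 2``.  A pulse-periodic stationary
   M-wave cancels exactly; the (uncorrelated) volitional component passes
   with its power halved.
3. **Envelope reconstruction** — full-wave rectification and a zero-phase
   low-pass at 2 Hz smooth the blanking discontinuities and yield the
   volitional amplitude envelope.  A fixed calibration gain undoes the
   known attenuation of steps 2-3 for Gaussian interference-pattern EMG,
   so the output estimates the RMS amplitude of the volitional signal.

The estimated envelopes of the two channels are converted to a volitional
joint torque by the EMG-torque regression model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

from .cnn import CnnTorqueRegressor, TorqueEstimate, estimate_torque

__all__ = [
    "StimulatedEmgStream",
    "FilterConfig",
    "BlankingOverlapError",
    "blank_artifacts",
    "comb_filter",
    "lowpass_reconstruct",
    "volitional_envelope",
    "volitional_torque",
    "carrier_window",
    "CASCADE_GAIN",
]

# Undoes the cascade attenuation for Gaussian volitional EMG: the comb
# halves the variance of the (uncorrelated) volitional component
# (factor 1/sqrt(2) in RMS) and rectification+low-pass of a zero-mean
# Gaussian yields sqrt(2/pi) of its RMS; together 1/sqrt(pi).
CASCADE_GAIN = math.sqrt(math.pi)


class BlankingOverlapError(ValueError):
    """Blanking windows of consecutive pulses overlap (window too long)."""


@dataclass
class StimulatedEmgStream:
    """A single-channel EMG recording with the FES pulse onsets that hit it."""

    t: np.ndarray  # s
    samples: np.ndarray  # mV
    pulse_times: np.ndarray  # s, strictly increasing pulse onsets
    rate: float  # Hz

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.samples = np.asarray(self.samples, dtype=float)
        self.pulse_times = np.asarray(self.pulse_times, dtype=float)
        if self.t.shape != self.samples.shape:
            raise ValueError("t and samples must be aligned")
        if len(self.pulse_times) and np.any(np.diff(self.pulse_times) <= 0):
            raise ValueError("pulse_times must be strictly increasing")


@dataclass(frozen=True)
class FilterConfig:
    """Artifact-removal cascade parameters."""

    blanking_ms: float = 5.0
    lowpass_cutoff_hz: float = 2.0
    lowpass_order: int = 4
    comb_mode: str = "paired-difference"

    def __post_init__(self) -> None:
        if self.blanking_ms <= 0 or self.lowpass_cutoff_hz <= 0:
            raise ValueError("blanking_ms and lowpass_cutoff_hz must be positive")


def blank_artifacts(
    stream: StimulatedEmgStream, cfg: FilterConfig
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Zero-order-hold blanking of the per-pulse artifact windows.

    Returns the blanked sample array and the list of inter-pulse segments
    (one per pulse: from the end of that pulse's blanking window to the
    next pulse onset, or the stream end for the last pulse).
    """
    samples = stream.samples.copy()
    n = len(samples)
    blank_len = int(round(cfg.blanking_ms * 1e-3 * stream.rate))
    pulse_idx = np.searchsorted(stream.t, stream.pulse_times)
    if len(pulse_idx) > 1 and np.any(np.diff(pulse_idx) <= blank_len):
        raise BlankingOverlapError(
            "blanking window >= inter-pulse interval; shorten blanking_ms"
        )
    segments: list[np.ndarray] = []
    for j, p in enumerate(pulse_idx):
        if p >= n:
            break
        hold = samples[p - 1] if p > 0 else 0.0
        stop = min(p + blank_len, n)
        samples[p:stop] = hold
        seg_end = pulse_idx[j + 1] if j + 1 < len(pulse_idx) else n
        segments.append(samples[stop : min(seg_end, n)].copy())
    return samples, segments


def comb_filter(
    segment_current: np.ndarray, segment_previous: np.ndarray
) -> np.ndarray:
    """Half-difference of consecutive inter-pulse segments.

        y = (x_i - x_{i-1}) / 2

    cancels any contaminant that repeats identically from pulse to pulse.
    When the segments differ in length (pulse-rate jitter), the shorter one
    is linearly resampled to the longer one's length before subtracting.
    """
    cur = np.asarray(segment_current, dtype=float)
    prev = np.asarray(segment_previous, dtype=float)
    if len(cur) == 0 or len(prev) == 0:
        return np.zeros(len(cur))
    if len(cur) != len(prev):
        n = len(cur)
        prev = np.interp(
            np.linspace(0.0, 1.0, n), np.linspace(0.0, 1.0, len(prev)), prev
        )
    return (cur - prev) / 2.0


def lowpass_reconstruct(signal: np.ndarray, cfg: FilterConfig, rate: float) -> np.ndarray:
    """Full-wave rectification then zero-phase Butterworth low-pass (DC gain 1)."""
    if cfg.lowpass_cutoff_hz >= rate / 2.0:
        raise ValueError("low-pass cutoff must be below the Nyquist frequency")
    b, a = butter(cfg.lowpass_order, cfg.lowpass_cutoff_hz, fs=rate)
    return filtfilt(b, a, np.abs(np.asarray(signal, dtype=float)))


def volitional_envelope(
    stream: StimulatedEmgStream, cfg: FilterConfig | None = None
) -> np.ndarray:
    """Volitional RMS-amplitude envelope of a contaminated stream.

    Runs the full blanking -> comb -> rectify/low-pass cascade and applies
    the calibration gain; the result is aligned with ``stream.t``.  With no
    pulses the stream is treated as already artifact-free (the comb stage
    is skipped and only the envelope stage applies, with the rectification
    factor still compensated).
    """
    cfg = cfg or FilterConfig()
    n = len(stream.samples)
    if len(stream.pulse_times) < 2:
        env = lowpass_reconstruct(stream.samples, cfg, stream.rate)
        return env * math.sqrt(math.pi / 2.0)
    blanked, segments = blank_artifacts(stream, cfg)
    blank_len = int(round(cfg.blanking_ms * 1e-3 * stream.rate))
    pulse_idx = np.searchsorted(stream.t, stream.pulse_times)
    comb = np.zeros(n)
    for j in range(1, len(segments)):
        y = comb_filter(segments[j], segments[j - 1])
        if len(y) == 0:
            continue
        start = min(pulse_idx[j] + blank_len, n)
        stop = pulse_idx[j + 1] if j + 1 < len(pulse_idx) else n
        # the blanked fraction of each inter-pulse span carries no signal;
        # scale the stitched segment so the rectified mean stays unbiased
        duty = (min(stop, n) - pulse_idx[j]) / len(y)
        comb[start : start + len(y)] = duty * y
    env = lowpass_reconstruct(comb, cfg, stream.rate) * CASCADE_GAIN
    return env


def volitional_torque(
    envelope_TA: float,
    envelope_sol: float,
    model: CnnTorqueRegressor,
) -> TorqueEstimate:
    """Volitional joint torque from the two muscle envelopes.

    Assembles a two-channel EMG window whose channel RMS amplitudes equal
    the given envelopes — each channel is a fixed unit-RMS broadband
    carrier scaled by its envelope — and delegates to the EMG-torque
    regression model.  Channel order is (TA, soleus).
    """
    carrier = carrier_window(model.window_len)
    window = np.vstack(
        [
            max(float(envelope_TA), 0.0) * carrier[0],
            max(float(envelope_sol), 0.0) * carrier[1],
        ]
    )
    return estimate_torque(model, window)


_CARRIER_CACHE: dict[int, np.ndarray] = {}


def carrier_window(window_len: int, rate: float = 1000.0) -> np.ndarray:
    """Fixed 2-channel unit-RMS broadband carrier used to embed envelope
    values into EMG windows (deterministic; cached per window length)."""
    cached = _CARRIER_CACHE.get(window_len)
    if cached is None:
        from .synth import bandlimited_noise  # deferred: synth imports filters

        rng = np.random.default_rng(20230917)
        cached = np.vstack(
            [bandlimited_noise(window_len, rate, rng) for _ in range(2)]
        )
        _CARRIER_CACHE[window_len] = cached
    return cached
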