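"""Ground-contact detection from foot-switch traces and gait-phase tracking.

Four force-sensitive resistors (FSRs) under the sole — medial/lateral heel
and medial/lateral toe — give raw pressure readings.  Contact is detected
per region by thresholding with a hysteresis band; heel strikes define the
gait cycle (0% = heel strike), and walking speed is mapped from cadence by
an affine calibration clamped to the 1-5 km/h envelope over which the
reference profiles are defined.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

__all__ = [
    "FsrFrame",
    "GaitStatus",
    "ColdStartError",
    "ContactDetector",
    "GaitPhaseTracker",
    "detect_contacts",
    "update_gait_phase",
    "estimate_speed",
]

SPEED_RANGE_KMH = (1.0, 5.0)


@dataclass(frozen=True)
class FsrFrame:
    """One sample of the four foot-switch channels (raw units >= 0)."""

    t: float
    heel_medial: float
    heel_lateral: float
    toe_medial: float
    toe_lateral: float


@dataclass(frozen=True)
class GaitStatus:
    """Gait phase in percent of cycle, cycle duration, speed and stance flag."""

    phase: float  # % of gait cycle, [0, 100)
    cycle_duration: float  # s
    speed: float  # km/h
    in_stance: bool


class ColdStartError(RuntimeError):
    """Phase requested before two heel strikes have defined a cycle."""


class ContactDetector:
    """Per-region contact detection with a hysteresis band.

    A channel turns ON when its raw value exceeds ``threshold * (1 + h)``
    and OFF when it falls below ``threshold * (1 - h)``; in between, the
    previous state is held, suppressing threshold chatter.  Heel and toe
    contacts are the OR of their two channels.
    """

    _CHANNELS = ("heel_medial", "heel_lateral", "toe_medial", "toe_lateral")

    def __init__(self, thresholds: dict[str, float], hysteresis: float = 0.10):
        for name in self._CHANNELS:
            if thresholds.get(name, 0.0) <= 0:
                raise ValueError(f"threshold for {name} must be positive")
        if not 0.0 <= hysteresis < 1.0:
            raise ValueError("hysteresis must be in [0, 1)")
        self.thresholds = dict(thresholds)
        self.hysteresis = hysteresis
        self._state = {name: False for name in self._CHANNELS}

    @classmethod
    def from_calibration(
        cls, frames: "np.ndarray", fraction: float = 0.20, hysteresis: float = 0.10
    ) -> "ContactDetector":
        """Thresholds at ``fraction`` of each channel's max over a calibration pass.

        ``frames``: array of shape (n, 4) ordered heel_medial, heel_lateral,
        toe_medial, toe_lateral.
        """
        maxima = np.asarray(frames, dtype=float).max(axis=0)
        thresholds = {
            name: fraction * m for name, m in zip(cls._CHANNELS, maxima, strict=True)
        }
        return cls(thresholds, hysteresis)

    def update(self, frame: FsrFrame) -> tuple[bool, bool]:
        """Process one frame; returns (heel_contact, toe_contact)."""
        for name in self._CHANNELS:
            raw = getattr(frame, name)
            thr = self.thresholds[name]
            if raw > thr * (1.0 + self.hysteresis):
                self._state[name] = True
            elif raw < thr * (1.0 - self.hysteresis):
                self._state[name] = False
        heel = self._state["heel_medial"] or self._state["heel_lateral"]
        toe = self._state["toe_medial"] or self._state["toe_lateral"]
        return heel, toe


def detect_contacts(
    frame: FsrFrame,
    thresholds: dict[str, float],
    hysteresis: float = 0.10,
    detector: ContactDetector | None = None,
) -> tuple[bool, bool]:
    """Stateless convenience wrapper around :class:`ContactDetector`.

    Without a ``detector`` a fresh (all-OFF) detector is used, so hysteresis
    memory only applies when the caller threads one through.
    """
    det = detector if detector is not None else ContactDetector(thresholds, hysteresis)
    return det.update(frame)


class GaitPhaseTracker:
    """Tracks gait phase from heel-strike timestamps.

    The cycle duration is the median of the last three inter-strike
    intervals (robust to a single mistimed strike); phase is the elapsed
    fraction of that duration since the most recent strike, clamped just
    below 100%.
    """

    def __init__(self, n_intervals: int = 3):
        self.strikes: list[float] = []
        self._intervals: deque[float] = deque(maxlen=n_intervals)

    def record_heel_strike(self, t: float) -> None:
        if self.strikes and t <= self.strikes[-1]:
            raise ValueError("heel strikes must be strictly increasing in time")
        if self.strikes:
            self._intervals.append(t - self.strikes[-1])
        self.strikes.append(t)

    @property
    def cycle_duration(self) -> float:
        if not self._intervals:
            raise ColdStartError("need two heel strikes before a cycle is defined")
        return float(np.median(self._intervals))

    def phase(self, t: float) -> float:
        duration = self.cycle_duration
        frac = 100.0 * (t - self.strikes[-1]) / duration
        return float(min(max(frac, 0.0), 100.0 - 1e-9))


def update_gait_phase(
    event_history: "list[float] | GaitPhaseTracker",
    t: float,
    speed_calibration: tuple[float, float] = (4.32, 0.0),
    in_stance: bool = True,
) -> GaitStatus:
    """Gait status at time ``t`` given the heel-strike history.

    ``event_history`` is either a tracker or a plain list of strike
    timestamps.  Raises :class:`ColdStartError` before the second strike,
    in which case the caller must hold reference playback.
    """
    if isinstance(event_history, GaitPhaseTracker):
        tracker = event_history
    else:
        tracker = GaitPhaseTracker()
        for ts in event_history:
            tracker.record_heel_strike(ts)
    duration = tracker.cycle_duration
    return GaitStatus(
        phase=tracker.phase(t),
        cycle_duration=duration,
        speed=estimate_speed(duration, speed_calibration),
        in_stance=in_stance,
    )


def estimate_speed(
    cycle_duration: float, calibration: tuple[float, float] = (4.32, 0.0)
) -> float:
    """Affine cadence-to-speed map, clamped to the validated 1-5 km/h range.

        speed = clamp(slope / cycle_duration + intercept, 1, 5)   [km/h]

    The default slope treats a 1.44 s cycle as 3 km/h treadmill walking,
    i.e. stride length grows with cadence only through the affine map.
    """
    if cycle_duration <= 0:
        raise ValueError("cycle_duration must be positive")
    slope, intercept = calibration
    speed = slope / cycle_duration + intercept
    lo, hi = SPEED_RANGE_KMH
    return float(min(max(speed, lo), hi))
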