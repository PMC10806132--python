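"""Speed-adaptive reference EMG envelopes and reference gait trajectories.

Two kinds of reference input drive the hybrid controller:

* **EMG envelopes** for the tibialis anterior (TA) and soleus, expressed as
  truncated Fourier series in gait phase, fitted separately at five walking
  speeds (1-5 km/h) and linearly interpolated in speed between those nodes.
  The soleus envelope concentrates in stance (propulsion, roughly 20-60% of
  the cycle); the TA envelope spans swing through heel strike (60-100% and
  0-20%) for toe clearance and controlled foot lowering.

* **Reference trajectories** for the orthosis: ankle angle, ankle torque
  and joint stiffness over one cycle on a uniform phase grid.  Stiffness is
  derived from the slope of the moment-angle relation along the cycle and
  shows the characteristic two peaks: loading response (~30%) and push-off
  propulsion (~50%).

The packaged default envelopes and trajectory tables are generated from
smooth analytic gait templates (raised-cosine activation bumps, periodic
splines through normative keypoints); ``fit_envelope`` lets users refit
from their own sampled profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "EnvelopeModel",
    "ReferenceTable",
    "emg_envelope",
    "fit_envelope",
    "stiffness_from_moment_angle",
    "default_envelope_model",
    "default_reference_table",
    "SPEED_NODES_KMH",
    "PHASE_GRID_POINTS",
]

SPEED_NODES_KMH = (1.0, 2.0, 3.0, 4.0, 5.0)
PHASE_GRID_POINTS = 201
DEFAULT_FOURIER_ORDER = 6

# Normative ankle-angle keypoints (phase %, degrees, dorsiflexion positive)
# for the packaged reference trajectory: controlled plantar flexion after
# heel strike, progressive dorsiflexion through midstance, rapid plantar
# flexion at push-off, dorsiflexion for toe clearance in swing.  A periodic
# cubic spline through these points gives the -10..12 deg range of motion
# of slow treadmill gait.
_ANGLE_KEYPOINTS_DEG = [
    (0.0, 0.0),
    (8.0, -5.0),
    (20.0, 3.0),
    (35.0, 9.0),
    (50.0, 12.0),
    (68.0, -10.0),
    (85.0, 2.0),
    (95.0, 1.0),
    (100.0, 0.0),
]

# The packaged reference torque is generated from a designed phase-varying
# quasi-stiffness profile, tau'(phi) = k(phi) * theta'(phi): the ankle is
# modelled as a phase-modulated elastic element, so torque and angle
# reversals coincide and the moment-angle slope recovers k(phi) exactly.
# k(phi) = K0 + A_LOAD * bump(30%) + s * A_PUSH * bump(50%), with the
# push-off amplitude scaled by the closure factor s that makes the torque
# return to its heel-strike value after one cycle.
_STIFFNESS_BASE = 12.0  # Nm/rad, swing-phase residual stiffness
_STIFFNESS_LOAD = (280.0, 30.0, 13.0)  # amplitude, center %, half-width %
_STIFFNESS_PUSH = (380.0, 50.0, 9.0)


@dataclass(frozen=True)
class EnvelopeModel:
    """Per-speed Fourier models of a muscle's normalized EMG envelope.

    ``coeffs`` has shape (n_speeds, 2M+1) laid out as
    ``[a0, a1..aM, b1..bM]`` for the series
    ``a0 + sum_k a_k cos(2 pi k phi/100) + b_k sin(2 pi k phi/100)``.
    """

    muscle: str
    speed_nodes: tuple[float, ...]
    coeffs: np.ndarray
    order: int

    def __post_init__(self) -> None:
        nodes = np.asarray(self.speed_nodes, dtype=float)
        if not np.all(np.diff(nodes) > 0):
            raise ValueError("speed_nodes must be strictly increasing")
        c = np.asarray(self.coeffs, dtype=float)
        if c.shape != (len(nodes), 2 * self.order + 1):
            raise ValueError(
                f"coeffs shape {c.shape} incompatible with "
                f"{len(nodes)} nodes and order {self.order}"
            )


def _design_matrix(phase: np.ndarray, order: int) -> np.ndarray:
    """Fourier design matrix on a 100%-periodic phase axis."""
    w = 2.0 * np.pi * np.asarray(phase, dtype=float)[:, None] / 100.0
    k = np.arange(1, order + 1)[None, :]
    return np.hstack(
        [np.ones((len(phase), 1)), np.cos(w * k), np.sin(w * k)]
    )


def _series_eval(coeffs: np.ndarray, phase: np.ndarray, order: int) -> np.ndarray:
    return _design_matrix(np.atleast_1d(phase), order) @ coeffs


def emg_envelope(
    model: EnvelopeModel, speed: float, phase: "float | np.ndarray"
) -> "float | np.ndarray":
    """Normalized activation in [0, 1] at a walking speed and gait phase.

    The Fourier series of the two speed nodes bracketing ``speed`` are
    evaluated at ``phase`` and linearly interpolated in speed; at a node the
    value is exactly that node's series.  The result is clipped to [0, 1].
    """
    nodes = np.asarray(model.speed_nodes)
    if not nodes[0] <= speed <= nodes[-1]:
        raise ValueError(f"speed {speed} km/h outside nodes [{nodes[0]}, {nodes[-1]}]")
    phase_arr = np.atleast_1d(np.asarray(phase, dtype=float))
    if np.any((phase_arr < 0) | (phase_arr >= 100)):
        raise ValueError("phase must lie in [0, 100)")
    hi = int(np.searchsorted(nodes, speed, side="left"))
    if hi == 0 or nodes[hi - 1] == speed or (hi < len(nodes) and nodes[hi] == speed):
        idx = hi if hi < len(nodes) and nodes[hi] == speed else hi - 1
        vals = _series_eval(model.coeffs[idx], phase_arr, model.order)
    else:
        lo = hi - 1
        w = (speed - nodes[lo]) / (nodes[hi] - nodes[lo])
        v_lo = _series_eval(model.coeffs[lo], phase_arr, model.order)
        v_hi = _series_eval(model.coeffs[hi], phase_arr, model.order)
        vals = (1.0 - w) * v_lo + w * v_hi
    vals = np.clip(vals, 0.0, 1.0)
    return float(vals[0]) if np.isscalar(phase) or np.ndim(phase) == 0 else vals


def fit_envelope(
    profiles: dict[float, np.ndarray],
    order: int = DEFAULT_FOURIER_ORDER,
    muscle: str = "muscle",
) -> tuple[EnvelopeModel, dict[float, float]]:
    """Least-squares Fourier fit of per-speed envelope profiles.

    Parameters
    ----------
    profiles : dict
        Maps speed (km/h) to an envelope sampled on a uniform phase grid
        covering [0, 100); values must lie in [0, 1].
    order : int
        Fourier order M; each profile needs at least 2M+1 samples.

    Returns
    -------
    model, rmse
        The fitted :class:`EnvelopeModel` and per-speed reconstruction RMSE.
    """
    speeds = sorted(profiles)
    coeffs, rmse = [], {}
    for v in speeds:
        y = np.asarray(profiles[v], dtype=float)
        if y.ndim != 1 or len(y) < 2 * order + 1:
            raise ValueError(
                f"profile at {v} km/h needs >= {2 * order + 1} samples for order {order}"
            )
        phase = np.linspace(0.0, 100.0, len(y), endpoint=False)
        X = _design_matrix(phase, order)
        c, *_ = np.linalg.lstsq(X, y, rcond=None)
        coeffs.append(c)
        rmse[v] = float(np.sqrt(np.mean((X @ c - y) ** 2)))
    model = EnvelopeModel(
        muscle=muscle,
        speed_nodes=tuple(speeds),
        coeffs=np.vstack(coeffs),
        order=order,
    )
    return model, rmse


def _raised_cosine(phase: np.ndarray, center: float, half_width: float) -> np.ndarray:
    """Periodic raised-cosine bump of unit height on the 0-100% phase axis."""
    d = np.mod(np.asarray(phase, dtype=float) - center + 50.0, 100.0) - 50.0
    out = np.zeros_like(d)
    inside = np.abs(d) <= half_width
    out[inside] = 0.5 * (1.0 + np.cos(np.pi * d[inside] / half_width))
    return out


def _template_profile(muscle: str, speed: float, phase: np.ndarray) -> np.ndarray:
    """Analytic activation template for one muscle at one speed.

    Amplitude grows with speed (stronger propulsion and foot-lift demand at
    faster walking); bump placement follows the stance/swing roles of the
    two muscles.
    """
    gain = 0.45 + 0.115 * (speed - 1.0)  # 0.45 at 1 km/h -> 0.91 at 5 km/h
    if muscle == "soleus":
        return gain * _raised_cosine(phase, center=42.0, half_width=21.0)
    if muscle == "TA":
        swing = _raised_cosine(phase, center=95.0, half_width=28.0)
        lowering = 0.55 * _raised_cosine(phase, center=6.0, half_width=12.0)
        return gain * np.clip(swing + lowering, 0.0, 1.0)
    raise ValueError(f"unknown muscle {muscle!r}")


def default_envelope_model(
    muscle: str, order: int = DEFAULT_FOURIER_ORDER
) -> EnvelopeModel:
    """Packaged default envelope model for ``'TA'`` or ``'soleus'``."""
    phase = np.linspace(0.0, 100.0, PHASE_GRID_POINTS - 1, endpoint=False)
    profiles = {
        v: _template_profile(muscle, v, phase) for v in SPEED_NODES_KMH
    }
    model, _ = fit_envelope(profiles, order=order, muscle=muscle)
    return model


@dataclass(frozen=True)
class ReferenceTable:
    """Reference ankle angle, torque and stiffness on a uniform phase grid."""

    phase_grid: np.ndarray  # %, uniform over [0, 100]
    theta_ref: np.ndarray  # rad, dorsiflexion positive
    tau_ref: np.ndarray  # Nm, plantar flexion positive
    k_ref: np.ndarray  # Nm/rad, >= 0

    def __post_init__(self) -> None:
        n = len(self.phase_grid)
        if not (len(self.theta_ref) == len(self.tau_ref) == len(self.k_ref) == n):
            raise ValueError("reference series must share the phase grid")
        if np.any(self.k_ref < 0):
            raise ValueError("k_ref must be nonnegative")

    def _interp(self, series: np.ndarray, phase: "float | np.ndarray"):
        vals = np.interp(np.mod(phase, 100.0), self.phase_grid, series)
        return float(vals) if np.ndim(phase) == 0 else vals

    def angle(self, phase):
        return self._interp(self.theta_ref, phase)

    def torque(self, phase):
        return self._interp(self.tau_ref, phase)

    def stiffness(self, phase):
        return self._interp(self.k_ref, phase)

    @property
    def k_ref_max(self) -> float:
        return float(np.max(self.k_ref))


def stiffness_from_moment_angle(
    theta_ref: np.ndarray,
    tau_ref: np.ndarray,
    *,
    eps: float = 1e-6,
    smooth_window: int = 5,
) -> np.ndarray:
    """Joint stiffness as the slope of the moment-angle curve along the cycle.

    Computes the centered finite difference d(tau)/d(theta) treating the
    series as periodic in phase, carries the neighbouring slope across
    angle-reversal points where ``|d theta| < eps`` (the slope is undefined
    there), rectifies to >= 0 and smooths with a centered moving average.
    """
    theta = np.asarray(theta_ref, dtype=float)
    tau = np.asarray(tau_ref, dtype=float)
    if theta.shape != tau.shape or theta.ndim != 1:
        raise ValueError("theta_ref and tau_ref must be aligned 1-D series")
    dtheta = np.roll(theta, -1) - np.roll(theta, 1)
    dtau = np.roll(tau, -1) - np.roll(tau, 1)
    n = len(theta)
    slope = np.empty(n)
    defined = np.abs(dtheta) >= eps
    if not np.any(defined):
        raise ValueError("moment-angle curve has no resolvable angle excursion")
    slope[defined] = dtau[defined] / dtheta[defined]
    # undefined points inherit the nearest defined slope along the cycle
    if not np.all(defined):
        idx_def = np.flatnonzero(defined)
        for i in np.flatnonzero(~defined):
            # circular nearest defined neighbour
            d = np.minimum(np.abs(idx_def - i), n - np.abs(idx_def - i))
            slope[i] = slope[idx_def[np.argmin(d)]]
    slope = np.maximum(slope, 0.0)
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        padded = np.concatenate([slope[-pad:], slope, slope[:pad]])
        slope = np.convolve(padded, kernel, mode="valid")[: n]
    return slope


def default_reference_table(n_points: int = PHASE_GRID_POINTS) -> ReferenceTable:
    """Packaged reference trajectories from the analytic gait templates.

    The angle comes from a periodic spline through normative keypoints; the
    torque integrates the designed quasi-stiffness profile along the angle
    trajectory (see module constants), which closes the moment-angle loop
    over one cycle and yields a stiffness curve with loading-response and
    push-off peaks near 30% and 50% of the cycle.
    """
    phase = np.linspace(0.0, 100.0, n_points)
    kp_a = np.asarray(_ANGLE_KEYPOINTS_DEG)
    theta = np.deg2rad(CubicSpline(kp_a[:, 0], kp_a[:, 1], bc_type="periodic")(phase))
    dtheta_dphi = np.gradient(theta, phase)

    a_load, c_load, w_load = _STIFFNESS_LOAD
    a_push, c_push, w_push = _STIFFNESS_PUSH
    base = _STIFFNESS_BASE + a_load * _raised_cosine(phase, c_load, w_load)
    push = a_push * _raised_cosine(phase, c_push, w_push)
    # closure factor: scale the push-off bump so the net work of the elastic
    # element over one cycle is zero (torque returns to its start value)
    s = -np.trapezoid(base * dtheta_dphi, phase) / np.trapezoid(
        push * dtheta_dphi, phase
    )
    k_profile = base + s * push
    tau = np.concatenate(
        [[0.0], np.cumsum(0.5 * (k_profile[1:] + k_profile[:-1]) * np.diff(theta))]
    )
    k_ref = stiffness_from_moment_angle(theta, tau)
    return ReferenceTable(phase_grid=phase, theta_ref=theta, tau_ref=tau, k_ref=k_ref)
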