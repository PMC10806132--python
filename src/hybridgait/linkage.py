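"""Kinematics, dynamics and control laws of a 1-DOF powered ankle-foot orthosis.

The orthosis couples a ball-screw linear actuator to the ankle joint through a
planar linkage with three revolute joints (R1 at the ankle, R2 at the ball
nut, R3 carrying the screw) and one prismatic joint.  The triangle R1-R2-R3
has fixed sides ``l1`` (R1-R2) and ``l2`` (R1-R3); the third side ``l3``
follows from the screw travel ``lscrew`` and the moment arm ``lR3`` of joint
R3.  Driving the screw changes ``l3`` and therefore the angle at R1.

Angles in this module live in the *linkage frame*: the raw angle of the
R1 triangle plus the structural offset ``theta_P1``.  The clinical
convention (dorsiflexion positive, zero at the neutral standing posture) is
obtained by subtracting :attr:`LinkageGeometry.neutral_angle`; all
higher-level modules use the clinical convention and convert at this
boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "LinkageGeometry",
    "PafoState",
    "ImpedanceSetpoint",
    "PDGains",
    "LinkageDomainError",
    "UnreachableAngleError",
    "IntegrationDivergedError",
    "ankle_angle_from_screw",
    "screw_from_ankle_angle",
    "external_torque",
    "impedance_torque",
    "actuator_torque",
    "gravity_torque",
    "desired_angle_step",
    "pd_control",
]


class LinkageDomainError(ValueError):
    """Screw travel incompatible with the linkage triangle inequality."""


class UnreachableAngleError(ValueError):
    """No admissible screw travel realises the requested joint angle."""


class IntegrationDivergedError(RuntimeError):
    """Desired-angle integration left the plausible range (instability)."""


@dataclass(frozen=True)
class LinkageGeometry:
    """Geometry of the four-joint ankle linkage.

    Parameters
    ----------
    l1, l2 : float
        Fixed link lengths R1-R2 and R1-R3 in metres.
    lR3 : float
        Moment arm of joint R3 in metres.
    theta_P1 : float
        Fixed structural angle of the upper frame, radians.
    screw_lead : float
        Ball-screw lead, metres per revolution.
    screw_travel_limits : tuple of float
        Admissible (min, max) ball-nut travel ``lscrew`` in metres.
    """

    l1: float = 0.25
    l2: float = 0.06
    lR3: float = 0.03
    theta_P1: float = 0.35
    screw_lead: float = 0.002
    screw_travel_limits: tuple[float, float] = (0.20, 0.30)

    def __post_init__(self) -> None:
        if min(self.l1, self.l2, self.lR3) <= 0:
            raise ValueError("link lengths must be positive")
        lo, hi = self.screw_travel_limits
        if not lo < hi:
            raise ValueError("screw_travel_limits must satisfy min < max")

    @property
    def neutral_angle(self) -> float:
        """Linkage-frame angle of the neutral (standing) ankle posture."""
        return math.pi / 2 + self.theta_P1

    def l3(self, lscrew: float) -> float:
        """Distance R2-R3 for a given ball-nut travel."""
        return math.hypot(lscrew, self.lR3)

    def to_clinical(self, theta_linkage: float) -> float:
        """Linkage-frame angle -> dorsiflexion-positive clinical angle."""
        return theta_linkage - self.neutral_angle

    def from_clinical(self, theta_clinical: float) -> float:
        """Dorsiflexion-positive clinical angle -> linkage-frame angle."""
        return theta_clinical + self.neutral_angle


@dataclass
class PafoState:
    """Instantaneous state of the orthosis joint."""

    theta: float = 0.0  # clinical angle, rad, dorsiflexion positive
    theta_dot: float = 0.0  # rad/s
    lscrew: float = 0.25  # m
    F_sensor: float = 0.0  # N, shank-orthosis interaction force
    t: float = 0.0  # s


@dataclass(frozen=True)
class ImpedanceSetpoint:
    """Reference angle with rendered stiffness and damping."""

    theta_ref: float  # rad
    k_d: float  # Nm/rad
    c_d: float  # Nm*s/rad

    def __post_init__(self) -> None:
        if self.k_d < 0 or self.c_d < 0:
            raise ValueError("impedance gains must be nonnegative")


@dataclass(frozen=True)
class PDGains:
    """Position-loop PD gains and joint inertia."""

    K_P: float = 250.0  # per rad
    K_D: float = 8.0  # per rad/s
    I: float = 0.05  # kg*m^2, foot + orthosis about the ankle

    def __post_init__(self) -> None:
        if self.K_P <= 0 or self.K_D < 0 or self.I <= 0:
            raise ValueError("require K_P > 0, K_D >= 0, I > 0")


def _check_travel(geom: LinkageGeometry, lscrew: float) -> None:
    lo, hi = geom.screw_travel_limits
    if not lo <= lscrew <= hi:
        raise LinkageDomainError(
            f"lscrew={lscrew:.4f} m outside travel limits [{lo}, {hi}]"
        )


def ankle_angle_from_screw(geom: LinkageGeometry, lscrew: float) -> float:
    """Forward kinematics: ball-nut travel -> linkage-frame joint angle.

    theta = arccos((l1^2 + l2^2 - lscrew^2 - lR3^2) / (2 l1 l2)) + theta_P1
    """
    _check_travel(geom, lscrew)
    l3sq = lscrew * lscrew + geom.lR3 * geom.lR3
    arg = (geom.l1**2 + geom.l2**2 - l3sq) / (2.0 * geom.l1 * geom.l2)
    if not -1.0 <= arg <= 1.0:
        raise LinkageDomainError(
            f"cosine argument {arg:.4f} outside [-1, 1]: linkage/travel mismatch"
        )
    return math.acos(arg) + geom.theta_P1


def screw_from_ankle_angle(geom: LinkageGeometry, theta: float) -> float:
    """Inverse kinematics: linkage-frame joint angle -> ball-nut travel.

    Inverts the law of cosines of the R1-R2-R3 triangle; raises
    :class:`UnreachableAngleError` when the implied travel leaves the screw
    limits or the triangle degenerates.
    """
    alpha = theta - geom.theta_P1
    if not 0.0 <= alpha <= math.pi:
        raise UnreachableAngleError(f"theta={theta:.4f} rad outside linkage range")
    l3sq = geom.l1**2 + geom.l2**2 - 2.0 * geom.l1 * geom.l2 * math.cos(alpha)
    lscrew_sq = l3sq - geom.lR3 * geom.lR3
    if lscrew_sq < 0:
        raise UnreachableAngleError(
            f"theta={theta:.4f} rad implies l3 shorter than the R3 moment arm"
        )
    lscrew = math.sqrt(lscrew_sq)
    lo, hi = geom.screw_travel_limits
    if not lo <= lscrew <= hi:
        raise UnreachableAngleError(
            f"theta={theta:.4f} rad needs lscrew={lscrew:.4f} m outside [{lo}, {hi}]"
        )
    return lscrew


def external_torque(geom: LinkageGeometry, lscrew: float, F_sensor: float) -> float:
    """Torque about the ankle from the measured shank interaction force.

    The load cell in the upper frame measures the force ``F_sensor`` along
    the shank cuff; the linkage geometry resolves it into a moment about R1.
    Linear in ``F_sensor`` at a fixed configuration.
    """
    _check_travel(geom, lscrew)
    l1, l2, lR3 = geom.l1, geom.l2, geom.lR3
    l3 = geom.l3(lscrew)
    a1 = (l2 * l2 + l3 * l3 - l1 * l1) / (2.0 * l2 * l3)
    a2 = (l1 * l1 + l3 * l3 - l2 * l2) / (2.0 * l1 * l3)
    if not (-1.0 <= a1 <= 1.0 and -1.0 <= a2 <= 1.0):
        raise LinkageDomainError("degenerate linkage triangle for external torque")
    term_sin = math.sin(math.acos(a1) + math.atan2(lscrew, lR3) - geom.theta_P1)
    term_cos = math.cos(math.acos(a2) + math.atan2(lR3, lscrew) - math.pi / 2)
    return F_sensor * l1 * term_sin * term_cos


def impedance_torque(e: float, e_dot: float, setpoint: ImpedanceSetpoint) -> float:
    """Virtual spring-damper torque tau_c = -(k_d e + c_d e_dot).

    ``e = theta - theta_ref``; a dorsiflexion excursion past the reference
    produces a plantar-flexion (negative) restoring torque.
    """
    return -(setpoint.k_d * e + setpoint.c_d * e_dot)


def actuator_torque(tau_c: float, tau_g_hat: float) -> float:
    """Actuator command tau_A = tau_c - tau_g_hat (gravity compensation)."""
    return tau_c - tau_g_hat


def gravity_torque(
    foot_mass: float, com_distance: float, theta_absolute: float, g: float = 9.81
) -> float:
    """Gravity torque of the foot modelled as a point mass on a pendulum.

    ``theta_absolute`` is the foot-segment angle from the vertical; at zero
    the centre of mass hangs below the joint and the torque vanishes.
    """
    if foot_mass < 0 or com_distance < 0:
        raise ValueError("foot_mass and com_distance must be nonnegative")
    return -foot_mass * g * com_distance * math.sin(theta_absolute)


def desired_angle_step(
    theta_d: float,
    theta_d_dot: float,
    setpoint: ImpedanceSetpoint,
    tau_ext: float,
    gains: PDGains,
    dt: float,
    *,
    theta_measured: float | None = None,
) -> tuple[float, float]:
    """One semi-implicit Euler step of the admittance (desired-angle) model.

        I * theta_d_ddot = -(k_d e + c_d e_dot) + tau_ext

    By default ``e = theta_d - theta_ref`` so the model is self-contained
    (admittance-style desired trajectory).  Passing ``theta_measured``
    switches the error to the measured joint angle instead.

    The semi-implicit update (velocity first, then position) keeps the
    stiffness term stable at millisecond steps; the damping term is treated
    implicitly because the rendered damping can be large relative to the
    joint inertia.
    """
    if not 0.0 < dt <= 0.010:
        raise ValueError("dt must be in (0, 10 ms] for the stability contract")
    e = (theta_measured if theta_measured is not None else theta_d) - setpoint.theta_ref
    drive = (-setpoint.k_d * e + tau_ext) / gains.I
    theta_d_dot_next = (theta_d_dot + dt * drive) / (1.0 + dt * setpoint.c_d / gains.I)
    theta_d_next = theta_d + dt * theta_d_dot_next
    if not (math.isfinite(theta_d_next) and abs(theta_d_next) <= 10.0):
        raise IntegrationDivergedError(
            f"desired angle diverged to {theta_d_next!r} rad"
        )
    return theta_d_next, theta_d_dot_next


def pd_control(e_d: float, e_d_dot: float, gains: PDGains) -> float:
    """Position-loop PD control signal u = K_P e_d + K_D e_d_dot.

    ``e_d = theta - theta_d``.  The sign convention is that the actuator
    applies ``-u`` to the joint, driving the measured angle toward the
    desired one.
    """
    return gains.K_P * e_d + gains.K_D * e_d_dot
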