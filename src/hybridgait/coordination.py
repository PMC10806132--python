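"""Torque-sharing laws coordinating orthosis, stimulation and volition.

Given the reference joint torque for the current gait phase and the torque
the wearer produces volitionally, the coordinator decides

* the stimulation amplitudes for the two muscles — the tibialis anterior
  (TA) produces dorsiflexion (negative torque), the soleus plantar flexion
  (positive torque); the muscles are assumed not to co-contract, so only
  the channel matching the sign of the reference torque is driven above
  its minimum, in proportion to the torque deficit the wearer leaves;
* the activation ratio ``r_v`` in [0, 1] — the wearer's share of the
  demanded torque, zero whenever they cannot meet the reference (the gait
  is then fully assisted);
* the rendered stiffness and damping of the orthosis — stiffness drops
  with ``r_v`` (assist-as-needed) and is clamped between configured
  bounds; damping scales with stiffness through the damping ratio.

Volitional torque offsets the demand only in its own direction: antagonist
effort does not increase the stimulation of the active channel.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "SubjectCalibration",
    "CoordinationOutput",
    "StimulationRangeError",
    "fes_amplitudes",
    "activation_ratio",
    "desired_stiffness",
    "desired_damping",
    "coordinate",
    "K_MIN_DEFAULT",
    "K_MAX_DEFAULT",
    "ZETA_DEFAULT",
]

K_MIN_DEFAULT = 5.0  # Nm/rad
K_MAX_DEFAULT = 150.0  # Nm/rad
ZETA_DEFAULT = 0.7


class StimulationRangeError(ValueError):
    """A commanded amplitude would exceed the subject's pain threshold."""


@dataclass(frozen=True)
class SubjectCalibration:
    """Per-subject stimulation bounds and torque extrema.

    Amplitudes in mA; the working range [min, max] of each channel must lie
    inside [onset, pain] found in the sensitivity test.  ``tau_ref_max_neg``
    is the magnitude of the most negative (dorsiflexion) reference torque,
    ``tau_ref_max_pos`` the largest positive (plantar flexion) one;
    ``tau_v_max`` is the subject's maximum volitional torque magnitude.
    """

    A_TA_min: float = 15.0
    A_TA_max: float = 40.0
    A_Sol_min: float = 15.0
    A_Sol_max: float = 40.0
    onset_TA: float = 10.0
    pain_TA: float = 50.0
    onset_Sol: float = 10.0
    pain_Sol: float = 50.0
    tau_ref_max_neg: float = 25.0  # Nm, magnitude
    tau_ref_max_pos: float = 25.0  # Nm
    tau_v_max: float = 40.0  # Nm

    def __post_init__(self) -> None:
        for lo, hi, onset, pain, name in (
            (self.A_TA_min, self.A_TA_max, self.onset_TA, self.pain_TA, "TA"),
            (self.A_Sol_min, self.A_Sol_max, self.onset_Sol, self.pain_Sol, "Sol"),
        ):
            if not lo < hi:
                raise ValueError(f"A_{name}_min must be < A_{name}_max")
            if not onset <= lo <= hi <= pain:
                raise ValueError(
                    f"{name} amplitude range [{lo}, {hi}] must lie inside "
                    f"[onset {onset}, pain {pain}]"
                )
        if self.tau_v_max <= 0:
            raise ValueError("tau_v_max must be positive")
        if self.tau_ref_max_neg <= 0 or self.tau_ref_max_pos <= 0:
            raise ValueError("reference torque extrema must be positive magnitudes")


@dataclass(frozen=True)
class CoordinationOutput:
    """Per-control-step output of the coordinator."""

    A_TA: float  # mA
    A_Sol: float  # mA
    r_v: float  # dimensionless, [0, 1]
    k_d: float  # Nm/rad
    c_d: float  # Nm*s/rad


def _clamp(x: float, lo: float, hi: float) -> float:
    return min(max(x, lo), hi)


def fes_amplitudes(
    tau_ref: float, tau_v: float, calib: SubjectCalibration
) -> tuple[float, float]:
    """Stimulation amplitudes for (TA, soleus) from the torque deficit.

    The channel matching the sign of ``tau_ref`` is driven proportionally
    to the unmet fraction of the demand,

        A = (A_max - A_min) * clamp((|tau_ref| - |tau_v,same-dir|)
                                     / tau_ref_max, 0, 1) + A_min,

    while the antagonist stays at its minimum (no co-stimulation).  With
    no volitional torque the amplitude follows the reference-torque
    profile; once the wearer meets or exceeds the demand the channel drops
    to its minimum.
    """
    A_TA, A_Sol = calib.A_TA_min, calib.A_Sol_min
    if tau_ref < 0.0:
        # dorsiflexion demand -> TA; volitional dorsiflexion torque is negative
        deficit = (-tau_ref - max(-tau_v, 0.0)) / calib.tau_ref_max_neg
        A_TA = _clamp(
            (calib.A_TA_max - calib.A_TA_min) * _clamp(deficit, 0.0, 1.0)
            + calib.A_TA_min,
            calib.A_TA_min,
            calib.A_TA_max,
        )
    elif tau_ref > 0.0:
        deficit = (tau_ref - max(tau_v, 0.0)) / calib.tau_ref_max_pos
        A_Sol = _clamp(
            (calib.A_Sol_max - calib.A_Sol_min) * _clamp(deficit, 0.0, 1.0)
            + calib.A_Sol_min,
            calib.A_Sol_min,
            calib.A_Sol_max,
        )
    if A_TA > calib.pain_TA or A_Sol > calib.pain_Sol:
        raise StimulationRangeError("commanded amplitude exceeds pain threshold")
    return A_TA, A_Sol


def activation_ratio(tau_ref: float, tau_v: float, tau_v_max: float) -> float:
    """Wearer's normalized share of the demanded joint torque.

    Magnitudes are compared.  When the volitional torque meets or exceeds
    the reference, the ratio is ``max(|tau_ref|, |tau_v|) / tau_v_max``
    clamped to [0, 1]; when the wearer falls short of the reference the
    ratio is 0 so the gait is fully assisted.
    """
    if tau_v_max <= 0:
        raise ValueError("tau_v_max must be positive")
    if abs(tau_v) >= abs(tau_ref):
        return _clamp(max(abs(tau_ref), abs(tau_v)) / tau_v_max, 0.0, 1.0)
    return 0.0


def desired_stiffness(
    k_ref: float,
    r_v: float,
    k_min: float = K_MIN_DEFAULT,
    k_max: float = K_MAX_DEFAULT,
    k_ref_max: float | None = None,
) -> float:
    """Rendered orthosis stiffness, reduced by the wearer's participation.

        k_d = clamp(k_max * (k_ref - r_v * k_ref_max) / k_ref_max + k_min,
                    k_min, k_max)

    ``k_ref_max`` defaults to ``k_ref`` scaled as its own maximum only when
    given; callers normally pass the maximum of the reference-stiffness
    table.  Non-increasing in ``r_v`` at fixed ``k_ref``.
    """
    if not 0.0 <= r_v <= 1.0:
        raise ValueError("r_v must be in [0, 1]")
    if k_ref < 0:
        raise ValueError("k_ref must be nonnegative")
    if k_ref_max is None:
        k_ref_max = max(k_ref, 1e-12)
    if k_ref_max <= 0:
        raise ValueError("k_ref_max must be positive")
    raw = k_max * (k_ref - r_v * k_ref_max) / k_ref_max + k_min
    return _clamp(raw, k_min, k_max)


def desired_damping(
    k_d: float,
    zeta: float = ZETA_DEFAULT,
    mode: str = "literal",
    inertia: float | None = None,
) -> float:
    """Rendered damping from the stiffness and damping ratio.

    ``literal`` mode scales stiffness directly, ``c_d = 2 zeta k_d``;
    ``critical`` mode uses the second-order relation
    ``c_d = 2 zeta sqrt(I k_d)`` (requires the joint inertia).
    """
    if k_d < 0 or zeta < 0:
        raise ValueError("k_d and zeta must be nonnegative")
    if mode == "literal":
        return 2.0 * zeta * k_d
    if mode == "critical":
        if inertia is None or inertia <= 0:
            raise ValueError("critical mode needs a positive inertia")
        return 2.0 * zeta * (inertia * k_d) ** 0.5
    raise ValueError(f"unknown damping mode {mode!r}")


def coordinate(
    tau_ref: float,
    tau_v: float,
    k_ref: float,
    k_ref_max: float,
    calib: SubjectCalibration,
    k_min: float = K_MIN_DEFAULT,
    k_max: float = K_MAX_DEFAULT,
    zeta: float = ZETA_DEFAULT,
    damping_mode: str = "literal",
    inertia: float | None = None,
) -> CoordinationOutput:
    """One full coordination step: amplitudes, ratio, stiffness, damping."""
    A_TA, A_Sol = fes_amplitudes(tau_ref, tau_v, calib)
    r_v = activation_ratio(tau_ref, tau_v, calib.tau_v_max)
    k_d = desired_stiffness(k_ref, r_v, k_min, k_max, k_ref_max)
    c_d = desired_damping(k_d, zeta, damping_mode, inertia)
    return CoordinationOutput(A_TA=A_TA, A_Sol=A_Sol, r_v=r_v, k_d=k_d, c_d=c_d)
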