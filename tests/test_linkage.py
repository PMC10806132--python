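"""Orthosis linkage kinematics, torque resolution and control laws."""

import math

import numpy as np
import pytest

from hybridgait.linkage import (
    ImpedanceSetpoint,
    IntegrationDivergedError,
    LinkageDomainError,
    LinkageGeometry,
    PDGains,
    UnreachableAngleError,
    actuator_torque,
    ankle_angle_from_screw,
    desired_angle_step,
    external_torque,
    gravity_torque,
    impedance_torque,
    pd_control,
    screw_from_ankle_angle,
)

GEOM = LinkageGeometry()


def triangle_angle_at_A(a_len: float, b_len: float, c_len: float) -> float:
    """Angle at vertex A of a triangle with |AB|=a_len, |AC|=b_len, |BC|=c_len,
    found by explicit coordinate construction (independent of the law of
    cosines as written in the kinematic formula)."""
    B = np.array([a_len, 0.0])
    cx = (a_len**2 + b_len**2 - c_len**2) / (2.0 * a_len)
    cy = math.sqrt(max(b_len**2 - cx**2, 0.0))
    C = np.array([cx, cy])
    return math.atan2(C[1], C[0])


class TestForwardKinematics:
    def test_right_angle_configuration(self):
        # l1^2 + l2^2 = lscrew^2 + lR3^2 makes the cosine argument zero
        geom = LinkageGeometry(
            l1=0.20, l2=0.10, lR3=0.05, theta_P1=0.0,
            screw_travel_limits=(0.05, 0.30),
        )
        lscrew = math.sqrt(geom.l1**2 + geom.l2**2 - geom.lR3**2)
        assert ankle_angle_from_screw(geom, lscrew) == pytest.approx(math.pi / 2)

    def test_matches_triangle_construction_oracle(self):
        for lscrew in np.linspace(0.21, 0.29, 25):
            l3 = math.hypot(lscrew, GEOM.lR3)
            expected = triangle_angle_at_A(GEOM.l1, GEOM.l2, l3) + GEOM.theta_P1
            assert ankle_angle_from_screw(GEOM, lscrew) == pytest.approx(
                expected, abs=1e-9
            )

    def test_degenerate_aligned_linkage(self):
        # argument exactly 1 -> arccos 0 -> theta = theta_P1
        geom = LinkageGeometry(
            l1=0.20, l2=0.10, lR3=0.05, theta_P1=0.35,
            screw_travel_limits=(0.05, 0.30),
        )
        lscrew = math.sqrt((geom.l1 - geom.l2) ** 2 - geom.lR3**2)
        assert ankle_angle_from_screw(geom, lscrew) == pytest.approx(geom.theta_P1)

    def test_travel_limit_enforced(self):
        with pytest.raises(LinkageDomainError):
            ankle_angle_from_screw(GEOM, 0.35)


class TestInverseKinematics:
    def test_arccos_zero_inversion(self):
        geom = LinkageGeometry(
            l1=0.20, l2=0.10, lR3=0.05, theta_P1=0.1,
            screw_travel_limits=(0.05, 0.30),
        )
        expected = math.sqrt(geom.l1**2 + geom.l2**2 - geom.lR3**2)
        assert screw_from_ankle_angle(geom, math.pi / 2 + geom.theta_P1) == (
            pytest.approx(expected, abs=1e-12)
        )

    def test_round_trip_identity_over_grid(self):
        lo = ankle_angle_from_screw(GEOM, GEOM.screw_travel_limits[0] + 1e-6)
        hi = ankle_angle_from_screw(GEOM, GEOM.screw_travel_limits[1] - 1e-6)
        for theta in np.linspace(lo, hi, 100):
            back = ankle_angle_from_screw(GEOM, screw_from_ankle_angle(GEOM, theta))
            assert abs(back - theta) < 1e-9

    def test_matches_bisection_oracle(self, rng):
        lo, hi = GEOM.screw_travel_limits
        for _ in range(20):
            lscrew_true = rng.uniform(lo + 1e-4, hi - 1e-4)
            theta = ankle_angle_from_screw(GEOM, lscrew_true)
            # 1-D root bracketing on the forward map (increasing in lscrew)
            a, b = lo, hi
            for _ in range(60):
                mid = 0.5 * (a + b)
                if ankle_angle_from_screw(GEOM, mid) < theta:
                    a = mid
                else:
                    b = mid
            oracle = 0.5 * (a + b)
            assert screw_from_ankle_angle(GEOM, theta) == pytest.approx(
                oracle, abs=1e-9
            )

    def test_unreachable_angle_rejected(self):
        with pytest.raises(UnreachableAngleError):
            screw_from_ankle_angle(GEOM, GEOM.theta_P1 - 0.5)


class TestExternalTorque:
    def test_zero_force_zero_torque(self):
        assert external_torque(GEOM, 0.25, 0.0) == 0.0

    def test_linear_in_force(self):
        tau1 = external_torque(GEOM, 0.25, 10.0)
        tau2 = external_torque(GEOM, 0.25, 20.0)
        assert tau2 == pytest.approx(2.0 * tau1, rel=1e-12)

    def test_angle_terms_match_coordinate_oracle(self):
        """The two triangle angles entering the force resolution must agree
        with an explicit coordinate construction over a configuration grid."""
        for lscrew in np.linspace(0.21, 0.29, 100):
            l3 = math.hypot(lscrew, GEOM.lR3)
            ang_R3 = triangle_angle_at_A(GEOM.l2, l3, GEOM.l1)
            ang_R2 = triangle_angle_at_A(GEOM.l1, l3, GEOM.l2)
            expected = (
                10.0
                * GEOM.l1
                * math.sin(ang_R3 + math.atan2(lscrew, GEOM.lR3) - GEOM.theta_P1)
                * math.cos(ang_R2 + math.atan2(GEOM.lR3, lscrew) - math.pi / 2)
            )
            assert external_torque(GEOM, lscrew, 10.0) == pytest.approx(
                expected, abs=1e-9
            )


class TestControlLaws:
    def test_impedance_zero_error(self):
        sp = ImpedanceSetpoint(theta_ref=0.0, k_d=100.0, c_d=5.0)
        assert impedance_torque(0.0, 0.0, sp) == 0.0

    def test_impedance_arithmetic(self):
        sp = ImpedanceSetpoint(theta_ref=0.0, k_d=100.0, c_d=5.0)
        assert impedance_torque(0.1, -0.2, sp) == pytest.approx(-9.0)

    def test_impedance_is_restoring(self):
        sp = ImpedanceSetpoint(theta_ref=0.0, k_d=80.0, c_d=2.0)
        for e in (0.05, 0.3, 1.0):
            assert impedance_torque(e, 0.0, sp) < 0
            assert impedance_torque(e, 0.0, sp) * e <= 0  # passivity

    def test_actuator_torque_subtracts_gravity_estimate(self):
        assert actuator_torque(5.0, 0.0) == 5.0
        assert actuator_torque(0.0, -2.0) == 2.0

    def test_gravity_torque_cases(self):
        assert gravity_torque(0.0, 0.1, 1.0) == 0.0
        assert gravity_torque(1.0, 0.1, 0.0) == 0.0
        assert gravity_torque(1.0, 0.1, math.pi / 2) == pytest.approx(-0.981)

    def test_pd_zero_and_proportional(self):
        g = PDGains(K_P=50.0, K_D=0.0, I=0.05)
        assert pd_control(0.0, 0.0, g) == 0.0
        assert pd_control(0.02, 0.0, g) == pytest.approx(1.0)


class TestDesiredAngleDynamics:
    SP = ImpedanceSetpoint(theta_ref=0.1, k_d=100.0, c_d=14.0)
    G = PDGains(K_P=250.0, K_D=8.0, I=0.05)

    def test_equilibrium_is_conserved(self):
        th, thd = desired_angle_step(0.1, 0.0, self.SP, 0.0, self.G, 1e-3)
        assert th == pytest.approx(0.1)
        assert thd == pytest.approx(0.0)

    def test_constant_load_converges_to_spring_deflection(self):
        tau_ext = 4.0
        th, thd = self.SP.theta_ref, 0.0
        # 50 time constants of the slow pole
        for _ in range(200_000):
            th, thd = desired_angle_step(th, thd, self.SP, tau_ext, self.G, 1e-3)
        assert th - self.SP.theta_ref == pytest.approx(
            tau_ext / self.SP.k_d, abs=1e-4
        )

    def test_step_overshoot_matches_second_order_theory(self):
        zeta = 0.7
        k_d = 100.0
        c_d = 2.0 * zeta * math.sqrt(self.G.I * k_d)
        sp = ImpedanceSetpoint(theta_ref=0.2, k_d=k_d, c_d=c_d)
        th, thd = 0.0, 0.0
        peak = 0.0
        for _ in range(50_000):
            th, thd = desired_angle_step(th, thd, sp, 0.0, self.G, 1e-4)
            peak = max(peak, th)
        overshoot = (peak - sp.theta_ref) / sp.theta_ref
        bound = math.exp(-math.pi * zeta / math.sqrt(1 - zeta**2))
        assert overshoot <= bound + 1e-3

    def test_divergence_guard(self):
        sp = ImpedanceSetpoint(theta_ref=0.0, k_d=0.0, c_d=0.0)
        with pytest.raises(IntegrationDivergedError):
            th, thd = 0.0, 0.0
            for _ in range(100_000):
                th, thd = desired_angle_step(th, thd, sp, 50.0, self.G, 1e-2)

    def test_dt_contract(self):
        with pytest.raises(ValueError):
            desired_angle_step(0.0, 0.0, self.SP, 0.0, self.G, 0.05)

    def test_tracking_error_shrinks_with_gain(self):
        """Closed loop on a simple inertial plant: steady-state error of a
        constant desired angle decreases monotonically with K_P."""
        errors = []
        for K_P in (10.0, 50.0, 250.0):
            g = PDGains(K_P=K_P, K_D=2.0 * math.sqrt(K_P * 0.05), I=0.05)
            theta, theta_dot = 0.0, 0.0
            theta_d = 0.3
            disturbance = -2.0  # constant load the controller must reject
            for _ in range(20_000):
                u = pd_control(theta - theta_d, theta_dot, g)
                acc = (-u + disturbance) / g.I
                theta_dot += 1e-3 * acc
                theta += 1e-3 * theta_dot
            errors.append(abs(theta - theta_d))
        assert errors[0] > errors[1] > errors[2]
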