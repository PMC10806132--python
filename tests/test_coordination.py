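"""Torque-sharing laws: stimulation amplitudes, activation ratio, impedance."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hybridgait.coordination import (
    CoordinationOutput,
    SubjectCalibration,
    activation_ratio,
    coordinate,
    desired_damping,
    desired_stiffness,
    fes_amplitudes,
)

CALIB = SubjectCalibration()

torques = st.floats(-60.0, 60.0, allow_nan=False)
calibs = st.builds(
    SubjectCalibration,
    A_TA_min=st.floats(11.0, 20.0),
    A_TA_max=st.floats(25.0, 45.0),
    A_Sol_min=st.floats(11.0, 20.0),
    A_Sol_max=st.floats(25.0, 45.0),
    tau_ref_max_neg=st.floats(5.0, 40.0),
    tau_ref_max_pos=st.floats(5.0, 40.0),
    tau_v_max=st.floats(10.0, 60.0),
)


class TestFesAmplitudes:
    def test_no_demand_gives_minimum_amplitudes(self):
        assert fes_amplitudes(0.0, 0.0, CALIB) == (CALIB.A_TA_min, CALIB.A_Sol_min)

    def test_full_dorsiflexion_deficit_saturates_ta(self):
        A_TA, A_Sol = fes_amplitudes(-CALIB.tau_ref_max_neg, 0.0, CALIB)
        assert A_TA == pytest.approx(CALIB.A_TA_max)
        assert A_Sol == CALIB.A_Sol_min

    def test_met_demand_drops_to_minimum(self):
        """A wearer matching the reference torque in direction and magnitude
        receives only the minimum stimulation."""
        A_TA, A_Sol = fes_amplitudes(15.0, 15.0, CALIB)
        assert (A_TA, A_Sol) == (CALIB.A_TA_min, CALIB.A_Sol_min)
        A_TA, A_Sol = fes_amplitudes(-2.0, -2.0, CALIB)
        assert (A_TA, A_Sol) == (CALIB.A_TA_min, CALIB.A_Sol_min)

    def test_zero_volition_tracks_reference_profile(self):
        """With no volitional torque the active amplitude is affine in the
        reference torque."""
        taus = np.linspace(1.0, CALIB.tau_ref_max_pos, 10)
        amps = [fes_amplitudes(tau, 0.0, CALIB)[1] for tau in taus]
        diffs = np.diff(amps)
        assert np.allclose(diffs, diffs[0])

    def test_antagonist_volition_does_not_boost_stimulation(self):
        base = fes_amplitudes(10.0, 0.0, CALIB)
        with_antagonist = fes_amplitudes(10.0, -20.0, CALIB)
        assert with_antagonist == base

    @given(tau_ref=torques, tau_v=torques, calib=calibs)
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_amplitudes_within_personal_bounds(self, tau_ref, tau_v, calib):
        A_TA, A_Sol = fes_amplitudes(tau_ref, tau_v, calib)
        assert calib.A_TA_min <= A_TA <= calib.A_TA_max
        assert calib.A_Sol_min <= A_Sol <= calib.A_Sol_max

    @given(tau_ref=torques, calib=calibs, v1=torques, v2=torques)
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_more_volition_never_more_stimulation(self, tau_ref, calib, v1, v2):
        """At fixed reference demand, growing same-direction volitional
        torque can only reduce the active channel's amplitude."""
        lo, hi = sorted((abs(v1), abs(v2)))
        sign = 1.0 if tau_ref >= 0 else -1.0
        a_lo = fes_amplitudes(tau_ref, sign * lo, calib)
        a_hi = fes_amplitudes(tau_ref, sign * hi, calib)
        assert a_hi[0] <= a_lo[0] + 1e-12
        assert a_hi[1] <= a_lo[1] + 1e-12

    @given(tau_ref=torques, tau_v=torques, calib=calibs)
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_no_co_stimulation(self, tau_ref, tau_v, calib):
        A_TA, A_Sol = fes_amplitudes(tau_ref, tau_v, calib)
        above_min = (A_TA > calib.A_TA_min + 1e-9) + (A_Sol > calib.A_Sol_min + 1e-9)
        assert above_min <= 1


class TestActivationRatio:
    def test_maximum_volition_gives_unity(self):
        assert activation_ratio(20.0, 40.0, 40.0) == 1.0

    def test_insufficient_volition_gives_zero(self):
        assert activation_ratio(20.0, 5.0, 40.0) == 0.0

    def test_ratio_arithmetic(self):
        assert activation_ratio(0.2 * 40.0, 0.5 * 40.0, 40.0) == pytest.approx(0.5)

    def test_magnitudes_compared(self):
        assert activation_ratio(-10.0, -20.0, 40.0) == pytest.approx(0.5)

    @given(tau_ref=torques, tau_v=torques, tau_v_max=st.floats(1.0, 100.0))
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_always_in_unit_interval(self, tau_ref, tau_v, tau_v_max):
        assert 0.0 <= activation_ratio(tau_ref, tau_v, tau_v_max) <= 1.0


class TestDesiredImpedance:
    def test_full_participation_at_max_reference_gives_minimum(self):
        assert desired_stiffness(300.0, 1.0, k_ref_max=300.0) == 5.0

    def test_no_participation_at_max_reference_clamps_to_maximum(self):
        # raw value k_max + k_min exceeds the band and clamps
        assert desired_stiffness(300.0, 0.0, k_ref_max=300.0) == 150.0

    def test_negative_preclamp_clamps_to_minimum(self):
        assert desired_stiffness(0.0, 1.0, k_ref_max=300.0) == 5.0

    @given(
        k_ref=st.floats(0.0, 400.0),
        r1=st.floats(0.0, 1.0),
        r2=st.floats(0.0, 1.0),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_stiffness_non_increasing_in_participation(self, k_ref, r1, r2):
        lo, hi = sorted((r1, r2))
        assert desired_stiffness(k_ref, hi, k_ref_max=400.0) <= desired_stiffness(
            k_ref, lo, k_ref_max=400.0
        )

    def test_damping_zero_stiffness(self):
        assert desired_damping(0.0, 0.7, "literal") == 0.0
        assert desired_damping(0.0, 0.7, "critical", inertia=0.05) == 0.0

    def test_damping_literal_arithmetic(self):
        assert desired_damping(100.0, 0.7, "literal") == pytest.approx(140.0)

    def test_damping_critical_closed_form(self):
        assert desired_damping(100.0, 0.7, "critical", inertia=0.05) == (
            pytest.approx(2 * 0.7 * math.sqrt(5.0))
        )


class TestCoordinate:
    def test_full_step_output_consistent(self):
        out = coordinate(10.0, 4.0, 120.0, 300.0, CALIB)
        assert isinstance(out, CoordinationOutput)
        assert out.r_v == 0.0  # volition below demand
        assert out.A_Sol > CALIB.A_Sol_min
        assert out.A_TA == CALIB.A_TA_min
        assert out.c_d == pytest.approx(2 * 0.7 * out.k_d)

    @given(tau_ref=torques, tau_v=torques, k_ref=st.floats(0, 400), calib=calibs)
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_all_outputs_within_bounds(self, tau_ref, tau_v, k_ref, calib):
        out = coordinate(tau_ref, tau_v, k_ref, 400.0, calib)
        assert 0.0 <= out.r_v <= 1.0
        assert calib.A_TA_min <= out.A_TA <= calib.A_TA_max
        assert calib.A_Sol_min <= out.A_Sol <= calib.A_Sol_max
        assert 5.0 <= out.k_d <= 150.0
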