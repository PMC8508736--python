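"""Activation closed forms, blood flow/volume, transport flux laws."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from musclesim.graph import ModularModel, ModuleDef, flatten
from musclesim.physiology import (ActivationParams, BloodCompartment,
                                  activation, blood_flow, blood_rhs,
                                  facilitated_flux, FiberVolumes,
                                  muscle_volume, passive_flux)


class TestActivation:
    def test_no_exercise_leaves_baseline(self):
        p = ActivationParams(alpha=0.004, tau=0.4)
        assert activation(37.0, 0.0, p) == 1.0

    def test_equals_one_at_onset(self):
        p = ActivationParams(alpha=0.004, tau=0.4, t_start=5.0)
        assert activation(5.0, 250.0, p) == 1.0

    def test_long_time_limit_is_one_plus_alpha_W(self):
        p = ActivationParams(alpha=0.004, tau=0.4)
        assert activation(1e3, 250.0, p) == pytest.approx(2.0, rel=1e-12)

    def test_monotone_rise_with_time(self):
        p = ActivationParams(alpha=0.01, tau=1.0)
        vals = [activation(t, 100.0, p) for t in np.linspace(0, 10, 50)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_one_time_constant_covers_1_minus_1_over_e(self):
        p = ActivationParams(alpha=0.01, tau=0.4, t_start=2.0)
        a_inf = 1 + 0.01 * 100
        expected = 1 + (1 - math.exp(-1)) * (a_inf - 1)
        assert activation(2.4, 100.0, p) == pytest.approx(expected, rel=1e-12)


class TestBloodFlowAndVolume:
    def test_resting_flow_is_q0(self):
        assert blood_flow(10.0, 0.0) == pytest.approx(0.9)

    def test_flow_equals_q0_at_onset(self):
        assert blood_flow(0.0, 200.0) == pytest.approx(0.9)

    def test_step_response_reaches_1_minus_1_over_e_at_tau(self):
        b = BloodCompartment()
        Q_inf = b.Q0 * (1 + b.alpha_Q * 150.0)
        Q_tau = blood_flow(0.4, 150.0, b)
        assert Q_tau - b.Q0 == pytest.approx(
            (1 - math.exp(-1)) * (Q_inf - b.Q0), rel=1e-12)

    def test_muscle_volume_rest_value(self):
        assert muscle_volume(5.0, 0.0) == pytest.approx(5.0)

    def test_volume_partitions(self):
        b = BloodCompartment()
        assert b.V_bl0 == pytest.approx(0.2 * b.V_mus0)
        assert b.V_tis0 == pytest.approx(0.8 * b.V_mus0)
        fv = FiberVolumes()
        assert fv.V_cyt_R + fv.V_mit_R == pytest.approx(fv.V_R)
        assert fv.V_cyt_W + fv.V_mit_W == pytest.approx(fv.V_W)
        assert fv.V_R == fv.V_W == 2.0


class TestTransportFluxes:
    def test_passive_zero_at_equal_concentrations(self):
        assert passive_flux(3.0, 3.0, 1.5, 2.0) == 0.0

    def test_passive_direct_evaluation(self):
        assert passive_flux(2.0, 1.0, 1.0, 1.0) == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(0, 50), st.floats(0, 50), st.floats(0.01, 10),
           st.floats(0.5, 3))
    def test_passive_antisymmetry(self, ca, cb, lam, act):
        assert passive_flux(ca, cb, lam, act) == pytest.approx(
            -passive_flux(cb, ca, lam, act), rel=1e-12, abs=1e-12)

    def test_facilitated_zero_at_equal_concentrations(self):
        assert facilitated_flux(2.0, 2.0, 5.0, 1.0) == 0.0

    def test_facilitated_half_saturation_point(self):
        assert facilitated_flux(1.0, 0.0, 10.0, 1.0) == pytest.approx(5.0)

    def test_facilitated_saturation_limit(self):
        assert facilitated_flux(1e9, 0.0, 10.0, 1.0) == pytest.approx(
            10.0, rel=1e-6)

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(0, 1e3), st.floats(0, 1e3), st.floats(0.1, 20),
           st.floats(0.01, 10), st.floats(0.5, 4))
    def test_facilitated_flux_is_bounded_by_rmax(self, ca, cb, rmax, km, act):
        assert abs(facilitated_flux(ca, cb, rmax, km, act)) <= rmax * act


class TestBloodMassBalance:
    def test_equilibrium_gives_zero_derivative(self):
        assert blood_rhs(2.0, 2.0, 0.9, 0.0, 0.0, 1.0, 2.0, 2.0) == 0.0

    def test_direct_evaluation_of_arterial_term(self):
        assert blood_rhs(0.0, 1.0, 0.9, 0.0, 0.0, 1.0, 2.0, 2.0) == \
            pytest.approx(0.9)

    def test_closed_two_compartment_system_conserves_mass(self):
        """Blood + one cytosol with passive exchange only and Q = 0: the
        volume-weighted total amount is a conserved quantity."""
        blood = ModuleDef("blood")
        blood.add_variable("V_bl", 1.0, dynamic=False)
        blood.add_variable("C_bl", 5.0, compartment="V_bl")
        blood.add_port("C_bl", "contact")
        tissue = ModuleDef("tissue")
        tissue.add_variable("V_cyt", 1.76, dynamic=False)
        tissue.add_variable("C_bl", None)
        tissue.add_variable("C_cyt", 1.0, compartment="V_cyt")
        tissue.add_reaction("T", {"C_bl": -1, "C_cyt": 1},
                            "0.8 * (C_bl - C_cyt) * 2.0")
        tissue.add_port("C_bl", "contact")
        model = ModularModel("closed")
        model.add_module(blood)
        model.add_module(tissue)
        model.connect(("blood", "C_bl"), ("tissue", "C_bl"), directed=False)
        flat = flatten(model)
        t, Y, idx = flat.integrate(np.linspace(0, 20, 41), rtol=1e-10,
                                   atol=1e-12)
        total = 1.0 * Y[idx["C_bl"]] + 1.76 * Y[idx["C_cyt"]]
        np.testing.assert_allclose(total, total[0], rtol=1e-8)
        # and the two concentrations equilibrate
        assert Y[idx["C_bl"]][-1] == pytest.approx(Y[idx["C_cyt"]][-1],
                                                   rel=1e-4)
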