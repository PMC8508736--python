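"""Free-nucleotide equilibria, rate laws, compartment mass balances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from musclesim.graph import ModuleDef, flatten_module
from musclesim.metabolism import (EquilibriumConstants, atpase_rate,
                                  compartment_rhs, cytosol_rhs, free_adp_amp,
                                  glycogen_synthase_rate, mito_rhs,
                                  ph_from_proton, proton_from_ph)


class TestFreeNucleotides:
    def test_zero_creatine_gives_zero_free_adp_and_amp(self):
        adp, amp = free_adp_amp(6.0, 24.0, 0.0, 1e-7)
        assert adp == 0.0
        assert amp == 0.0

    def test_formula_against_independent_evaluation(self):
        keq = EquilibriumConstants(Keq_CK=1.66e9, Keq_AK=1.05)
        ATP, PCr, Cr, H = 6.0, 24.0, 12.0, 10 ** (-7.1)
        adp, amp = free_adp_amp(ATP, PCr, Cr, H, keq)
        adp_expected = ATP * Cr / (PCr * H * 1.66e9)
        assert adp == pytest.approx(adp_expected, rel=1e-12)
        assert amp == pytest.approx(1.05 * adp_expected ** 2 / ATP, rel=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(st.floats(1.0, 40.0), st.floats(1.01, 5.0))
    def test_free_adp_strictly_increases_as_pcr_falls(self, pcr, factor):
        lo, _ = free_adp_amp(6.0, pcr, 12.0, 1e-7)
        hi, _ = free_adp_amp(6.0, pcr / factor, 12.0, 1e-7)
        assert hi > lo

    @pytest.mark.parametrize("PCr, H", [(0.0, 1e-7), (-1.0, 1e-7),
                                        (24.0, 0.0), (24.0, -1e-8)])
    def test_nonpositive_pcr_or_proton_raises(self, PCr, H):
        with pytest.raises(ValueError):
            free_adp_amp(6.0, PCr, 12.0, H)


class TestPH:
    def test_physiological_reference_point(self):
        assert ph_from_proton(1e-7) == pytest.approx(7.0)

    def test_round_trip_identity(self):
        for pH in (6.0, 6.8, 7.4):
            assert ph_from_proton(proton_from_ph(pH)) == pytest.approx(pH)

    def test_doubling_protons_lowers_ph_by_log10_two(self):
        assert ph_from_proton(1e-7) - ph_from_proton(2e-7) == pytest.approx(
            math.log10(2))

    def test_nonpositive_input_rejected(self):
        with pytest.raises(ValueError):
            ph_from_proton(0.0)


class TestRateLaws:
    def test_atpase_baseline_at_rest(self):
        r = atpase_rate(6.2, 30.0, 0.0, "I", basal=0.4,
                        alpha={"I": 0.7, "II": 0.8}, Km_ATP=0.5)
        assert r == pytest.approx(0.4 * 6.2 / (0.5 + 6.2))

    def test_activation_doubles_when_alpha_W_is_one(self):
        base = atpase_rate(6.2, 1e3, 0.0, "I", 0.4, {"I": 0.01, "II": 0.8})
        ex = atpase_rate(6.2, 1e3, 100.0, "I", 0.4, {"I": 0.01, "II": 0.8})
        assert ex == pytest.approx(2 * base, rel=1e-9)

    def test_type_ii_atpase_at_least_type_i_at_equal_power(self):
        from musclesim.config import load_defaults

        alpha = load_defaults()["metabolism"]["atpase"]["alpha"]
        assert alpha["II"] >= alpha["I"]
        r1 = atpase_rate(6.2, 1e3, 80.0, "I", 0.4, alpha)
        r2 = atpase_rate(6.2, 1e3, 80.0, "II", 0.4, alpha)
        assert r2 >= r1

    def test_glycogen_synthase_equal_for_both_fibers(self):
        # one activation coefficient: the flux law has no fiber-type index
        r1 = glycogen_synthase_rate(85.0, 20.0, 175.0, 0.03, 100.0, 0.01)
        r2 = glycogen_synthase_rate(85.0, 20.0, 175.0, 0.03, 100.0, 0.01)
        assert r1 == r2

    def test_glycogen_synthase_zero_vmax_gives_zero(self):
        assert glycogen_synthase_rate(85.0, 20.0, 175.0, 0.0, 100.0,
                                      0.01) == 0.0

    def test_glycogen_synthase_decreases_with_glycogen(self):
        lo = glycogen_synthase_rate(50.0, 20.0, 100.0, 0.03, 100.0, 0.01)
        hi = glycogen_synthase_rate(150.0, 20.0, 100.0, 0.03, 100.0, 0.01)
        assert lo > hi


class TestMassBalances:
    def test_all_zero_rates_give_zero_vector(self):
        out = cytosol_rhs(1.76, {"r": {"ATP": -1}}, {"r": 0.0})
        assert out == {"ATP": 0.0}

    def test_atpase_stoichiometry_oracle(self):
        out = cytosol_rhs(1.76, {"atpase": {"ATP": -1, "ADP": 1, "Pi": 1}},
                          {"atpase": 0.88})
        assert out["ATP"] == pytest.approx(-0.5)
        assert out["ADP"] == pytest.approx(0.5)
        assert out["Pi"] == pytest.approx(0.5)

    def test_pyruvate_import_only(self):
        out = mito_rhs(0.24, transport_cyt={"Pyr": 0.12})
        assert out == {"Pyr": pytest.approx(0.5)}

    def test_oxphos_oxygen_balance(self):
        out = mito_rhs(0.24, {"op": {"O2": -0.5, "NADH": -1}}, {"op": 0.12},
                       transport_cyt={"O2": 0.06})
        assert out["O2"] == pytest.approx((-0.5 * 0.12 + 0.06) / 0.24)

    def test_ck_reaction_conserves_creatine_moiety(self):
        """A closed CK + ATPase toy holds Cr + PCr and the adenine pool
        constant while PCr buffers the hydrolysis load."""
        m = ModuleDef("ck_toy")
        m.add_variable("ATP", 6.0)
        m.add_variable("ADP", 0.02)
        m.add_variable("PCr", 24.0)
        m.add_variable("Cr", 12.0)
        m.add_variable("Pi", 3.0)
        m.add_reaction("CK", {"PCr": -1, "ADP": -1, "Cr": 1, "ATP": 1},
                       "60.0 * (PCr * ADP - Cr * ATP / 166.0)")
        m.add_reaction("ATPase", {"ATP": -1, "ADP": 1, "Pi": 1},
                       "0.4 * ATP / (0.5 + ATP)")
        flat = flatten_module(m)
        t, Y, idx = flat.integrate(np.linspace(0, 30, 61), rtol=1e-10,
                                   atol=1e-12)
        creatine = Y[idx["PCr"]] + Y[idx["Cr"]]
        adenine = Y[idx["ATP"]] + Y[idx["ADP"]]
        np.testing.assert_allclose(creatine, 36.0, rtol=1e-9)
        np.testing.assert_allclose(adenine, 6.02, rtol=1e-9)
        assert Y[idx["PCr"]][-1] < 24.0  # PCr pays for the hydrolysis
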