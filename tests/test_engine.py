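"""Integrated-model behavior: structure, resting state, exercise responses,
conservation, solver quality."""

import numpy as np
import pytest

from musclesim.config import deep_merge, load_defaults
from musclesim.engine import (FIBERS, build_flat_model, build_model,
                              find_rest_state, recruitment_from_config,
                              simulate)
from musclesim.graph import ode_count, validate
from musclesim.physiology import BLOOD_SPECIES
from musclesim.protocols import (FatigueModel, FiberLoad, continuous_protocol,
                                 interval_protocol, ramp_protocol)


# ---------------------------------------------------------------------------
# structure


def test_default_model_validates_cleanly(cfg):
    assert validate(build_model(cfg)) == []


def test_fiber_modules_are_structurally_identical(cfg):
    model = build_model(cfg)
    for stem in ("Cytosol", "Mitochondria", "Fiber_Transport", "Signaling",
                 "Gene_Expression", "Cytosol_Capillary_Transport"):
        m1 = model.modules[f"{stem}_I"]
        m2 = model.modules[f"{stem}_II"]
        strip = lambda s: s.replace("_II", "_f").replace("_I", "_f")
        assert sorted(strip(v) for v in m1.variables) == \
            sorted(strip(v) for v in m2.variables)
        assert len(m1.reactions) == len(m2.reactions)
        assert len(m1.rate_rules) == len(m2.rate_rules)


def test_each_blood_species_is_one_flat_variable_shared_by_three_modules(flat):
    for sp in BLOOD_SPECIES:
        name = f"{sp}_b"
        assert name in flat.variables
        owners = {q.split(".")[0] for q in flat.provenance[name]}
        assert owners == {"Capillary_Blood_Flow",
                          "Cytosol_Capillary_Transport_I",
                          "Cytosol_Capillary_Transport_II"}


def test_flat_model_is_a_closed_symbol_table(flat):
    # every ODE corresponds to a distinct dynamic state
    assert ode_count(flat) == len(flat.state_names()) > 100


# ---------------------------------------------------------------------------
# resting steady state


def test_resting_derivatives_vanish_after_equilibration(flat, rest):
    y, idx = rest
    zero = lambda t: 0.0
    rhs, _, _ = flat.compile({"W_tot": zero, "W_I": zero, "W_II": zero})
    d = np.abs(np.asarray(rhs(0.0, y)))
    assert d.max() < 1e-6


def test_resting_state_is_physiological(flat, rest):
    y, idx = rest
    for f in FIBERS:
        assert 5.5 < y[idx[f"ATP_c_{f}"]] < 6.5
        assert 20.0 < y[idx[f"PCr_c_{f}"]] < 35.0
        pH = -np.log10(y[idx[f"H_c_{f}"]])
        assert 6.8 < pH < 7.45
    assert all(y > -1e-12)


# ---------------------------------------------------------------------------
# exercise responses


def test_moderate_exercise_direction_checks(sim70, rest):
    """At 70% VO2max: PCr falls, lactate rises, pH falls, ATP is nearly
    constant (the classic pattern of moderate aerobic exercise)."""
    d = sim70.data
    t = sim70.time
    i0, i1 = np.argmin(np.abs(t - 9.9)), np.argmin(np.abs(t - 40.0))
    for f in FIBERS:
        assert d[f"PCr_c_{f}"].iloc[i1] < 0.9 * d[f"PCr_c_{f}"].iloc[i0]
        assert d[f"Lac_c_{f}"].iloc[i1] > 1.5 * d[f"Lac_c_{f}"].iloc[i0]
        assert d[f"pH_c_{f}"].iloc[i1] < d[f"pH_c_{f}"].iloc[i0]
        atp_rel = abs(d[f"ATP_c_{f}"].iloc[i1] / d[f"ATP_c_{f}"].iloc[i0] - 1)
        assert atp_rel < 0.02
    # type II works closer to its glycolytic limit than type I
    assert d["Lac_c_II"].iloc[i1] > d["Lac_c_I"].iloc[i1]
    assert d["pH_c_II"].iloc[i1] < d["pH_c_I"].iloc[i1]


def test_ph_stays_in_physiological_range(sim70):
    for f in FIBERS:
        pH = sim70.data[f"pH_c_{f}"].to_numpy()
        assert pH.min() > 6.0
        assert pH.max() < 7.45


def test_no_state_goes_negative_on_moderate_exercise(sim70, flat):
    states = flat.state_names()
    values = sim70.data[states].to_numpy()
    assert values.min() > -1e-8


def test_phospho_fractions_stay_in_unit_interval(sim70, sim70_genes):
    for res in (sim70, sim70_genes):
        for f in FIBERS:
            for c in (f"CaMKIIp_{f}", f"CREBp_{f}", f"CRTC_{f}",
                      f"p_a2b2g3_{f}", f"p_a2b2g1_{f}", f"p_a1b2g1_{f}"):
                v = res.data[c].to_numpy()
                assert v.min() >= 0.0
                assert v.max() <= 1.0


def test_intensity_monotonicity_of_phospho_fractions(rest, sim50, sim70):
    """Steady phosphorylation of CaMKII, the gamma3 heterotrimer and CREB1
    is non-decreasing across rest, 50% and 70% VO2max."""
    y, idx = rest
    t50, t70 = sim50.time, sim70.time
    i50 = np.argmin(np.abs(t50 - 40.0))
    i70 = np.argmin(np.abs(t70 - 40.0))
    for f in FIBERS:
        for c in (f"CaMKIIp_{f}", f"p_a2b2g3_{f}", f"CREBp_{f}"):
            v_rest = y[idx[c]]
            v50 = sim50.data[c].iloc[i50]
            v70 = sim70.data[c].iloc[i70]
            assert v_rest <= v50 + 1e-9
            assert v50 <= v70 + 1e-9


def test_signaling_relaxes_to_baseline_within_an_hour(sim70_genes):
    d = sim70_genes.data
    t = sim70_genes.time
    i_rest = 0
    i_post = np.argmin(np.abs(t - 130.0))  # one hour after exercise end
    for c in ("CaMKIIp_I", "CREBp_I", "CRTC_I", "p_a2b2g3_I", "p_a2b2g3_II"):
        assert abs(d[c].iloc[i_post] - d[c].iloc[i_rest]) < 0.01


def test_net_glycogen_breakdown_during_exercise(sim70):
    d = sim70.data
    t = sim70.time
    sel = (t > 15) & (t < 40)
    for f in FIBERS:
        gp = d[f"v_GP_{f}"].to_numpy()[sel]
        gs = d[f"v_GS_{f}"].to_numpy()[sel]
        assert np.all(gs < gp)
        i0 = np.argmin(np.abs(t - 9.9))
        i1 = np.argmin(np.abs(t - 40.0))
        assert d[f"GLY_c_{f}"].iloc[i1] < d[f"GLY_c_{f}"].iloc[i0]


def test_glycogen_synthase_activation_identical_across_fibers(sim70):
    """Glycogen synthesis carries one activation coefficient for both fiber
    types: the activation trajectories coincide exactly, and at rest (where
    the fiber states coincide) so do the fluxes."""
    d = sim70.data
    np.testing.assert_allclose(d["a_gs_I"].to_numpy(),
                               d["a_gs_II"].to_numpy(), rtol=1e-9)
    at_rest = sim70.time <= 9.9
    np.testing.assert_allclose(d["v_GS_I"].to_numpy()[at_rest],
                               d["v_GS_II"].to_numpy()[at_rest], rtol=0.01)


def test_creatine_and_coa_moieties_are_conserved(sim70, cfg):
    d = sim70.data
    for f in FIBERS:
        cr_tot = d[f"PCr_c_{f}"] + d[f"Cr_c_{f}"]
        np.testing.assert_allclose(cr_tot, cr_tot.iloc[0], rtol=1e-7)
    V = {"cyt_I": 1.76, "mit_I": 0.24, "cyt_II": 1.84, "mit_II": 0.16}
    for f in FIBERS:
        coa = (V[f"cyt_{f}"] * (d[f"CoA_c_{f}"] + d[f"FAC_c_{f}"])
               + V[f"mit_{f}"] * (d[f"CoA_m_{f}"] + d[f"FAC_m_{f}"]
                                  + d[f"ACoA_m_{f}"]))
        np.testing.assert_allclose(coa, coa.iloc[0], rtol=1e-6)


def test_mass_conservation_in_closed_configuration(cfg):
    """With blood flow off and every reaction silenced, transport merely
    moves matter between compartments: the volume-weighted total of each
    exchanged species is invariant."""
    closed = deep_merge(cfg, {
        "physiology": {"Q0": 0.0},
        "metabolism": {
            "atpase": {"basal": 0.0}, "glycogen_phosphorylase": {"vmax": 0.0},
            "glycogen_synthase": {"vmax": 0.0}, "hexokinase": {"vmax": 0.0},
            "glycolysis": {"vmax": 0.0}, "ldh": {"kf": 0.0},
            "alt": {"kf": 0.0}, "lipolysis": {"vmax": 0.0},
            "fa_activation": {"vmax": 0.0}, "ck": {"k": 0.0},
            "pdh": {"vmax": 0.0}, "tca": {"vmax": 0.0},
            "beta_ox": {"vmax": 0.0}, "oxphos": {"vmax": 0.0},
        },
    })
    flat = build_flat_model(closed)
    zero = lambda t: 0.0
    rhs, y0, idx = flat.compile({"W_tot": zero, "W_I": zero, "W_II": zero})
    from scipy.integrate import solve_ivp

    sol = solve_ivp(rhs, (0, 60), y0, t_eval=np.linspace(0, 60, 13),
                    method="LSODA", rtol=1e-10, atol=1e-13)
    assert sol.success
    V = {"bl": 1.0, "cyt_I": 1.76, "mit_I": 0.24, "cyt_II": 1.84,
         "mit_II": 0.16}
    for sp in ("O2", "CO2", "Glc", "Lac", "Pyr", "Ala", "Glr", "FFA"):
        total = V["bl"] * sol.y[idx[f"{sp}_b"]]
        for f in FIBERS:
            total = total + V[f"cyt_{f}"] * sol.y[idx[f"{sp}_c_{f}"]]
            if f"{sp}_m_{f}" in idx:
                total = total + V[f"mit_{f}"] * sol.y[idx[f"{sp}_m_{f}"]]
        np.testing.assert_allclose(total, total[0], rtol=1e-8)


def test_interval_protocol_pcr_oscillates_once_per_bout(cfg, flat, rest,
                                                        recruitment):
    from scipy.signal import argrelextrema

    n_bouts = 6
    proto = interval_protocol(16, 32, n_bouts, 250.0, t_start=5.0)
    load = FiberLoad(proto, recruitment, FatigueModel())
    res = simulate(flat, load, cfg, proto.t_end + 3.0, y0=rest[0],
                   output_dt=0.02)
    pcr = res.data["PCr_c_II"].to_numpy()
    minima = argrelextrema(pcr, np.less, order=5)[0]
    assert len(minima) == n_bouts


def test_removing_factor_x_abolishes_delayed_response(cfg):
    """The model-variant toggle: without X translation the delayed gene
    never rises above its constitutive level."""
    ko = deep_merge(cfg, {"variants": {"x_factor_enabled": False}})
    flat = build_flat_model(ko)
    y, _ = find_rest_state(flat)
    rec = recruitment_from_config(ko)
    proto = continuous_protocol(0.7, 60.0, t_start=10.0, recruitment=rec)
    load = FiberLoad(proto, rec, FatigueModel())
    res = simulate(flat, load, ko, 70.0 + 370.0, y0=y, output_dt=1.0)
    fc = res.fold_change("PPARGC1A", "mixed")
    assert np.max(np.abs(fc - 1.0)) < 0.02
    # the early response is untouched
    assert res.fold_change("NR4A3", "mixed").max() > 5.0


# ---------------------------------------------------------------------------
# solver quality


def test_simulation_is_deterministic(cfg, flat, rest, recruitment):
    proto = continuous_protocol(0.7, 5.0, t_start=2.0, recruitment=recruitment)
    runs = []
    for _ in range(2):
        load = FiberLoad(proto, recruitment, FatigueModel())
        res = simulate(flat, load, cfg, 10.0, y0=rest[0])
        runs.append(res.data.to_csv(index=False))
    assert runs[0] == runs[1]


def test_halving_tolerances_barely_changes_the_ramp_trajectory(cfg, flat,
                                                               rest,
                                                               recruitment):
    proto = ramp_protocol(10.0, t_start=5.0, recruitment=recruitment)
    load = FiberLoad(proto, recruitment, FatigueModel())
    tight = deep_merge(cfg, {"solver": {"rtol": 5e-9, "atol": 5e-11}})
    res1 = simulate(flat, load, cfg, proto.t_end, y0=rest[0])
    res2 = simulate(flat, load, tight, proto.t_end, y0=rest[0])
    for c in ("PCr_c_I", "PCr_c_II", "Lac_c_II", "ATP_c_I"):
        a = res1.data[c].to_numpy()
        b = res2.data[c].to_numpy()
        scale = np.abs(a).max()
        assert np.max(np.abs(a - b)) / scale < 1e-3


def test_result_table_has_no_gaps_and_strictly_increasing_time(sim70):
    t = sim70.time
    assert np.all(np.diff(t) > 0)
    assert np.isfinite(sim70.data.to_numpy(dtype=float)).all()
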