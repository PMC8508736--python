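"""Model assembly and simulation.

``build_model`` constructs the integrated modular model from a
configuration: one capillary-blood module, per-fiber blood<->cytosol
transport modules, and per-fiber cytosol, mitochondria, cytosol<->mito
transport, signaling and gene-expression modules, wired through contact
ports (shared species), directed output->input connections (computed
inputs) and buses for the nine blood-exchanged species.  ``flatten`` turns
the graph into one hybrid ODE system; ``simulate`` integrates it with a
stiff solver, stopping at every protocol discontinuity, and returns a
result table with all states and derived observables.

Exercise enters through three driver functions bound at compile time —
total, type-I and type-II work rates — and every exercise-sensitive
process carries its own first-order activation state
``da/dt = ((1 + alpha * W(t)) - a) / tau``, which reproduces the
closed-form activation for a constant-W step from rest and relaxes
symmetrically when the protocol steps down.

Proton pools are buffered: acid fluxes J (mmol/min) move pH at rate
J / (beta * V) so proton states (mol/L) evolve as
dH/dt = ln(10) * H * J / (beta * V).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .config import config_hash, load_defaults
from .graph import FlatModel, ModularModel, ModuleDef, flatten
from .physiology import (BLOOD_SPECIES, FACILITATED_BLOOD_SPECIES,
                         FACILITATED_MITO_SPECIES, PASSIVE_BLOOD_SPECIES,
                         PASSIVE_MITO_SPECIES)
from .protocols import (ExerciseProtocol, FatigueModel, FiberLoad,
                        RecruitmentModel, exhaustion_time)

__all__ = [
    "build_model",
    "build_flat_model",
    "simulate",
    "find_rest_state",
    "mixed_muscle",
    "SimulationResult",
    "recruitment_from_config",
]

LN10 = 2.302585092994046

FIBERS = ("I", "II")
CYT_SPECIES = ("ATP", "PCr", "Cr", "Pi", "GLY", "Glc", "HexP", "Pyr", "Lac",
               "Ala", "Glr", "FFA", "FAC", "CoA", "O2", "CO2")
MIT_SPECIES = ("Pyr", "O2", "CO2", "Pi", "NADH", "FAC", "CoA", "ACoA")
GENE_LIST = ("NR4A3", "NR4A2", "X", "PPARGC1A")


def _mich(c: str, km: float) -> str:
    return f"({c} / ({km!r} + {c}))"


def _hill2(c: str, k: float) -> str:
    return f"({c}**2 / ({k!r}**2 + {c}**2))"


def _act_rule(name: str, alpha: float, tau: float, driver: str) -> str:
    return f"((1.0 + {alpha!r} * {driver}) - {name}) / {tau!r}"


def recruitment_from_config(cfg: Mapping) -> RecruitmentModel:
    p = cfg["protocol"]
    return RecruitmentModel(W_max=p["W_max"], theta=p["theta"],
                            cap_I=p["cap_I"], cap_II=p["cap_II"])


# ===========================================================================
# module builders


def _blood_module(cfg) -> ModuleDef:
    phys = cfg["physiology"]
    init = cfg["initial"]["blood"]
    m = ModuleDef("Capillary_Blood_Flow")
    m.add_variable("a_Q", 1.0)
    m.add_variable("a_V", 1.0)
    m.add_variable("Q", None, dynamic=False)
    m.add_variable("V_mus", None, dynamic=False)
    m.add_variable("V_bl", None, dynamic=False)
    m.add_rate_rule("a_Q", _act_rule("a_Q", phys["alpha_Q"], phys["tau_QV"], "W_tot(t)"))
    m.add_rate_rule("a_V", _act_rule("a_V", phys["alpha_V"], phys["tau_QV"], "W_tot(t)"))
    m.add_assignment("Q", f"{phys['Q0']!r} * a_Q")
    m.add_assignment("V_mus", f"{phys['V_mus0']!r} * a_V")
    m.add_assignment("V_bl", "0.2 * V_mus")
    m.add_variable("pH_b", None, dynamic=False)
    for sp in BLOOD_SPECIES:
        m.add_variable(f"{sp}_b", float(init[sp]),
                       compartment=None if sp == "H" else "V_bl")
        m.add_port(f"{sp}_b", "contact")
    m.add_assignment("pH_b", "-log10(H_b)")
    for sp in BLOOD_SPECIES:
        if sp == "H":
            continue
        m.add_reaction(
            f"arterial_{sp}", {f"{sp}_b": 1.0},
            f"Q * ({float(phys['arterial'][sp])!r} - {sp}_b)",
        )
    # acid washout by perfusion: blood pH is pulled toward arterial pH with
    # an effective carrying capacity beta_blood (bicarbonate, lumped)
    beta_bl = float(phys["beta_blood"])
    h_art = float(phys["arterial"]["H"])
    m.add_rate_rule(
        "H_b",
        f"{LN10!r} * H_b * (-(Q * {beta_bl!r} * log10(H_b / {h_art!r})))"
        f" / ({beta_bl!r} * V_bl)",
    )
    m.add_port("V_bl", "output")
    m.add_port("Q", "output")
    return m


def _transport_module(cfg, f: str) -> ModuleDef:
    tr = cfg["transport"]
    phys = cfg["physiology"]
    m = ModuleDef(f"Cytosol_Capillary_Transport_{f}")
    m.add_variable(f"V_{f}", None, dynamic=False)
    m.add_variable(f"V_cyt_{f}", None, dynamic=False)
    m.add_variable("V_bl", None, dynamic=False)
    m.add_port(f"V_{f}", "input")
    m.add_port(f"V_cyt_{f}", "input")
    m.add_port("V_bl", "input")
    a = f"a_T_{f}"
    m.add_variable(a, 1.0)
    m.add_rate_rule(a, _act_rule(a, tr["alpha"][f], tr["tau"], f"W_{f}(t)"))
    for sp in BLOOD_SPECIES:
        m.add_variable(f"{sp}_b", None)
        m.add_port(f"{sp}_b", "contact")
        m.add_variable(f"{sp}_c_{f}", None)
        m.add_port(f"{sp}_c_{f}", "contact")
    for sp in PASSIVE_BLOOD_SPECIES:
        lam = float(tr["blood_passive"][sp])
        m.add_reaction(
            f"T_bl_{sp}", {f"{sp}_b": -1.0, f"{sp}_c_{f}": 1.0},
            f"{lam!r} * ({sp}_b - {sp}_c_{f}) * {a} * V_{f}",
        )
    for sp in FACILITATED_BLOOD_SPECIES:
        p = tr["blood_facilitated"][sp]
        flux = (f"{float(p['Rmax'])!r} * ({_mich(sp + '_b', float(p['KM']))}"
                f" - {_mich(f'{sp}_c_{f}', float(p['KM']))}) * {a}")
        if sp == "H":
            beta_bl = float(phys["beta_blood"])
            beta_cyt = float(cfg["fibers"]["beta_cyt"])
            m.add_rate_rule(
                "H_b",
                f"{LN10!r} * H_b * (-({flux}) * V_{f}) / ({beta_bl!r} * V_bl)",
            )
            m.add_rate_rule(
                f"H_c_{f}",
                f"{LN10!r} * H_c_{f} * (({flux}) * V_{f}) / ({beta_cyt!r} * V_cyt_{f})",
            )
        else:
            m.add_reaction(
                f"T_bl_{sp}", {f"{sp}_b": -1.0, f"{sp}_c_{f}": 1.0},
                f"({flux}) * V_{f}",
            )
    return m


def _cytosol_module(cfg, f: str) -> ModuleDef:
    met = cfg["metabolism"]
    fib = cfg["fibers"]
    init = cfg["initial"]["cytosol"]
    V_f = 0.5 * (0.8 * cfg["physiology"]["V_mus0"])  # each fiber type: 2 kg w.w.
    V_cyt = fib["cyt_fraction"][f] * V_f
    beta = float(fib["beta_cyt"])
    m = ModuleDef(f"Cytosol_{f}")
    m.add_variable(f"V_{f}", V_f, dynamic=False)
    m.add_variable(f"V_cyt_{f}", V_cyt, dynamic=False)
    m.add_port(f"V_{f}", "output")
    m.add_port(f"V_cyt_{f}", "output")
    for sp in CYT_SPECIES:
        m.add_variable(f"{sp}_c_{f}", float(init[sp]), compartment=f"V_cyt_{f}")
        m.add_port(f"{sp}_c_{f}", "contact")
    m.add_variable(f"H_c_{f}", float(init["H"]))
    m.add_port(f"H_c_{f}", "contact")
    m.add_variable(f"pH_c_{f}", None, dynamic=False)
    m.add_assignment(f"pH_c_{f}", f"-log10(H_c_{f})")
    # metabolically active ADP: adenine pool closed over ATP + free ADP
    m.add_variable(f"ADP_c_{f}", None, dynamic=False)
    m.add_assignment(f"ADP_c_{f}", f"{float(fib['Atot'])!r} - ATP_c_{f}")
    m.add_port(f"ADP_c_{f}", "output")

    # activation states
    for name, sect, driver in (
        ("a_met", met["glycolysis"], f"W_{f}(t)"),
        ("a_atp", met["atpase"], f"W_{f}(t)"),
        ("a_lip", met["lipolysis"], f"W_{f}(t)"),
    ):
        nm = f"{name}_{f}"
        m.add_variable(nm, 1.0)
        m.add_rate_rule(nm, _act_rule(nm, sect["alpha"][f], sect["tau"], driver))
    gs = met["glycogen_synthase"]
    m.add_variable(f"a_gs_{f}", 1.0)
    # glycogen-synthase activation is identical in both fiber types and is
    # therefore driven by the total work rate
    m.add_rate_rule(f"a_gs_{f}", _act_rule(f"a_gs_{f}", gs["alpha"], gs["tau"], "W_tot(t)"))

    def S(sp):  # local species name
        return f"{sp}_c_{f}"

    rates: list[tuple[str, str, dict[str, float]]] = []
    gp = met["glycogen_phosphorylase"]
    rates.append((
        "GP",
        f"{float(gp['vmax'])!r} * a_met_{f} * {_mich(S('GLY'), float(gp['K_gly']))}"
        f" * {_hill2(f'ADP_c_{f}', float(gp['K_adp']))}"
        f" * {_mich(S('Pi'), float(gp['K_pi']))} * V_{f}",
        {S("GLY"): -1, S("Pi"): -1, S("HexP"): 1},
    ))
    rates.append((
        "GS",
        f"{float(gs['vmax'])!r} * a_gs_{f} * ({float(gs['K_gly'])!r}"
        f" / ({float(gs['K_gly'])!r} + {S('GLY')}))"
        f" * {_mich(S('HexP'), 0.1)} * {_mich(S('ATP'), 0.5)} * V_{f}",
        {S("HexP"): -1, S("ATP"): -1, S("GLY"): 1, S("Pi"): 2},
    ))
    hk = met["hexokinase"]
    rates.append((
        "HK",
        f"{float(hk['vmax'])!r} * a_met_{f} * {_mich(S('Glc'), float(hk['Km_Glc']))}"
        f" * {_mich(S('ATP'), float(hk['Km_ATP']))}"
        f" * ({float(hk['K_hexp_inh'])!r} / ({float(hk['K_hexp_inh'])!r} + {S('HexP')})) * V_{f}",
        {S("Glc"): -1, S("ATP"): -1, S("HexP"): 1},
    ))
    gl = met["glycolysis"]
    rates.append((
        "GLYC",
        f"{float(gl['vmax'])!r} * a_met_{f} * {_mich(S('HexP'), float(gl['Km_HexP']))}"
        f" * {_hill2(f'ADP_c_{f}', float(gl['K_adp']))}"
        f" * {_mich(S('Pi'), float(gl['Km_Pi']))} * V_{f}",
        {S("HexP"): -1, S("Pi"): -2, S("ATP"): 3, S("Pyr"): 2},
    ))
    ldh = met["ldh"]
    rates.append((
        "LDH",
        f"{float(ldh['kf'])!r} * ({S('Pyr')} - {S('Lac')} / {float(ldh['Keq'])!r}) * V_{f}",
        {S("Pyr"): -1, S("Lac"): 1},
    ))
    alt = met["alt"]
    rates.append((
        "ALT",
        f"{float(alt['kf'])!r} * ({S('Pyr')} - {S('Ala')} / {float(alt['Keq'])!r}) * V_{f}",
        {S("Pyr"): -1, S("Ala"): 1},
    ))
    lip = met["lipolysis"]
    rates.append((
        "LIP",
        f"{float(lip['vmax'])!r} * a_lip_{f} * ({float(lip['K_ffa_inh'])!r}"
        f" / ({float(lip['K_ffa_inh'])!r} + {S('FFA')})) * V_{f}",
        {S("Glr"): 1, S("FFA"): 3},
    ))
    fa = met["fa_activation"]
    rates.append((
        "FAA",
        f"{float(fa['vmax'])!r} * {_mich(S('FFA'), float(fa['Km_FFA']))}"
        f" * {_mich(S('CoA'), float(fa['Km_CoA']))}"
        f" * {_mich(S('ATP'), float(fa['Km_ATP']))} * V_{f}",
        {S("FFA"): -1, S("CoA"): -1, S("FAC"): 1, S("ATP"): -2, S("Pi"): 2},
    ))
    ck = met["ck"]
    keq_ck = float(fib["Keq_CK"])
    rates.append((
        "CK",
        f"{float(ck['k'])!r} * ({S('PCr')} * ADP_c_{f}"
        f" - {S('Cr')} * {S('ATP')} / ({keq_ck!r} * H_c_{f})) * V_{f}",
        {S("PCr"): -1, S("Cr"): 1, S("ATP"): 1},
    ))
    at = met["atpase"]
    rates.append((
        "ATPASE",
        f"{float(at['basal'])!r} * a_atp_{f} * {_mich(S('ATP'), float(at['Km_ATP']))} * V_{f}",
        {S("ATP"): -1, S("Pi"): 1},
    ))
    for name, expr, stoich in rates:
        vname = f"v_{name}_{f}"
        m.add_variable(vname, None, dynamic=False)
        m.add_assignment(vname, expr)
        m.add_reaction(name, stoich, vname)

    # buffered proton balance: lactate formation acidifies 1:1, ATP
    # hydrolysis releases nu_H protons, net CK flux toward Cr consumes them
    m.add_rate_rule(
        f"H_c_{f}",
        f"{LN10!r} * H_c_{f} * ({float(at['nu_H'])!r} * v_ATPASE_{f}"
        f" + v_LDH_{f} - {float(ck['nu_H'])!r} * v_CK_{f})"
        f" / ({beta!r} * V_cyt_{f})",
    )
    return m


def _mito_module(cfg, f: str) -> ModuleDef:
    met = cfg["metabolism"]
    fib = cfg["fibers"]
    init = cfg["initial"]["mito"]
    V_f = 0.5 * (0.8 * cfg["physiology"]["V_mus0"])
    V_mit = (1.0 - fib["cyt_fraction"][f]) * V_f
    beta_c = float(fib["beta_cyt"])
    m = ModuleDef(f"Mitochondria_{f}")
    m.add_variable(f"V_{f}", None, dynamic=False)
    m.add_variable(f"V_cyt_{f}", None, dynamic=False)
    m.add_port(f"V_{f}", "input")
    m.add_port(f"V_cyt_{f}", "input")
    m.add_variable(f"V_mit_{f}", V_mit, dynamic=False)
    m.add_port(f"V_mit_{f}", "output")
    for sp in MIT_SPECIES:
        m.add_variable(f"{sp}_m_{f}", float(init[sp]), compartment=f"V_mit_{f}")
        m.add_port(f"{sp}_m_{f}", "contact")
    m.add_variable(f"H_m_{f}", float(init["H"]))
    m.add_port(f"H_m_{f}", "contact")
    for sp in ("ATP", "Pi"):
        m.add_variable(f"{sp}_c_{f}", None)
        m.add_port(f"{sp}_c_{f}", "contact")
    m.add_variable(f"H_c_{f}", None)
    m.add_port(f"H_c_{f}", "contact")
    m.add_variable(f"ADP_c_{f}", None, dynamic=False)
    m.add_port(f"ADP_c_{f}", "input")
    m.add_variable(f"NAD_m_{f}", None, dynamic=False)
    m.add_assignment(f"NAD_m_{f}", f"{float(fib['NADtot'])!r} - NADH_m_{f}")

    for name, sect in (("a_pdh", met["pdh"]), ("a_ox", met["oxphos"]),
                       ("a_box", met["beta_ox"])):
        nm = f"{name}_{f}"
        m.add_variable(nm, 1.0)
        m.add_rate_rule(nm, _act_rule(nm, sect["alpha"][f], sect["tau"], f"W_{f}(t)"))

    def Sm(sp):
        return f"{sp}_m_{f}"

    pdh = met["pdh"]
    tca = met["tca"]
    box = met["beta_ox"]
    op = met["oxphos"]
    rates = [
        (
            "PDH",
            f"{float(pdh['vmax'])!r} * a_pdh_{f} * {_mich(Sm('Pyr'), float(pdh['Km_Pyr']))}"
            f" * {_mich(Sm('CoA'), float(pdh['Km_CoA']))}"
            f" * {_mich(f'NAD_m_{f}', float(pdh['Km_NAD']))} * V_{f}",
            {Sm("Pyr"): -1, Sm("CoA"): -1, Sm("ACoA"): 1, Sm("CO2"): 1, Sm("NADH"): 1},
        ),
        (
            "TCA",
            f"{float(tca['vmax'])!r} * {_mich(Sm('ACoA'), float(tca['Km_ACoA']))}"
            f" * {_mich(f'NAD_m_{f}', float(tca['Km_NAD']))} * V_{f}",
            {Sm("ACoA"): -1, Sm("CoA"): 1, Sm("CO2"): 2, Sm("NADH"): 4},
        ),
        (
            "BOX",
            f"{float(box['vmax'])!r} * a_box_{f} * {_mich(Sm('FAC'), float(box['Km_FAC']))}"
            f" * {_mich(Sm('CoA'), float(box['Km_CoA']))}"
            f" * {_mich(f'NAD_m_{f}', float(box['Km_NAD']))} * V_{f}",
            {Sm("FAC"): -1, Sm("CoA"): -7, Sm("ACoA"): 8, Sm("NADH"): 14},
        ),
        (
            "OP",
            f"{float(op['vmax'])!r} * a_ox_{f} * {_mich(Sm('NADH'), float(op['Km_NADH']))}"
            f" * {_hill2(f'ADP_c_{f}', float(op['K_adp']))}"
            f" * {_mich(Sm('O2'), float(op['Km_O2']))}"
            f" * {_mich(f'Pi_c_{f}', 0.3)} * V_{f}",
            {Sm("NADH"): -1, Sm("O2"): -0.5,
             f"ATP_c_{f}": float(op["P_per_NADH"]),
             f"Pi_c_{f}": -float(op["P_per_NADH"])},
        ),
    ]
    for name, expr, stoich in rates:
        vname = f"v_{name}_{f}"
        m.add_variable(vname, None, dynamic=False)
        m.add_assignment(vname, expr)
        m.add_reaction(name, stoich, vname)
    # oxidative phosphorylation consumes cytosolic protons (lumped with the
    # mitochondrial proton circuit)
    m.add_rate_rule(
        f"H_c_{f}",
        f"{LN10!r} * H_c_{f} * (-{float(op['nu_H'])!r} * v_OP_{f}) / ({beta_c!r} * V_cyt_{f})",
    )
    return m


def _fiber_transport_module(cfg, f: str) -> ModuleDef:
    tr = cfg["transport"]
    fib = cfg["fibers"]
    m = ModuleDef(f"Fiber_Transport_{f}")
    for v in (f"V_{f}", f"V_cyt_{f}", f"V_mit_{f}"):
        m.add_variable(v, None, dynamic=False)
        m.add_port(v, "input")
    a = f"a_tm_{f}"
    m.add_variable(a, 1.0)
    m.add_rate_rule(a, _act_rule(a, tr["alpha"][f], tr["tau"], f"W_{f}(t)"))
    species = set(PASSIVE_MITO_SPECIES) | set(FACILITATED_MITO_SPECIES)
    for sp in sorted(species):
        m.add_variable(f"{sp}_c_{f}", None)
        m.add_port(f"{sp}_c_{f}", "contact")
        m.add_variable(f"{sp}_m_{f}", None)
        m.add_port(f"{sp}_m_{f}", "contact")
    for sp in PASSIVE_MITO_SPECIES:
        lam = float(tr["mito_passive"][sp])
        m.add_reaction(
            f"T_mit_{sp}", {f"{sp}_c_{f}": -1.0, f"{sp}_m_{f}": 1.0},
            f"{lam!r} * ({sp}_c_{f} - {sp}_m_{f}) * {a} * V_{f}",
        )
    for sp in FACILITATED_MITO_SPECIES:
        p = tr["mito_facilitated"][sp]
        flux = (f"{float(p['Rmax'])!r} * ({_mich(f'{sp}_c_{f}', float(p['KM']))}"
                f" - {_mich(f'{sp}_m_{f}', float(p['KM']))}) * {a}")
        if sp == "H":
            bc, bm = float(fib["beta_cyt"]), float(fib["beta_mit"])
            m.add_rate_rule(
                f"H_c_{f}",
                f"{LN10!r} * H_c_{f} * (-({flux}) * V_{f}) / ({bc!r} * V_cyt_{f})",
            )
            m.add_rate_rule(
                f"H_m_{f}",
                f"{LN10!r} * H_m_{f} * (({flux}) * V_{f}) / ({bm!r} * V_mit_{f})",
            )
        else:
            m.add_reaction(
                f"T_mit_{sp}", {f"{sp}_c_{f}": -1.0, f"{sp}_m_{f}": 1.0},
                f"({flux}) * V_{f}",
            )
    return m


def _signaling_module(cfg, f: str) -> ModuleDef:
    sig = cfg["signaling"]
    fib = cfg["fibers"]
    cap = cfg["protocol"][f"cap_{f}"]
    ca = sig["calcium"]
    m = ModuleDef(f"Signaling_{f}")
    for v in ("ATP", "PCr", "Cr"):
        m.add_variable(f"{v}_c_{f}", None)
        m.add_port(f"{v}_c_{f}", "contact")
    m.add_variable(f"H_c_{f}", None)
    m.add_port(f"H_c_{f}", "contact")

    # free nucleotides from the CK and AK near-equilibria
    m.add_variable(f"ADPfree_{f}", None, dynamic=False)
    m.add_variable(f"AMPfree_{f}", None, dynamic=False)
    m.add_assignment(
        f"ADPfree_{f}",
        f"ATP_c_{f} * Cr_c_{f} / (PCr_c_{f} * H_c_{f} * {float(fib['Keq_CK'])!r})",
    )
    m.add_assignment(
        f"AMPfree_{f}",
        f"{float(fib['Keq_AK'])!r} * ADPfree_{f}**2 / ATP_c_{f}",
    )

    m.add_variable(f"Ca_{f}", float(ca["Ca_rest"]))
    m.add_rate_rule(
        f"Ca_{f}",
        f"(({float(ca['Ca_rest'])!r} + {float(ca['Ca_slope'])!r}"
        f" * min(W_{f}(t) / {float(cap)!r}, 1.0)) - Ca_{f}) / {float(ca['tau_Ca'])!r}",
    )
    n = float(ca["n_CaM"])
    K = float(ca["K_CaM"])
    m.add_variable(f"CaCaM_{f}", None, dynamic=False)
    m.add_assignment(
        f"CaCaM_{f}", f"Ca_{f}**{n!r} / ({K!r}**{n!r} + Ca_{f}**{n!r})"
    )
    m.add_variable(f"CN_{f}", None, dynamic=False)
    m.add_assignment(f"CN_{f}",
                     f"CaCaM_{f} / ({float(sig['calcineurin']['K'])!r} + CaCaM_{f})")
    m.add_variable(f"CaMKK2_{f}", None, dynamic=False)
    m.add_assignment(f"CaMKK2_{f}",
                     f"CaCaM_{f} / ({float(sig['camkk2']['K'])!r} + CaCaM_{f})")

    cam = sig["camkii"]
    m.add_variable(f"CaMKIIp_{f}", 0.05)
    m.add_rate_rule(
        f"CaMKIIp_{f}",
        f"{float(cam['k_act'])!r} * CaCaM_{f} * (1.0 - CaMKIIp_{f})"
        f" - {float(cam['k_dp'])!r} * CaMKIIp_{f}",
    )
    crtc = sig["crtc"]
    m.add_variable(f"CRTC_{f}", 0.1)
    m.add_rate_rule(
        f"CRTC_{f}",
        f"{float(crtc['k_cn'])!r} * CN_{f} * (1.0 - CRTC_{f})"
        f" - {float(crtc['k_rp'])!r} * CRTC_{f}",
    )

    lkb1 = float(sig["lkb1_activity"])
    atp_ref = float(sig["ATP_ref"])
    act_terms = []
    for h, hp in sig["ampk"].items():
        pv = f"p_{h}_{f}"
        m.add_variable(pv, 0.05)
        kin = (f"({float(hp['k_lkb1'])!r} * {lkb1!r}"
               f" + {float(hp['k_camkk2'])!r} * CaMKK2_{f})")
        deph = (f"{float(hp['k_pp'])!r} * (ATP_c_{f} / {atp_ref!r})"
                f" / (1.0 + AMPfree_{f} / {float(hp['K_amp'])!r})")
        m.add_rate_rule(pv, f"{kin} * (1.0 - {pv}) - ({deph}) * {pv}")
        av = f"act_{h}_{f}"
        m.add_variable(av, None, dynamic=False)
        allo = (f"(1.0 + {float(hp['amp_allosteric'])!r} * AMPfree_{f}"
                f" / ({float(hp['K_amp_allosteric'])!r} + AMPfree_{f}))")
        m.add_assignment(
            av,
            f"{float(hp['total'])!r} * ({float(hp['baseline_activity'])!r}"
            f" + {float(hp['activity_scale'])!r} * {pv} * {allo})",
        )
        act_terms.append(av)
    m.add_variable(f"AMPKact_{f}", None, dynamic=False)
    m.add_assignment(f"AMPKact_{f}", " + ".join(act_terms))

    creb = sig["creb"]
    m.add_variable(f"CREBp_{f}", 0.1)
    m.add_rate_rule(
        f"CREBp_{f}",
        f"({float(creb['k_camkii'])!r} * CaMKIIp_{f}"
        f" + {float(creb['k_ampk'])!r} * AMPKact_{f}) * (1.0 - CREBp_{f})"
        f" - {float(creb['k_dp'])!r} * CREBp_{f}",
    )

    # observables: percentages of phosphorylated pools
    totals = {h: float(hp["total"]) for h, hp in sig["ampk"].items()}
    t_a2 = totals["a2b2g3"] + totals["a2b2g1"]
    m.add_variable(f"phos_g3_pct_{f}", None, dynamic=False)
    m.add_assignment(f"phos_g3_pct_{f}", f"100.0 * p_a2b2g3_{f}")
    m.add_variable(f"phos_a2_pct_{f}", None, dynamic=False)
    m.add_assignment(
        f"phos_a2_pct_{f}",
        f"100.0 * ({totals['a2b2g3']!r} * p_a2b2g3_{f}"
        f" + {totals['a2b2g1']!r} * p_a2b2g1_{f}) / {t_a2!r}",
    )
    m.add_variable(f"CaMKIIp_pct_{f}", None, dynamic=False)
    m.add_assignment(f"CaMKIIp_pct_{f}", f"100.0 * CaMKIIp_{f}")
    m.add_variable(f"CREBp_pct_{f}", None, dynamic=False)
    m.add_assignment(f"CREBp_pct_{f}", f"100.0 * CREBp_{f}")

    for out in (f"CREBp_{f}", f"CRTC_{f}", f"AMPKact_{f}"):
        m.add_port(out, "output")
    return m


def _genes_module(cfg, f: str) -> ModuleDef:
    g = cfg["genes"]
    var = cfg["variants"]
    m = ModuleDef(f"Gene_Expression_{f}")
    for v in (f"CREBp_{f}", f"CRTC_{f}", f"AMPKact_{f}"):
        m.add_variable(v, None, dynamic=False)
        m.add_port(v, "input")
    ref = float(g["creb_crtc_ref"])
    m.add_variable(f"tf_drive_{f}", None, dynamic=False)
    m.add_assignment(f"tf_drive_{f}",
                     f"max(CREBp_{f} * CRTC_{f} - {ref!r}, 0.0)")
    xp = g["X"]
    for gene in GENE_LIST:
        p = g[gene]
        mr = f"mRNA_{gene}_{f}"
        m.add_variable(mr, float(p["k0"]) / float(p["kdeg"]))
        if gene == "PPARGC1A" and not var["direct_creb_regulation"]:
            xref = float(g["x_protein_ref"])
            drive = f"max(Xprot_{f} - {xref!r}, 0.0)"
        else:
            drive = f"tf_drive_{f}"
        K, nn = float(p["K"]), float(p["n"])
        hill = f"(({drive})**{nn!r} / ({K!r}**{nn!r} + ({drive})**{nn!r} + 1e-300))"
        m.add_rate_rule(
            mr,
            f"{float(p['k0'])!r} + {float(p['vmax'])!r} * {hill}"
            f" - {float(p['kdeg'])!r} * {mr}",
        )
    ktr = float(xp["k_translate"]) if var["x_factor_enabled"] else 0.0
    kpd = float(xp["k_prot_deg"])
    x0 = (ktr / kpd) * (float(xp["k0"]) / float(xp["kdeg"])) if kpd > 0 else 0.0
    m.add_variable(f"Xprot_{f}", x0)
    m.add_rate_rule(
        f"Xprot_{f}",
        f"{ktr!r} * mRNA_X_{f} - {kpd!r} * Xprot_{f}",
    )
    return m


# ===========================================================================
# assembly


def build_model(cfg: Mapping | None = None) -> ModularModel:
    """Assemble the integrated modular model from a configuration."""
    cfg = cfg or load_defaults()
    model = ModularModel("skeletal_muscle")
    blood = model.add_module(_blood_module(cfg))
    for f in FIBERS:
        tr = model.add_module(_transport_module(cfg, f))
        cy = model.add_module(_cytosol_module(cfg, f))
        mi = model.add_module(_mito_module(cfg, f))
        ft = model.add_module(_fiber_transport_module(cfg, f))
        sg = model.add_module(_signaling_module(cfg, f))
        gn = model.add_module(_genes_module(cfg, f))

        # volumes are fanned out through buses (one output, many inputs)
        model.add_bus(f"V_{f}_bus", [
            (cy.name, f"V_{f}"), (tr.name, f"V_{f}"),
            (mi.name, f"V_{f}"), (ft.name, f"V_{f}"),
        ])
        model.add_bus(f"V_cyt_{f}_bus", [
            (cy.name, f"V_cyt_{f}"), (tr.name, f"V_cyt_{f}"),
            (mi.name, f"V_cyt_{f}"), (ft.name, f"V_cyt_{f}"),
        ])
        model.connect((mi.name, f"V_mit_{f}"), (ft.name, f"V_mit_{f}"))
        model.connect((cy.name, f"ADP_c_{f}"), (mi.name, f"ADP_c_{f}"))

        # shared cytosolic species: transport <-> cytosol
        for sp in BLOOD_SPECIES:
            model.connect((tr.name, f"{sp}_c_{f}"), (cy.name, f"{sp}_c_{f}"),
                          directed=False)
        # mitochondria modify cytosolic ATP/Pi/H
        for sp in ("ATP", "Pi", "H"):
            model.connect((mi.name, f"{sp}_c_{f}"), (cy.name, f"{sp}_c_{f}"),
                          directed=False)
        # intra-fiber transport
        for sp in sorted(set(PASSIVE_MITO_SPECIES) | set(FACILITATED_MITO_SPECIES)):
            model.connect((ft.name, f"{sp}_c_{f}"), (cy.name, f"{sp}_c_{f}"),
                          directed=False)
            model.connect((ft.name, f"{sp}_m_{f}"), (mi.name, f"{sp}_m_{f}"),
                          directed=False)
        # signaling reads the cytosolic energy state
        for sp in ("ATP", "PCr", "Cr", "H"):
            model.connect((sg.name, f"{sp}_c_{f}"), (cy.name, f"{sp}_c_{f}"),
                          directed=False)
        # gene expression reads signaling outputs
        for v in (f"CREBp_{f}", f"CRTC_{f}", f"AMPKact_{f}"):
            model.connect((sg.name, v), (gn.name, v))

    model.add_bus("V_bl_bus", [
        ("Capillary_Blood_Flow", "V_bl"),
        ("Cytosol_Capillary_Transport_I", "V_bl"),
        ("Cytosol_Capillary_Transport_II", "V_bl"),
    ])
    # blood species run through named buses shared by all transport modules
    for sp in BLOOD_SPECIES:
        model.add_bus(f"{sp}_bus", [
            ("Capillary_Blood_Flow", f"{sp}_b"),
            ("Cytosol_Capillary_Transport_I", f"{sp}_b"),
            ("Cytosol_Capillary_Transport_II", f"{sp}_b"),
        ])
    return model


def build_flat_model(cfg: Mapping | None = None) -> FlatModel:
    """Build and flatten the integrated model in one step."""
    return flatten(build_model(cfg))


# ===========================================================================
# simulation


@dataclass
class SimulationResult:
    """Time-indexed trajectories plus derived observables and metadata."""

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy()

    def observable(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy()

    def mixed(self, name_template: str) -> np.ndarray:
        """Volume-weighted mixed-muscle observable from per-fiber columns;
        ``name_template`` contains ``{f}`` for the fiber suffix."""
        V_I = self.metadata.get("V_I", 2.0)
        V_II = self.metadata.get("V_II", 2.0)
        a = self.data[name_template.format(f="I")].to_numpy()
        b = self.data[name_template.format(f="II")].to_numpy()
        return mixed_muscle(a, b, V_I, V_II)

    def fold_change(self, gene: str, fiber: str = "mixed") -> np.ndarray:
        from .genes import fold_change as _fc

        t0 = self.metadata["exercise_start"]
        if fiber == "mixed":
            v = self.mixed(f"mRNA_{gene}_{{f}}")
        else:
            v = self.observable(f"mRNA_{gene}_{fiber}")
        return _fc(self.time, v, t0)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def mixed_muscle(series_I, series_II, V_I: float = 2.0, V_II: float = 2.0):
    """Volume-weighted whole-muscle average of per-fiber observables."""
    series_I = np.asarray(series_I, dtype=float)
    series_II = np.asarray(series_II, dtype=float)
    if series_I.shape != series_II.shape:
        raise ValueError("fiber trajectories must share one time grid")
    return (V_I * series_I + V_II * series_II) / (V_I + V_II)


def _drivers_for(load: FiberLoad | None) -> dict[str, Callable[[float], float]]:
    if load is None:
        zero = lambda t: 0.0
        return {"W_tot": zero, "W_I": zero, "W_II": zero}
    return {"W_tot": load.W_total, "W_I": load.W_I, "W_II": load.W_II}


def find_rest_state(flat: FlatModel, overrides: Mapping[str, float] | None = None,
                    equilibrate_min: float = 2000.0):
    """Resting steady state of the flattened model (all drivers zero).

    Integrates from the configured initial values for ``equilibrate_min``
    model minutes, then polishes with damped (Levenberg-Marquardt) Newton
    iteration on the scaled right-hand side — damping is needed because
    conserved moieties (creatine, CoA) make the steady state non-isolated
    and the Jacobian singular along those directions.  Returns
    ``(y_rest, index)``.
    """
    from scipy.integrate import solve_ivp
    from scipy.optimize import least_squares

    drivers = _drivers_for(None)
    rhs, y0, index = flat.compile(drivers, overrides)
    f = lambda y: np.asarray(rhs(0.0, y))
    sol = solve_ivp(rhs, (0.0, equilibrate_min), y0, method="LSODA",
                    rtol=1e-8, atol=1e-12)
    if not sol.success:
        raise RuntimeError(f"rest equilibration failed: {sol.message}")
    y_eq = sol.y[:, -1]
    scale = np.maximum(np.abs(y_eq), 1e-10)
    res = least_squares(lambda z: f(z * scale), y_eq / scale, method="lm",
                        xtol=1e-15, ftol=1e-15, gtol=1e-15)
    y_rest = res.x * scale
    if np.abs(f(y_rest)).max() > np.abs(f(y_eq)).max() or y_rest.min() < -1e-9:
        y_rest = y_eq
    return np.maximum(y_rest, 0.0), index


def simulate(flat: FlatModel, load: FiberLoad | None, cfg: Mapping,
             t_end: float, y0: np.ndarray | None = None,
             output_dt: float | None = None,
             stop_at_exhaustion: bool = False) -> SimulationResult:
    """Integrate the flat model under an exercise load.

    The solver is restarted at every protocol discontinuity so no bout edge
    is stepped over.  With ``stop_at_exhaustion`` the integration carries a
    terminal event that fires when the demanded power reaches the
    recruitment capacity; exercise ends there and the remaining time is
    simulated as recovery.
    """
    from scipy.integrate import solve_ivp

    solver = cfg["solver"]
    rtol = float(solver["rtol"])
    atol = float(solver["atol"])
    method = solver.get("method", "LSODA")
    dt = float(output_dt or solver["output_dt"])

    drivers = _drivers_for(load)
    rhs, y_default, index = flat.compile(drivers)
    if y0 is None:
        y0 = y_default

    breaks = {0.0, float(t_end)}
    exercise_start = 0.0
    exercise_end = float(t_end)
    t_exh = None
    if load is not None:
        proto = load.protocol
        exercise_start = proto.t_start
        exercise_end = min(proto.t_end, t_end)
        breaks.update(p for p in proto.event_times() if 0.0 < p < t_end)
        if stop_at_exhaustion:
            t_exh = exhaustion_time(proto, load.recruitment)
            if t_exh is not None:
                breaks.add(t_exh)
                exercise_end = min(exercise_end, t_exh)

                original = drivers
                def _clip(fn):
                    return lambda t: 0.0 if t > t_exh else fn(t)
                drivers = {k: _clip(v) for k, v in original.items()}
                rhs, _, index = flat.compile(drivers)

    edges = sorted(breaks)
    ts: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    y = np.asarray(y0, dtype=float).copy()
    for a, b in zip(edges[:-1], edges[1:]):
        n = max(int(round((b - a) / dt)), 1)
        seg = np.linspace(a, b, n + 1)
        sol = solve_ivp(rhs, (a, b), y, t_eval=seg, rtol=rtol, atol=atol,
                        method=method)
        if not sol.success:
            state = dict(zip(index, y))
            worst = sorted(state, key=lambda k: -abs(state[k]))[:5]
            raise RuntimeError(
                f"solver failed at t={sol.t[-1] if len(sol.t) else a:.3f} min "
                f"({sol.message}); largest states: "
                + ", ".join(f"{k}={state[k]:.3g}" for k in worst)
            )
        ts.append(sol.t if not ts else sol.t[1:])
        ys.append(sol.y if not ys else sol.y[:, 1:])
        y = sol.y[:, -1].copy()
    t = np.concatenate(ts)
    Y = np.concatenate(ys, axis=1)

    obs_fn = flat.compile_assignments(drivers)
    obs_rows = [obs_fn(ti, Y[:, i]) for i, ti in enumerate(t)]
    cols: dict[str, np.ndarray] = {"time": t}
    for name, i in index.items():
        cols[name] = Y[i]
    obs_df = pd.DataFrame(obs_rows)
    for col in obs_df.columns:
        cols[col] = obs_df[col].to_numpy()
    if load is not None:
        cols["W_total"] = np.array([drivers["W_tot"](ti) for ti in t])
        cols["W_I"] = np.array([drivers["W_I"](ti) for ti in t])
        cols["W_II"] = np.array([drivers["W_II"](ti) for ti in t])
    data = pd.DataFrame(cols)

    if not np.all(np.isfinite(data.to_numpy(dtype=float))):
        raise RuntimeError("simulation produced non-finite values")

    V_f = 0.5 * (0.8 * cfg["physiology"]["V_mus0"])
    meta = {
        "config_hash": config_hash(cfg),
        "package_version": _pkg_version,
        "protocol": load.protocol.label if load is not None else "rest",
        "exercise_start": exercise_start,
        "exercise_end": exercise_end,
        "exhaustion_time": t_exh,
        "peak_power": (load.protocol(min(exercise_end, t_exh))
                       if (load is not None and t_exh is not None)
                       else (max(load.protocol(ti) for ti in t) if load else 0.0)),
        "V_I": V_f,
        "V_II": V_f,
        "solver": {"rtol": rtol, "atol": atol, "method": method},
    }
    return SimulationResult(data, meta)


def run_protocol(cfg: Mapping, protocol: ExerciseProtocol,
                 recovery_min: float = 60.0, rest_state=None,
                 stop_at_exhaustion: bool = False,
                 output_dt: float | None = None) -> SimulationResult:
    """End-to-end run: build, flatten, equilibrate at rest, then simulate
    baseline + exercise + recovery."""
    flat = build_flat_model(cfg)
    load = FiberLoad(
        protocol, recruitment_from_config(cfg),
        FatigueModel(**cfg["protocol"]["fatigue"]),
    )
    if rest_state is None:
        y_rest, _ = find_rest_state(flat)
    else:
        y_rest = rest_state
    t_end = protocol.t_end + recovery_min
    return simulate(flat, load, cfg, t_end, y0=y_rest,
                    output_dt=output_dt, stop_at_exhaustion=stop_at_exhaustion)
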