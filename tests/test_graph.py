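"""Modular composition: port typing, validation, flattening, ODE counting."""

import numpy as np
import pytest

from musclesim.graph import (Diagnostic, FlatModel, FlattenError, ModularModel,
                             ModuleDef, Variable, flatten, flatten_module,
                             ode_count, validate)

from conftest import make_fig1_model, make_fig1_model_with_bus


# ---------------------------------------------------------------------------
# validation


def test_worked_example_validates_cleanly(fig1_model):
    assert validate(fig1_model) == []


def test_single_module_without_connections_is_valid():
    m = ModuleDef("solo")
    m.add_variable("x", 1.0)
    m.add_reaction("decay", {"x": -1}, "0.1 * x")
    model = ModularModel("one")
    model.add_module(m)
    assert validate(model) == []


def test_output_to_output_connection_is_a_direction_typing_diagnostic():
    a = ModuleDef("A")
    a.add_variable("x", 1.0)
    a.add_port("x", "output")
    b = ModuleDef("B")
    b.add_variable("y", 1.0)
    b.add_port("y", "output")
    model = ModularModel("bad")
    model.add_module(a)
    model.add_module(b)
    model.connect(("A", "x"), ("B", "y"))
    diags = validate(model)
    assert len(diags) == 1
    assert diags[0].kind == "direction typing"


def test_multiply_driven_input_and_dangling_port_are_reported():
    src1 = ModuleDef("S1")
    src1.add_variable("x", 1.0)
    src1.add_port("x", "output")
    src2 = ModuleDef("S2")
    src2.add_variable("x", 2.0)
    src2.add_port("x", "output")
    sink = ModuleDef("T")
    sink.add_variable("x", None)
    sink.add_port("x", "input")
    model = ModularModel("multi")
    for m in (src1, src2, sink):
        model.add_module(m)
    model.connect(("S1", "x"), ("T", "x"))
    model.connect(("S2", "x"), ("T", "x"))
    model.connect(("S1", "nope"), ("T", "x"))
    kinds = {d.kind for d in validate(model)}
    assert "multiply-driven" in kinds
    assert "dangling" in kinds


# ---------------------------------------------------------------------------
# flattening


def test_worked_example_flattens_to_expected_species_and_reactions(fig1_model):
    flat = flatten(fig1_model)
    assert flat.species_labels() == {"A", "B", "A:B", "C", "C{p}", "X", "Z",
                                     "A_1"}
    assert len(flat.reactions) == 3
    # contact variable A is consumed by reactions from both M1 and M3
    consumers = [r.name for r in flat.reactions
                 if r.stoichiometry.get("A", 0) < 0]
    assert sorted(consumers) == ["M1_bind", "M3_convert"]
    # provenance is total: every module variable maps somewhere
    merged = {q for quals in flat.provenance.values() for q in quals}
    assert {"M1.A", "M3.A", "M1.A_B", "M2.A_B"} <= merged


def test_flatten_single_module_preserves_names():
    m = ModuleDef("solo")
    m.add_variable("x", 2.0)
    m.add_variable("k", 0.1, dynamic=False)
    m.add_reaction("decay", {"x": -1}, "k * x")
    flat = flatten_module(m)
    assert set(flat.variables) == {"x", "k"}
    assert flat.reactions[0].rate == "k * x"
    assert ode_count(flat) == 1


def test_ode_count_of_worked_example_is_eight(fig1_model):
    assert ode_count(flatten(fig1_model)) == 8


def test_ode_count_empty_model_is_zero():
    flat = FlatModel("empty")
    assert ode_count(flat) == 0


def test_merging_a_shared_contact_variable_reduces_the_count_by_one():
    def two_modules(connected: bool) -> ModularModel:
        a = ModuleDef("A")
        a.add_variable("s", 1.0)
        a.add_reaction("prod", {"s": 1}, "0.3")
        a.add_port("s", "contact")
        b = ModuleDef("B")
        b.add_variable("s", 1.0)
        b.add_reaction("deg", {"s": -1}, "0.3 * s")
        b.add_port("s", "contact")
        model = ModularModel("pair")
        model.add_module(a)
        model.add_module(b)
        if connected:
            model.connect(("A", "s"), ("B", "s"), directed=False)
        return model

    assert (ode_count(flatten(two_modules(False)))
            - ode_count(flatten(two_modules(True)))) == 1


def test_flatten_raises_on_invalid_model():
    a = ModuleDef("A")
    a.add_variable("x", 1.0)
    a.add_port("x", "output")
    b = ModuleDef("B")
    b.add_variable("y", 1.0)
    b.add_port("y", "output")
    model = ModularModel("bad")
    model.add_module(a)
    model.add_module(b)
    model.connect(("A", "x"), ("B", "y"))
    with pytest.raises(FlattenError):
        flatten(model)


def test_flatten_raises_on_unit_conflict():
    a = ModuleDef("A")
    a.add_variable("x", 1.0, unit="mM")
    a.add_port("x", "contact")
    b = ModuleDef("B")
    b.add_variable("x", 1.0, unit="uM")
    b.add_port("x", "contact")
    model = ModularModel("units")
    model.add_module(a)
    model.add_module(b)
    model.connect(("A", "x"), ("B", "x"), directed=False)
    with pytest.raises(FlattenError, match="unit"):
        flatten(model)


def test_flatten_raises_on_conflicting_initial_values():
    a = ModuleDef("A")
    a.add_variable("x", 1.0)
    a.add_port("x", "contact")
    b = ModuleDef("B")
    b.add_variable("x", 2.0)
    b.add_port("x", "contact")
    model = ModularModel("init")
    model.add_module(a)
    model.add_module(b)
    model.connect(("A", "x"), ("B", "x"), directed=False)
    with pytest.raises(FlattenError, match="initial"):
        flatten(model)


def test_flatten_is_idempotent_on_already_flat_models(fig1_model):
    flat = flatten(fig1_model)
    m = ModuleDef(flat.name, variables=dict(flat.variables),
                  reactions=list(flat.reactions),
                  assignments=list(flat.assignments),
                  rate_rules=list(flat.rate_rules),
                  events=list(flat.events))
    again = flatten_module(m)
    assert set(again.variables) == set(flat.variables)
    assert [r.stoichiometry for r in again.reactions] == \
        [r.stoichiometry for r in flat.reactions]
    assert ode_count(again) == ode_count(flat)


def test_bus_and_direct_connection_variants_flatten_identically():
    direct = flatten(make_fig1_model())
    bused = flatten(make_fig1_model_with_bus())
    assert set(direct.variables) == set(bused.variables)
    assert [(r.name, r.stoichiometry, r.rate) for r in direct.reactions] == \
        [(r.name, r.stoichiometry, r.rate) for r in bused.reactions]
    assert direct.provenance == bused.provenance


# ---------------------------------------------------------------------------
# dynamics of flattened models


def manual_fig1_rhs(t, y):
    """Independent hand-written right-hand side of the worked example."""
    A, A_1, A_B, B, C, C_p, X, Z = y
    r1 = 0.05 * A * B
    r2 = 0.2 * A_B * C
    r3 = 0.1 * C_p * A * X
    return [-r1 - r3, r3, r1, -r1, -r2, r2, -r3, r3]


def test_flattened_trajectory_matches_hand_written_model(fig1_model):
    from scipy.integrate import solve_ivp

    flat = flatten(fig1_model)
    t_eval = np.linspace(0, 20, 81)
    t, Y, idx = flat.integrate(t_eval, rtol=1e-10, atol=1e-12)

    order = sorted(idx)  # A, A_1, A_B, B, C, C_p, X, Z
    assert order == ["A", "A_1", "A_B", "B", "C", "C_p", "X", "Z"]
    y0 = [10.0, 0.0, 0.0, 8.0, 5.0, 0.0, 6.0, 0.0]
    ref = solve_ivp(manual_fig1_rhs, (0, 20), y0, t_eval=t_eval,
                    rtol=1e-10, atol=1e-12)
    for name in order:
        np.testing.assert_allclose(Y[idx[name]], ref.y[order.index(name)],
                                   rtol=1e-6, atol=1e-9)


def test_contact_variable_accumulates_rate_contributions_from_both_modules():
    """d(shared)/dt equals the sum of per-module mass-action contributions,
    checked against the closed form of ds/dt = k1 - k2 s."""
    a = ModuleDef("A")
    a.add_variable("s", 0.0)
    a.add_reaction("prod", {"s": 1}, "0.7")
    a.add_port("s", "contact")
    b = ModuleDef("B")
    b.add_variable("s", None)
    b.add_reaction("deg", {"s": -1}, "0.2 * s")
    b.add_port("s", "contact")
    model = ModularModel("sum")
    model.add_module(a)
    model.add_module(b)
    model.connect(("A", "s"), ("B", "s"), directed=False)
    flat = flatten(model)
    t_eval = np.linspace(0, 10, 51)
    t, Y, idx = flat.integrate(t_eval, rtol=1e-10, atol=1e-12)
    expected = (0.7 / 0.2) * (1 - np.exp(-0.2 * t_eval))
    np.testing.assert_allclose(Y[idx["s"]], expected, rtol=1e-7, atol=1e-9)


def test_events_fire_and_apply_assignments():
    m = ModuleDef("ev")
    m.add_variable("x", 0.0)
    m.add_rate_rule("x", "1.0")
    m.add_event("x > 2.0", [("x", "0.0")], name="reset")
    flat = flatten_module(m)
    t, Y, idx = flat.integrate(np.linspace(0, 5, 501))
    x = Y[idx["x"]]
    assert x.max() < 2.1
    assert (np.diff(x) < -1.0).sum() >= 1  # at least one reset happened


def test_rate_expression_referencing_unknown_symbol_is_reported():
    m = ModuleDef("oops")
    m.add_variable("x", 1.0)
    m.add_reaction("r", {"x": -1}, "k_missing * x")
    assert any("k_missing" in p for p in m.check())
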