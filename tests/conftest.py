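"""Shared fixtures: the default configuration, the flattened muscle model,
its resting steady state, and a couple of canonical exercise simulations.

Heavy objects are session-scoped so the full suite builds and equilibrates
the model once and reuses the trajectories across tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from musclesim.config import load_defaults
from musclesim.engine import (build_flat_model, find_rest_state,
                              recruitment_from_config, simulate)
from musclesim.graph import ModularModel, ModuleDef
from musclesim.protocols import (FatigueModel, FiberLoad, continuous_protocol)


@pytest.fixture(scope="session")
def cfg():
    return load_defaults()


@pytest.fixture(scope="session")
def flat(cfg):
    return build_flat_model(cfg)


@pytest.fixture(scope="session")
def rest(cfg, flat):
    y, idx = find_rest_state(flat)
    return y, idx


@pytest.fixture(scope="session")
def recruitment(cfg):
    return recruitment_from_config(cfg)


def _run(cfg, flat, rest_y, fraction, duration, t_end, dt=0.25):
    rec = recruitment_from_config(cfg)
    proto = continuous_protocol(fraction, duration, t_start=10.0,
                                recruitment=rec)
    load = FiberLoad(proto, rec, FatigueModel())
    return simulate(flat, load, cfg, t_end, y0=rest_y, output_dt=dt)


@pytest.fixture(scope="session")
def sim70(cfg, flat, rest):
    """30-min continuous exercise at 70% VO2max with 30 min recovery."""
    return _run(cfg, flat, rest[0], 0.7, 30.0, 70.0)


@pytest.fixture(scope="session")
def sim50(cfg, flat, rest):
    """30-min continuous exercise at 50% VO2max with 30 min recovery."""
    return _run(cfg, flat, rest[0], 0.5, 30.0, 70.0)


@pytest.fixture(scope="session")
def sim70_genes(cfg, flat, rest):
    """60-min exercise at 70% VO2max followed by >6 h of recovery."""
    return _run(cfg, flat, rest[0], 0.7, 60.0, 70.0 + 370.0, dt=0.5)


def make_fig1_model() -> ModularModel:
    """Three-module worked example used throughout the composition tests.

    M1: A + B -> A:B (contact port A, output port A_B).
    M2: A:B catalyzes C -> C{p} (input A_B, output C_p).
    M3: C{p} catalyzes A + X -> A_1 + Z (input C_p, contact A).
    """
    m1 = ModuleDef("M1")
    m1.add_variable("A", 10.0, display="A")
    m1.add_variable("B", 8.0)
    m1.add_variable("A_B", 0.0, display="A:B")
    m1.add_reaction("bind", {"A": -1, "B": -1, "A_B": 1}, "0.05 * A * B")
    m1.add_port("A", "contact")
    m1.add_port("A_B", "output")

    m2 = ModuleDef("M2")
    m2.add_variable("A_B", None, display="A:B")
    m2.add_variable("C", 5.0)
    m2.add_variable("C_p", 0.0, display="C{p}")
    m2.add_reaction("phos", {"C": -1, "C_p": 1}, "0.2 * A_B * C",
                    modifiers=("A_B",))
    m2.add_port("A_B", "input")
    m2.add_port("C_p", "output")

    m3 = ModuleDef("M3")
    m3.add_variable("C_p", None, display="C{p}")
    m3.add_variable("A", None, display="A")
    m3.add_variable("X", 6.0)
    m3.add_variable("Z", 0.0)
    m3.add_variable("A_1", 0.0, display="A_1")
    m3.add_reaction("convert", {"A": -1, "X": -1, "A_1": 1, "Z": 1},
                    "0.1 * C_p * A * X", modifiers=("C_p",))
    m3.add_port("C_p", "input")
    m3.add_port("A", "contact")

    model = ModularModel("fig1")
    for m in (m1, m2, m3):
        model.add_module(m)
    model.connect(("M1", "A_B"), ("M2", "A_B"))
    model.connect(("M2", "C_p"), ("M3", "C_p"))
    model.connect(("M1", "A"), ("M3", "A"), directed=False)
    return model


def make_fig1_model_with_bus() -> ModularModel:
    """The same model with the contact connection replaced by bus clones."""
    model = make_fig1_model()
    model.connections = [c for c in model.connections if c.directed]
    model.add_bus("A", [("M1", "A")])
    model.add_bus("A", [("M3", "A")])
    return model


@pytest.fixture()
def fig1_model():
    return make_fig1_model()
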