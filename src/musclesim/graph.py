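"""Modular model composition: modules, typed ports, connections, buses, flattening.

A modular model is a graph of self-contained kinetic modules. Each module owns
its variables, reactions, equations and events, and exposes a subset of its
variables through typed *ports*:

``input``
    the variable is computed outside the module and read inside it;
``output``
    the variable is computed inside the module and may be read elsewhere;
``contact``
    a shared variable that several modules modify simultaneously (its time
    derivative is the sum of every attached module's contribution).

Directed connections link an output port to an input port; undirected
connections link two contact ports. A *bus* is a named junction: every port
attached to any clone of a bus with the same name resolves to one flat
variable. Buses change diagram layout only, never semantics.

``flatten`` turns a modular model into a single :class:`FlatModel` — one set
of variables, reactions, assignments, rate rules and events — by union-find
over the connection/bus graph, with a provenance map recording where every
flat variable came from.
"""

from __future__ import annotations

import ast
import io
import math
import re
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Variable",
    "Reaction",
    "Assignment",
    "RateRule",
    "Event",
    "Port",
    "ModuleDef",
    "Connection",
    "Bus",
    "ModularModel",
    "Diagnostic",
    "FlatModel",
    "FlattenError",
    "validate",
    "flatten",
    "ode_count",
]

_IDENT = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


class FlattenError(ValueError):
    """Raised when a modular model cannot be flattened."""


@dataclass(frozen=True)
class Variable:
    """A named module variable.

    ``initial`` may be ``None`` for variables whose value is defined in
    another module (typical for input-port variables).  ``dynamic`` marks
    state variables (species); non-dynamic variables are constants unless an
    assignment targets them.  ``compartment`` optionally names the variable
    holding the volume that converts total reaction rates (amount/time) into
    concentration derivatives.  ``display`` carries the species-notation
    title (e.g. ``"A:B"``) when the identifier itself must stay plain.
    """

    name: str
    initial: float | None = 0.0
    unit: str = ""
    dynamic: bool = True
    compartment: str | None = None
    display: str | None = None

    def __post_init__(self) -> None:
        if not _IDENT.match(self.name):
            raise ValueError(f"variable name {self.name!r} is not an identifier")

    @property
    def label(self) -> str:
        return self.display if self.display is not None else self.name


@dataclass(frozen=True)
class Reaction:
    """A reaction with net stoichiometry and a rate-law expression.

    ``rate`` is an expression over module variables (Python syntax; the
    functions exp/log/log10/sqrt/fabs/tanh/min/max are available).  The rate
    is in amount per time; species derivatives receive
    ``stoichiometry * rate / volume`` where volume is the species'
    compartment value (1 if the species has no compartment).
    """

    name: str
    stoichiometry: Mapping[str, float]
    rate: str
    modifiers: tuple[str, ...] = ()


@dataclass(frozen=True)
class Assignment:
    """Algebraic assignment ``target := expr``, re-evaluated continuously."""

    target: str
    expr: str


@dataclass(frozen=True)
class RateRule:
    """Raw ODE ``d(target)/dt = expr`` not expressed as a reaction."""

    target: str
    expr: str


@dataclass(frozen=True)
class Event:
    """Discrete event: when ``trigger`` crosses from False to True, apply
    ``assignments`` (list of (target, expr) pairs) instantaneously."""

    trigger: str
    assignments: tuple[tuple[str, str], ...]
    name: str = ""


PORT_DIRECTIONS = ("input", "output", "contact")


@dataclass(frozen=True)
class Port:
    name: str
    variable: str
    direction: str

    def __post_init__(self) -> None:
        if self.direction not in PORT_DIRECTIONS:
            raise ValueError(
                f"port direction must be one of {PORT_DIRECTIONS}, got {self.direction!r}"
            )


@dataclass
class ModuleDef:
    """One self-contained module of a modular model."""

    name: str
    variables: dict[str, Variable] = field(default_factory=dict)
    reactions: list[Reaction] = field(default_factory=list)
    assignments: list[Assignment] = field(default_factory=list)
    rate_rules: list[RateRule] = field(default_factory=list)
    events: list[Event] = field(default_factory=list)
    ports: list[Port] = field(default_factory=list)

    def add_variable(self, name: str, initial: float | None = 0.0, **kw) -> Variable:
        if name in self.variables:
            raise ValueError(f"duplicate variable {name!r} in module {self.name!r}")
        v = Variable(name, initial, **kw)
        self.variables[name] = v
        return v

    def add_reaction(self, name: str, stoichiometry: Mapping[str, float], rate: str,
                     modifiers: Sequence[str] = ()) -> Reaction:
        r = Reaction(name, dict(stoichiometry), rate, tuple(modifiers))
        self.reactions.append(r)
        return r

    def add_assignment(self, target: str, expr: str) -> None:
        self.assignments.append(Assignment(target, expr))

    def add_rate_rule(self, target: str, expr: str) -> None:
        self.rate_rules.append(RateRule(target, expr))

    def add_event(self, trigger: str, assignments, name: str = "") -> None:
        self.events.append(Event(trigger, tuple(tuple(a) for a in assignments), name))

    def add_port(self, variable: str, direction: str, name: str | None = None) -> Port:
        p = Port(name or variable, variable, direction)
        self.ports.append(p)
        return p

    def port(self, name: str) -> Port | None:
        for p in self.ports:
            if p.name == name:
                return p
        return None

    def check(self) -> list[str]:
        """Internal consistency of a single module."""
        problems: list[str] = []
        seen_ports: set[str] = set()
        for p in self.ports:
            if p.variable not in self.variables:
                problems.append(
                    f"module {self.name!r}: port {p.name!r} references unknown "
                    f"variable {p.variable!r}"
                )
            if p.name in seen_ports:
                problems.append(f"module {self.name!r}: duplicate port name {p.name!r}")
            seen_ports.add(p.name)
        known = set(self.variables)
        for r in self.reactions:
            for s in r.stoichiometry:
                if s not in known:
                    problems.append(
                        f"module {self.name!r}: reaction {r.name!r} references "
                        f"unknown species {s!r}"
                    )
            for sym in _expr_names(r.rate):
                if sym in known or sym in _MATH_NAMES or sym == "t":
                    continue
                problems.append(
                    f"module {self.name!r}: reaction {r.name!r} rate references "
                    f"unknown symbol {sym!r}"
                )
        return problems


@dataclass(frozen=True)
class Connection:
    """A link between two module ports.

    Directed connections must run output -> input (``a`` is the output end).
    Undirected connections must link two contact ports.
    """

    a: tuple[str, str]
    b: tuple[str, str]
    directed: bool = True


@dataclass(frozen=True)
class Bus:
    """A named junction; clones share the name and merge their attachments."""

    name: str
    attached: tuple[tuple[str, str], ...]


@dataclass
class ModularModel:
    name: str
    modules: dict[str, ModuleDef] = field(default_factory=dict)
    connections: list[Connection] = field(default_factory=list)
    buses: list[Bus] = field(default_factory=list)

    def add_module(self, module: ModuleDef) -> ModuleDef:
        if module.name in self.modules:
            raise ValueError(f"duplicate module name {module.name!r}")
        self.modules[module.name] = module
        return module

    def connect(self, a: tuple[str, str], b: tuple[str, str], directed: bool = True) -> None:
        self.connections.append(Connection(tuple(a), tuple(b), directed))

    def add_bus(self, name: str, attached: Iterable[tuple[str, str]]) -> None:
        self.buses.append(Bus(name, tuple(tuple(x) for x in attached)))


@dataclass(frozen=True)
class Diagnostic:
    kind: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"[{self.kind}] {self.message}"


# --------------------------------------------------------------------------
# validation


def _resolve_port(model: ModularModel, ref: tuple[str, str]) -> Port | None:
    mod_name, port_name = ref
    mod = model.modules.get(mod_name)
    if mod is None:
        return None
    return mod.port(port_name)


def validate(model: ModularModel) -> list[Diagnostic]:
    """Check a modular model; an empty list means it is ready to flatten.

    Reported problems: references to nonexistent modules/ports (dangling),
    direction-typing violations (e.g. output connected to output), inputs
    driven by more than one output, and buses whose attached ports mix
    incompatibly.  Unconnected ports are legal: a module is simulable on its
    own, with unconnected inputs held at their declared values.
    """
    diags: list[Diagnostic] = []
    if not model.modules:
        diags.append(Diagnostic("empty", "model has no modules"))
        return diags

    for mod in model.modules.values():
        for msg in mod.check():
            diags.append(Diagnostic("module", msg))

    def port_of(ref: tuple[str, str], where: str) -> Port | None:
        p = _resolve_port(model, ref)
        if p is None:
            diags.append(
                Diagnostic("dangling", f"{where}: port {ref[0]}.{ref[1]} does not exist")
            )
        return p

    # drivers[input ref] = number of outputs feeding it
    drivers: dict[tuple[str, str], int] = {}

    for i, con in enumerate(model.connections):
        where = f"connection #{i}"
        pa = port_of(con.a, where)
        pb = port_of(con.b, where)
        if pa is None or pb is None:
            continue
        if con.directed:
            if pa.direction != "output" or pb.direction != "input":
                diags.append(
                    Diagnostic(
                        "direction typing",
                        f"{where}: directed connection must link an output to an "
                        f"input, got {pa.direction} -> {pb.direction}",
                    )
                )
            if pb.direction == "input":
                drivers[con.b] = drivers.get(con.b, 0) + 1
        else:
            if pa.direction != "contact" or pb.direction != "contact":
                diags.append(
                    Diagnostic(
                        "direction typing",
                        f"{where}: undirected connection must link contact ports, "
                        f"got {pa.direction} -- {pb.direction}",
                    )
                )

    # buses: merge clones by name, then type-check membership
    by_name: dict[str, list[tuple[str, str]]] = {}
    for bus in model.buses:
        by_name.setdefault(bus.name, []).extend(bus.attached)
    for bus_name, refs in by_name.items():
        ports = []
        for ref in refs:
            p = port_of(ref, f"bus {bus_name!r}")
            if p is not None:
                ports.append((ref, p))
        outputs = [ref for ref, p in ports if p.direction == "output"]
        contacts = [ref for ref, p in ports if p.direction == "contact"]
        inputs = [ref for ref, p in ports if p.direction == "input"]
        if outputs and contacts:
            diags.append(
                Diagnostic(
                    "direction typing",
                    f"bus {bus_name!r} mixes output and contact ports",
                )
            )
        if len(outputs) > 1:
            diags.append(
                Diagnostic(
                    "multiply-driven",
                    f"bus {bus_name!r} has {len(outputs)} output ports attached",
                )
            )
        if inputs and not outputs and not contacts:
            diags.append(
                Diagnostic(
                    "dangling",
                    f"bus {bus_name!r} drives inputs but has no output or contact "
                    "attached",
                )
            )
        for ref in inputs:
            drivers[ref] = drivers.get(ref, 0) + (1 if outputs else 0)

    for ref, n in drivers.items():
        if n > 1:
            diags.append(
                Diagnostic(
                    "multiply-driven",
                    f"input port {ref[0]}.{ref[1]} is driven by {n} outputs",
                )
            )
    return diags


# --------------------------------------------------------------------------
# expression utilities

_MATH_NAMES = {
    "exp", "log", "log10", "sqrt", "fabs", "tanh", "min", "max", "pow", "pi",
}


def _expr_names(expr: str) -> set[str]:
    try:
        tree = ast.parse(expr, mode="eval")
    except SyntaxError as e:  # pragma: no cover - guarded upstream
        raise ValueError(f"cannot parse expression {expr!r}: {e}") from e
    return {n.id for n in ast.walk(tree) if isinstance(n, ast.Name)}


def _called_names(expr: str) -> set[str]:
    tree = ast.parse(expr, mode="eval")
    return {
        n.func.id
        for n in ast.walk(tree)
        if isinstance(n, ast.Call) and isinstance(n.func, ast.Name)
    }


class _Renamer(ast.NodeTransformer):
    def __init__(self, mapping: Mapping[str, str]):
        self.mapping = mapping

    def visit_Name(self, node: ast.Name) -> ast.Name:
        new = self.mapping.get(node.id)
        if new is not None:
            return ast.copy_location(ast.Name(id=new, ctx=node.ctx), node)
        return node


def rename_expr(expr: str, mapping: Mapping[str, str]) -> str:
    """Rename identifiers in an expression (identifier-aware, not textual)."""
    tree = ast.parse(expr, mode="eval")
    tree = _Renamer(mapping).visit(tree)
    ast.fix_missing_locations(tree)
    return ast.unparse(tree)


# --------------------------------------------------------------------------
# flat model


@dataclass
class FlatModel:
    """A single non-modular hybrid ODE model produced by :func:`flatten`.

    No port objects remain; each equivalence class of connected module
    variables is one flat variable, and ``provenance`` maps every flat name
    to the qualified ``module.variable`` names it merged.
    """

    name: str
    variables: dict[str, Variable] = field(default_factory=dict)
    reactions: list[Reaction] = field(default_factory=list)
    assignments: list[Assignment] = field(default_factory=list)
    rate_rules: list[RateRule] = field(default_factory=list)
    events: list[Event] = field(default_factory=list)
    provenance: dict[str, tuple[str, ...]] = field(default_factory=dict)

    # -- structure ---------------------------------------------------------

    @property
    def assignment_targets(self) -> set[str]:
        return {a.target for a in self.assignments}

    def state_names(self) -> list[str]:
        """Dynamic state variables, in declaration order."""
        algebraic = self.assignment_targets
        return [v.name for v in self.variables.values()
                if v.dynamic and v.name not in algebraic]

    def parameter_names(self) -> list[str]:
        algebraic = self.assignment_targets
        return [v.name for v in self.variables.values()
                if not v.dynamic and v.name not in algebraic]

    def species_labels(self) -> set[str]:
        return {v.label for v in self.variables.values() if v.dynamic}

    # -- compilation -------------------------------------------------------

    def _sorted_assignments(self) -> list[Assignment]:
        """Topologically order assignments by mutual dependency."""
        targets = {a.target: a for a in self.assignments}
        deps = {
            a.target: _expr_names(a.expr) & set(targets) for a in self.assignments
        }
        ordered: list[Assignment] = []
        done: set[str] = set()
        visiting: set[str] = set()

        def visit(name: str) -> None:
            if name in done:
                return
            if name in visiting:
                raise FlattenError(f"cyclic assignment dependency at {name!r}")
            visiting.add(name)
            for d in sorted(deps[name]):
                visit(d)
            visiting.discard(name)
            done.add(name)
            ordered.append(targets[name])

        for t in sorted(targets):
            visit(t)
        return ordered

    def compile(
        self,
        functions: Mapping[str, Callable] | None = None,
        overrides: Mapping[str, float] | None = None,
    ):
        """Generate the ODE right-hand side as one compiled Python function.

        Returns ``(rhs, y0, index)`` where ``rhs(t, y)`` yields dy/dt for the
        state vector, ``y0`` is the initial state and ``index`` maps state
        name to position.  ``functions`` binds external time-dependent
        drivers referenced by name in expressions (e.g. a protocol's work
        rate); ``overrides`` replaces parameter values or initial conditions.
        """
        functions = dict(functions or {})
        overrides = dict(overrides or {})

        states = self.state_names()
        index = {s: i for i, s in enumerate(states)}
        assigns = self._sorted_assignments()
        params: dict[str, float] = {}
        for p in self.parameter_names():
            v = self.variables[p]
            val = overrides.get(p, v.initial)
            if val is None:
                raise FlattenError(f"parameter {p!r} has no value")
            params[p] = float(val)

        known_callables = set(functions) | _MATH_NAMES
        for r in self.reactions:
            missing = _called_names(r.rate) - known_callables
            if missing:
                raise FlattenError(
                    f"reaction {r.name!r} calls unbound functions {sorted(missing)}"
                )

        buf = io.StringIO()
        w = buf.write
        w("def _rhs(t, y):\n")
        for s, i in index.items():
            w(f"    {s} = y[{i}]\n")
        for a in assigns:
            w(f"    {a.target} = {a.expr}\n")
        contributions: dict[str, list[str]] = {s: [] for s in states}
        for k, r in enumerate(self.reactions):
            w(f"    _r{k} = {r.rate}\n")
            for sp, coeff in r.stoichiometry.items():
                if sp not in index:
                    continue
                vol = self.variables[sp].compartment
                term = f"{coeff!r} * _r{k}" + (f" / {vol}" if vol else "")
                contributions[sp].append(term)
        for rr in self.rate_rules:
            if rr.target in index:
                contributions[rr.target].append(f"({rr.expr})")
        rows = ", ".join(
            " + ".join(terms) if terms else "0.0" for terms in contributions.values()
        )
        w(f"    return [{rows}]\n")

        ns: dict = {
            "exp": math.exp, "log": math.log, "log10": math.log10,
            "sqrt": math.sqrt, "fabs": math.fabs, "tanh": math.tanh,
            "min": min, "max": max, "pow": pow, "pi": math.pi,
        }
        ns.update(params)
        ns.update(functions)
        code = buf.getvalue()
        exec(compile(code, f"<flat:{self.name}>", "exec"), ns)
        rhs = ns["_rhs"]

        y0 = np.empty(len(states))
        for s, i in index.items():
            val = overrides.get(s, self.variables[s].initial)
            if val is None:
                raise FlattenError(f"state {s!r} has no initial value")
            y0[i] = float(val)
        return rhs, y0, index

    def compile_assignments(
        self,
        functions: Mapping[str, Callable] | None = None,
        overrides: Mapping[str, float] | None = None,
    ):
        """Compile a function ``(t, y) -> dict`` of all assignment values."""
        functions = dict(functions or {})
        overrides = dict(overrides or {})
        states = self.state_names()
        index = {s: i for i, s in enumerate(states)}
        assigns = self._sorted_assignments()
        buf = io.StringIO()
        w = buf.write
        w("def _obs(t, y):\n")
        for s, i in index.items():
            w(f"    {s} = y[{i}]\n")
        for a in assigns:
            w(f"    {a.target} = {a.expr}\n")
        keys = ", ".join(f"{a.target!r}: {a.target}" for a in assigns)
        w(f"    return {{{keys}}}\n")
        ns: dict = {
            "exp": math.exp, "log": math.log, "log10": math.log10,
            "sqrt": math.sqrt, "fabs": math.fabs, "tanh": math.tanh,
            "min": min, "max": max, "pow": pow, "pi": math.pi,
        }
        for p in self.parameter_names():
            v = overrides.get(p, self.variables[p].initial)
            ns[p] = float(v) if v is not None else 0.0
        ns.update(functions)
        exec(compile(buf.getvalue(), f"<obs:{self.name}>", "exec"), ns)
        return ns["_obs"]

    def integrate(
        self,
        t_eval: np.ndarray,
        functions: Mapping[str, Callable] | None = None,
        overrides: Mapping[str, float] | None = None,
        rtol: float = 1e-8,
        atol: float = 1e-10,
        method: str = "LSODA",
    ):
        """Convenience integration of a flat model without protocol events.

        Returns ``(t, Y, index)`` with ``Y`` of shape (n_states, n_times).
        Discrete events declared on the model are honoured by restarting the
        solver when a trigger fires (trigger expressions must be of the form
        ``expr`` crossing zero upward or a comparison ``a > b`` etc.).
        """
        from scipy.integrate import solve_ivp

        rhs, y0, index = self.compile(functions, overrides)
        if not self.events:
            sol = solve_ivp(
                rhs, (t_eval[0], t_eval[-1]), y0, t_eval=t_eval,
                rtol=rtol, atol=atol, method=method,
            )
            if not sol.success:  # pragma: no cover - solver guard
                raise RuntimeError(f"integration failed: {sol.message}")
            return sol.t, sol.y, index
        return self._integrate_with_events(
            rhs, y0, index, t_eval, functions, overrides, rtol, atol, method
        )

    def _integrate_with_events(self, rhs, y0, index, t_eval, functions,
                               overrides, rtol, atol, method):
        from scipy.integrate import solve_ivp

        functions = dict(functions or {})
        guards = []
        appliers = []
        # deterministic tie-break: events are stored sorted by originating
        # module name at flatten time; preserve that order here
        for ev in self.events:
            guards.append(_compile_event_guard(self, ev, functions))
            appliers.append(_compile_event_apply(self, ev, functions, index))

        ts: list[np.ndarray] = []
        ys: list[np.ndarray] = []
        t0, t_end = float(t_eval[0]), float(t_eval[-1])
        y = y0.copy()
        remaining = np.asarray(t_eval, dtype=float)
        while t0 < t_end:
            mask = remaining >= t0 - 1e-12
            seg_eval = remaining[mask]
            evts = []
            for g in guards:
                f = (lambda gg: lambda t, yy: gg(t, yy))(g)
                f.terminal = True
                f.direction = 1
                evts.append(f)
            sol = solve_ivp(rhs, (t0, t_end), y, t_eval=seg_eval, rtol=rtol,
                            atol=atol, method=method, events=evts)
            if not sol.success:  # pragma: no cover
                raise RuntimeError(f"integration failed: {sol.message}")
            ts.append(sol.t)
            ys.append(sol.y)
            fired = [k for k, te in enumerate(sol.t_events) if len(te)]
            if not fired:
                break
            t_fire = min(float(sol.t_events[k][0]) for k in fired)
            y = sol.y_events[fired[0]][0].copy() if len(sol.y_events[fired[0]]) else y
            for k in fired:
                y = appliers[k](t_fire, y)
            t0 = t_fire
        t = np.concatenate(ts) if ts else np.array([])
        Y = np.concatenate(ys, axis=1) if ys else np.empty((len(index), 0))
        # drop duplicated boundary points
        if len(t):
            keep = np.concatenate([[True], np.diff(t) > 0])
            t, Y = t[keep], Y[:, keep]
        return t, Y, index


def _compile_event_guard(flat: FlatModel, ev: Event, functions):
    expr = ev.trigger
    # turn comparisons into sign-crossing expressions
    tree = ast.parse(expr, mode="eval")
    node = tree.body
    if isinstance(node, ast.Compare) and len(node.ops) == 1:
        left = ast.unparse(node.left)
        right = ast.unparse(node.comparators[0])
        if isinstance(node.ops[0], (ast.Gt, ast.GtE)):
            expr = f"({left}) - ({right})"
        elif isinstance(node.ops[0], (ast.Lt, ast.LtE)):
            expr = f"({right}) - ({left})"
    states = flat.state_names()
    src = "def _g(t, y):\n"
    for i, s in enumerate(states):
        src += f"    {s} = y[{i}]\n"
    for a in flat._sorted_assignments():
        src += f"    {a.target} = {a.expr}\n"
    src += f"    return {expr}\n"
    ns: dict = {"exp": math.exp, "log": math.log, "log10": math.log10,
                "sqrt": math.sqrt, "min": min, "max": max, "pi": math.pi}
    for p in flat.parameter_names():
        v = flat.variables[p].initial
        ns[p] = float(v) if v is not None else 0.0
    ns.update(functions)
    exec(compile(src, "<event-guard>", "exec"), ns)
    return ns["_g"]


def _compile_event_apply(flat: FlatModel, ev: Event, functions, index):
    states = flat.state_names()
    src = "def _a(t, y):\n    y = y.copy()\n"
    for i, s in enumerate(states):
        src += f"    {s} = y[{i}]\n"
    for a in flat._sorted_assignments():
        src += f"    {a.target} = {a.expr}\n"
    for tgt, expr in ev.assignments:
        if tgt in index:
            src += f"    y[{index[tgt]}] = {expr}\n"
    src += "    return y\n"
    ns: dict = {"exp": math.exp, "log": math.log, "log10": math.log10,
                "sqrt": math.sqrt, "min": min, "max": max, "pi": math.pi}
    for p in flat.parameter_names():
        v = flat.variables[p].initial
        ns[p] = float(v) if v is not None else 0.0
    ns.update(functions)
    exec(compile(src, "<event-apply>", "exec"), ns)
    return ns["_a"]


def ode_count(flat: FlatModel) -> int:
    """Number of dynamic state variables (one ODE each) in a flat model."""
    return len(flat.state_names())


# --------------------------------------------------------------------------
# flattening


class _UnionFind:
    def __init__(self):
        self.parent: dict = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller qualified name becomes the root
            lo, hi = sorted((ra, rb))
            self.parent[hi] = lo


def flatten(model: ModularModel) -> FlatModel:
    """Flatten a modular model into a single hybrid ODE model.

    Union-find over the connection/bus graph gives the variable equivalence
    classes; each class becomes one flat variable named by its (common) local
    name, disambiguated with a module prefix only on collision.  Reactions,
    assignments, rate rules and events are carried over with symbols renamed;
    contact variables accumulate rate contributions from every module that
    modifies them.  Raises :class:`FlattenError` on validation failure or on
    conflicting units/initial values between merged variables.
    """
    diags = validate(model)
    if diags:
        raise FlattenError(
            "model does not validate: " + "; ".join(str(d) for d in diags)
        )

    uf = _UnionFind()
    for mod in model.modules.values():
        for v in mod.variables:
            uf.find((mod.name, v))

    def port_var(ref: tuple[str, str]) -> tuple[str, str]:
        p = _resolve_port(model, ref)
        assert p is not None
        return (ref[0], p.variable)

    for con in model.connections:
        uf.union(port_var(con.a), port_var(con.b))
    by_name: dict[str, list[tuple[str, str]]] = {}
    for bus in model.buses:
        by_name.setdefault(bus.name, []).extend(bus.attached)
    for refs in by_name.values():
        nodes = [port_var(r) for r in refs]
        for other in nodes[1:]:
            uf.union(nodes[0], other)

    # group members per class
    classes: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for mod in model.modules.values():
        for v in mod.variables:
            classes.setdefault(uf.find((mod.name, v)), []).append((mod.name, v))
    for members in classes.values():
        members.sort()

    # choose flat names: common local name when unique model-wide
    local_name_counts: dict[str, int] = {}
    class_local: dict[tuple[str, str], str] = {}
    for root, members in classes.items():
        locals_ = sorted({v for _, v in members})
        class_local[root] = locals_[0]
        local_name_counts[locals_[0]] = local_name_counts.get(locals_[0], 0) + 1

    flat_name: dict[tuple[str, str], str] = {}
    for root, members in sorted(classes.items()):
        base = class_local[root]
        if local_name_counts[base] > 1:
            base = f"{members[0][0]}_{base}"
        flat_name[root] = base

    # merge variable attributes per class
    flat = FlatModel(name=model.name)
    rename: dict[str, dict[str, str]] = {m: {} for m in model.modules}
    for root, members in sorted(classes.items(), key=lambda kv: flat_name[kv[0]]):
        name = flat_name[root]
        vs = [model.modules[m].variables[v] for m, v in members]
        units = {v.unit for v in vs if v.unit}
        if len(units) > 1:
            raise FlattenError(
                f"variable {name!r} merges conflicting units {sorted(units)}"
            )
        initials = {v.initial for v in vs if v.initial is not None}
        if len(initials) > 1:
            raise FlattenError(
                f"variable {name!r} merges conflicting initial values "
                f"{sorted(initials)} from {members}"
            )
        compartments = {v.compartment for v in vs if v.compartment}
        if len(compartments) > 1:
            raise FlattenError(
                f"variable {name!r} merges conflicting compartments "
                f"{sorted(compartments)}"
            )
        displays = [v.display for v in vs if v.display]
        flat.variables[name] = Variable(
            name=name,
            initial=(initials.pop() if initials else None),
            unit=(units.pop() if units else ""),
            dynamic=any(v.dynamic for v in vs),
            compartment=(compartments.pop() if compartments else None),
            display=(displays[0] if displays else None),
        )
        flat.provenance[name] = tuple(f"{m}.{v}" for m, v in members)
        for m, v in members:
            rename[m][v] = name

    # compartments are named by variables; remap them too
    for name, var in list(flat.variables.items()):
        if var.compartment is not None:
            # compartment was a local name in the owning module
            owners = [m for m, v in (tuple(p.split(".", 1)) for p in flat.provenance[name])]
            comp = var.compartment
            for m in owners:
                if comp in rename[m]:
                    flat.variables[name] = replace(var, compartment=rename[m][comp])
                    break

    assigned: dict[str, str] = {}
    for mod_name in sorted(model.modules):
        mod = model.modules[mod_name]
        rmap = rename[mod_name]
        for r in mod.reactions:
            flat.reactions.append(
                Reaction(
                    name=f"{mod_name}_{r.name}",
                    stoichiometry={rmap[s]: c for s, c in r.stoichiometry.items()},
                    rate=rename_expr(r.rate, rmap),
                    modifiers=tuple(rmap.get(m, m) for m in r.modifiers),
                )
            )
        for a in mod.assignments:
            tgt = rmap[a.target]
            if tgt in assigned:
                raise FlattenError(
                    f"flat variable {tgt!r} is assigned in both "
                    f"{assigned[tgt]!r} and {mod_name!r}"
                )
            assigned[tgt] = mod_name
            flat.assignments.append(Assignment(tgt, rename_expr(a.expr, rmap)))
        for rr in mod.rate_rules:
            tgt = rmap[rr.target]
            expr = rename_expr(rr.expr, rmap)
            existing = next((x for x in flat.rate_rules if x.target == tgt), None)
            if existing is None:
                flat.rate_rules.append(RateRule(tgt, expr))
            else:
                # contact variable modified by several modules: contributions add
                flat.rate_rules.remove(existing)
                flat.rate_rules.append(
                    RateRule(tgt, f"({existing.expr}) + ({expr})")
                )
        for ev in mod.events:
            flat.events.append(
                Event(
                    trigger=rename_expr(ev.trigger, rmap),
                    assignments=tuple(
                        (rmap[t], rename_expr(e, rmap)) for t, e in ev.assignments
                    ),
                    name=f"{mod_name}_{ev.name}" if ev.name else mod_name,
                )
            )
    # deterministic same-instant ordering: already appended in module-name order
    return flat


def flatten_module(module: ModuleDef) -> FlatModel:
    """Flatten a single module (identity transform, names preserved)."""
    m = ModularModel(name=module.name)
    m.add_module(module)
    return flatten(m)
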