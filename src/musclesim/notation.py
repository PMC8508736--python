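"""Text-notation layer: species-structure strings and ``@`` annotation lines.

Species structures follow the Transpath-style conventions used in pathway
text formats: a complex of entities A and B is ``"A:B"``, an entity with a
state variable p (e.g. phosphorylated) is ``"A{p}"``, a homotrimer of A is
``"(A)3"``, and these compose, e.g. ``"(A{p})3:B{r}{p}:C"``.

Annotation lines attach display/semantic properties to model entities with
the syntax ``@entity_id.property = value`` (e.g. ``sbgnType``,
``sbgnViewTitle``).  Lines not starting with ``@`` belong to the host model
language (e.g. Antimony) and are passed through untouched.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Union

__all__ = [
    "Entity",
    "Multimer",
    "Complex",
    "SpeciesStructure",
    "SpeciesSyntaxError",
    "parse_species",
    "emit_species",
    "AnnotationRecord",
    "AnnotationSyntaxError",
    "parse_annotations",
    "split_annotations",
]


class SpeciesSyntaxError(ValueError):
    """Malformed species-notation string; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class Entity:
    """A named entity with an ordered list of opaque state tokens."""

    name: str
    states: tuple[str, ...] = ()

    kind = "entity"


@dataclass(frozen=True)
class Multimer:
    """``multiplicity`` copies of one component; multiplicity >= 2."""

    component: "SpeciesStructure"
    multiplicity: int

    kind = "multimer"

    def __post_init__(self) -> None:
        if self.multiplicity < 2:
            raise ValueError("multimer multiplicity must be >= 2")


@dataclass(frozen=True)
class Complex:
    """An ordered complex of >= 2 components."""

    components: tuple["SpeciesStructure", ...]

    kind = "complex"

    def __post_init__(self) -> None:
        if len(self.components) < 2:
            raise ValueError("a complex needs at least 2 components")


SpeciesStructure = Union[Entity, Multimer, Complex]

_NAME = re.compile(r"[^:{}()\s]+")
_INT = re.compile(r"\d+")


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def error(self, msg: str) -> SpeciesSyntaxError:
        return SpeciesSyntaxError(msg, self.pos)

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def parse(self) -> SpeciesStructure:
        node = self.parse_complex()
        if self.pos != len(self.text):
            raise self.error(f"unexpected character {self.peek()!r}")
        return node

    def parse_complex(self) -> SpeciesStructure:
        components = [self.parse_component()]
        while self.peek() == ":":
            self.pos += 1
            components.append(self.parse_component())
        if len(components) == 1:
            return components[0]
        return Complex(tuple(components))

    def parse_component(self) -> SpeciesStructure:
        if self.peek() in ("", ":"):
            raise self.error("empty component")
        if self.peek() == "(":
            return self.parse_multimer()
        return self.parse_entity()

    def parse_multimer(self) -> Multimer:
        assert self.peek() == "("
        open_pos = self.pos
        self.pos += 1
        inner = self.parse_complex()
        if self.peek() != ")":
            self.pos = open_pos
            raise self.error("unbalanced parenthesis")
        self.pos += 1
        m = _INT.match(self.text, self.pos)
        if not m:
            raise self.error("multimer needs an integer multiplicity")
        mult = int(m.group())
        if mult < 2:
            raise self.error(f"multimer multiplicity must be >= 2, got {mult}")
        self.pos = m.end()
        return Multimer(inner, mult)

    def parse_entity(self) -> Entity:
        m = _NAME.match(self.text, self.pos)
        if not m:
            raise self.error("expected an entity name")
        name = m.group()
        self.pos = m.end()
        states: list[str] = []
        while self.peek() == "{":
            open_pos = self.pos
            close = self.text.find("}", self.pos + 1)
            if close < 0:
                self.pos = open_pos
                raise self.error("unbalanced brace")
            token = self.text[self.pos + 1 : close]
            if not token:
                self.pos = open_pos
                raise self.error("empty state token")
            if any(c in token for c in "{}():"):
                raise self.error(f"illegal character in state token {token!r}")
            states.append(token)
            self.pos = close + 1
        return Entity(name, tuple(states))


def parse_species(text: str) -> SpeciesStructure:
    """Parse a Transpath-style species string into its structure tree.

    >>> parse_species("A:B")
    Complex(components=(Entity(name='A', states=()), Entity(name='B', states=())))
    """
    if not text:
        raise SpeciesSyntaxError("empty species string", 0)
    return _Parser(text).parse()


def emit_species(node: SpeciesStructure) -> str:
    """Serialize a structure tree back to notation; inverse of parse."""
    if isinstance(node, Entity):
        return node.name + "".join("{%s}" % s for s in node.states)
    if isinstance(node, Multimer):
        return f"({emit_species(node.component)}){node.multiplicity}"
    if isinstance(node, Complex):
        return ":".join(emit_species(c) for c in node.components)
    raise TypeError(f"not a species structure: {node!r}")


# --------------------------------------------------------------------------
# @ annotations


class AnnotationSyntaxError(ValueError):
    def __init__(self, message: str, line: int):
        super().__init__(f"{message} (line {line})")
        self.line = line


@dataclass(frozen=True)
class AnnotationRecord:
    """One ``@entity_id.property = value`` record."""

    entity_id: str
    property: str
    value: str


def split_annotations(text: str) -> tuple[list[AnnotationRecord], str]:
    """Separate ``@`` annotation lines from host-language lines.

    Returns ``(records, passthrough)`` where ``passthrough`` keeps every
    non-annotation line untouched (and in order) for the downstream model
    language processor.
    """
    records: list[AnnotationRecord] = []
    passthrough: list[str] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped.startswith("@"):
            passthrough.append(line)
            continue
        body = stripped[1:]
        head, eq, value = body.partition("=")
        if not eq:
            raise AnnotationSyntaxError("annotation line lacks '='", lineno)
        entity, dot, prop = head.strip().rpartition(".")
        if not dot or not entity or not prop:
            raise AnnotationSyntaxError(
                "annotation line lacks 'entity.property' before '='", lineno
            )
        value = value.strip()
        if len(value) >= 2 and value[0] == value[-1] and value[0] in "\"'":
            value = value[1:-1]
        records.append(AnnotationRecord(entity, prop.strip(), value))
    return records, "\n".join(passthrough)


def parse_annotations(text: str) -> list[AnnotationRecord]:
    """Parse all ``@entity_id.property = value`` lines of a document."""
    records, _ = split_annotations(text)
    return records
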