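"""Boolean networks: expressions, rule files, states, and update semantics.

A Boolean network is a directed graph G(V, E) in which every node ``v`` carries a
binary state X_v(t) and a logical transition function f_v over the current states
of its regulators, X_v(t+1) = f_v(X_r1(t), ..., X_rk(t)).  Two update schemes are
provided: synchronous (all nodes updated at once; used for fixed-point testing)
and asynchronous (one uniformly chosen node updated per step; used for
simulation).  Nodes may be *clamped* to a fixed truth value, which models
overexpression (clamp true) and knockout (clamp false): a clamped node's rule is
never evaluated and the node is excluded from the asynchronous draw.

Rule files use a small text dialect, one rule per line::

    # comment
    NODE = expr

with operators ``!`` (not), ``&`` (and), ``|`` (or), parentheses, and the
constants ``0``/``1``.  Precedence: ``!`` > ``&`` > ``|``.  Node order equals
declaration order and defines bit positions in integer state encodings.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field
from typing import Iterator

import networkx as nx
import numpy as np

__all__ = [
    "BoolExpr",
    "BooleanNetwork",
    "NetworkState",
    "ClampSet",
    "RuleSyntaxError",
    "parse_rules",
    "serialize_rules",
    "evaluate",
    "sync_step",
    "async_step",
]


# ---------------------------------------------------------------------------
# Expressions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoolExpr:
    """Immutable Boolean expression tree.

    ``kind`` is one of ``variable``, ``constant``, ``not``, ``and``, ``or``.
    ``and``/``or`` are n-ary (children in left-to-right source order).
    """

    kind: str
    children: tuple["BoolExpr", ...] = ()
    name: str | None = None
    value: bool | None = None

    # -- constructors -------------------------------------------------------
    @staticmethod
    def var(name: str) -> "BoolExpr":
        return BoolExpr("variable", name=name)

    @staticmethod
    def const(value: bool) -> "BoolExpr":
        return BoolExpr("constant", value=bool(value))

    @staticmethod
    def not_(child: "BoolExpr") -> "BoolExpr":
        return BoolExpr("not", (child,))

    @staticmethod
    def and_(*children: "BoolExpr") -> "BoolExpr":
        if not children:
            raise ValueError("and_ requires at least one operand")
        return children[0] if len(children) == 1 else BoolExpr("and", tuple(children))

    @staticmethod
    def or_(*children: "BoolExpr") -> "BoolExpr":
        if not children:
            raise ValueError("or_ requires at least one operand")
        return children[0] if len(children) == 1 else BoolExpr("or", tuple(children))

    # -- introspection ------------------------------------------------------
    def variables(self) -> set[str]:
        """Names of all variables referenced anywhere in the expression."""
        if self.kind == "variable":
            return {self.name}  # type: ignore[arg-type]
        out: set[str] = set()
        for c in self.children:
            out |= c.variables()
        return out

    def __str__(self) -> str:
        return _expr_to_str(self, 0)


# precedence levels: or=1, and=2, not=3, atom=4
_PREC = {"or": 1, "and": 2, "not": 3, "variable": 4, "constant": 4}


def _expr_to_str(e: BoolExpr, parent_prec: int) -> str:
    prec = _PREC[e.kind]
    if e.kind == "variable":
        s = e.name or ""
    elif e.kind == "constant":
        s = "1" if e.value else "0"
    elif e.kind == "not":
        s = "!" + _expr_to_str(e.children[0], prec)
    else:
        op = " & " if e.kind == "and" else " | "
        s = op.join(_expr_to_str(c, prec) for c in e.children)
    return "(" + s + ")" if prec < parent_prec else s


def evaluate(expr: BoolExpr, state: Mapping[str, bool]) -> bool:
    """Truth-functional evaluation of ``expr`` against a node→value mapping.

    Pure; raises ``KeyError`` for an unassigned variable.
    """
    k = expr.kind
    if k == "variable":
        return bool(state[expr.name])
    if k == "constant":
        return bool(expr.value)
    if k == "not":
        return not evaluate(expr.children[0], state)
    if k == "and":
        return all(evaluate(c, state) for c in expr.children)
    if k == "or":
        return any(evaluate(c, state) for c in expr.children)
    raise ValueError(f"unknown expression kind {k!r}")


def evaluate_columns(expr: BoolExpr, columns: Mapping[str, np.ndarray]) -> np.ndarray:
    """Vectorized evaluation: each variable is a boolean array of states."""
    k = expr.kind
    if k == "variable":
        return columns[expr.name]
    if k == "constant":
        n = len(next(iter(columns.values()))) if columns else 1
        return np.full(n, bool(expr.value))
    if k == "not":
        return ~evaluate_columns(expr.children[0], columns)
    acc = evaluate_columns(expr.children[0], columns)
    for c in expr.children[1:]:
        nxt = evaluate_columns(c, columns)
        acc = (acc & nxt) if k == "and" else (acc | nxt)
    return acc


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

class RuleSyntaxError(ValueError):
    """Syntax or semantic error in a rule file; carries a 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


_TOKEN_CHARS = set("!&|()=")


def _tokenize(text: str, lineno: int) -> list[str]:
    toks: list[str] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch.isspace():
            i += 1
        elif ch in _TOKEN_CHARS:
            toks.append(ch)
            i += 1
        elif ch.isalnum() or ch == "_":
            j = i
            while j < len(text) and (text[j].isalnum() or text[j] == "_"):
                j += 1
            toks.append(text[i:j])
            i = j
        else:
            raise RuleSyntaxError(f"unexpected character {ch!r}", lineno)
    return toks


class _ExprParser:
    """Recursive descent over the token list of a single rule right-hand side."""

    def __init__(self, tokens: list[str], lineno: int):
        self.toks = tokens
        self.pos = 0
        self.lineno = lineno

    def peek(self) -> str | None:
        return self.toks[self.pos] if self.pos < len(self.toks) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise RuleSyntaxError("unexpected end of expression", self.lineno)
        self.pos += 1
        return tok

    def parse(self) -> BoolExpr:
        e = self.parse_or()
        if self.peek() is not None:
            raise RuleSyntaxError(f"unexpected token {self.peek()!r}", self.lineno)
        return e

    def parse_or(self) -> BoolExpr:
        terms = [self.parse_and()]
        while self.peek() == "|":
            self.take()
            terms.append(self.parse_and())
        return BoolExpr.or_(*terms)

    def parse_and(self) -> BoolExpr:
        factors = [self.parse_factor()]
        while self.peek() == "&":
            self.take()
            factors.append(self.parse_factor())
        return BoolExpr.and_(*factors)

    def parse_factor(self) -> BoolExpr:
        tok = self.take()
        if tok == "!":
            return BoolExpr.not_(self.parse_factor())
        if tok == "(":
            e = self.parse_or()
            if self.take() != ")":
                raise RuleSyntaxError("expected ')'", self.lineno)
            return e
        if tok in ("0", "1"):
            return BoolExpr.const(tok == "1")
        if tok in _TOKEN_CHARS:
            raise RuleSyntaxError(f"unexpected token {tok!r}", self.lineno)
        return BoolExpr.var(tok)


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BooleanNetwork:
    """A Boolean network: ordered node list plus one transition rule per node.

    Node order is significant: it defines bit positions in integer state
    encodings (node ``i`` ↔ bit ``i``) and the column order of reports.
    """

    nodes: tuple[str, ...]
    rules: dict[str, BoolExpr] = field(compare=False)

    def __post_init__(self):
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node names")
        missing = set(self.nodes) - set(self.rules)
        if missing:
            raise ValueError(f"nodes without rules: {sorted(missing)}")
        extra = set(self.rules) - set(self.nodes)
        if extra:
            raise ValueError(f"rules for unknown nodes: {sorted(extra)}")
        for node, rule in self.rules.items():
            undeclared = rule.variables() - set(self.nodes)
            if undeclared:
                raise ValueError(
                    f"rule for {node!r} references undeclared node(s) "
                    f"{sorted(undeclared)}"
                )

    @property
    def n(self) -> int:
        return len(self.nodes)

    def index(self, node: str) -> int:
        return self.nodes.index(node)

    @property
    def edges(self) -> set[tuple[str, str]]:
        """Derived regulator→target pairs E."""
        return {
            (reg, target)
            for target, rule in self.rules.items()
            for reg in rule.variables()
        }

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def regulators(self, node: str) -> tuple[str, ...]:
        """Regulators of ``node`` in network node order."""
        deps = self.rules[node].variables()
        return tuple(v for v in self.nodes if v in deps)


def parse_rules(text: str) -> BooleanNetwork:
    """Parse a rule file (``NODE = expr`` per line) into a :class:`BooleanNetwork`.

    Raises :class:`RuleSyntaxError` on malformed lines, duplicate rules, or
    references to nodes that never receive a rule.
    """
    nodes: list[str] = []
    rules: dict[str, BoolExpr] = {}
    line_of: dict[str, int] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        toks = _tokenize(line, lineno)
        if len(toks) < 3 or toks[1] != "=":
            raise RuleSyntaxError("expected 'NODE = expression'", lineno)
        node = toks[0]
        if node in _TOKEN_CHARS or node in ("0", "1"):
            raise RuleSyntaxError(f"invalid node name {node!r}", lineno)
        if node in rules:
            raise RuleSyntaxError(f"duplicate rule for {node!r}", lineno)
        nodes.append(node)
        rules[node] = _ExprParser(toks[2:], lineno).parse()
        line_of[node] = lineno
    declared = set(nodes)
    for node, rule in rules.items():
        undeclared = rule.variables() - declared
        if undeclared:
            raise RuleSyntaxError(
                f"rule for {node!r} references undeclared node(s) "
                f"{sorted(undeclared)}",
                line_of[node],
            )
    return BooleanNetwork(tuple(nodes), rules)


def serialize_rules(net: BooleanNetwork) -> str:
    """Render a network back to the rule-file dialect (parse∘serialize fixpoint)."""
    return "".join(f"{node} = {net.rules[node]}\n" for node in net.nodes)


# ---------------------------------------------------------------------------
# States and clamps
# ---------------------------------------------------------------------------

class NetworkState(Mapping):
    """A truth assignment over all nodes of a network.

    Behaves as a read-only mapping node→bool and round-trips losslessly through
    an integer bitmask using the network's node order (node ``i`` ↔ bit ``i``).
    """

    __slots__ = ("nodes", "bits")

    def __init__(self, nodes: tuple[str, ...], bits: int):
        if not 0 <= bits < (1 << len(nodes)):
            raise ValueError("bitmask out of range for node list")
        self.nodes = tuple(nodes)
        self.bits = int(bits)

    # -- constructors -------------------------------------------------------
    @classmethod
    def from_dict(cls, net: BooleanNetwork, assignment: Mapping[str, bool]) -> "NetworkState":
        if set(assignment) != set(net.nodes):
            raise ValueError("assignment must cover exactly the network's nodes")
        bits = 0
        for i, node in enumerate(net.nodes):
            if assignment[node]:
                bits |= 1 << i
        return cls(net.nodes, bits)

    @classmethod
    def from_int(cls, net: BooleanNetwork, bits: int) -> "NetworkState":
        return cls(net.nodes, bits)

    @classmethod
    def from_on_set(cls, net: BooleanNetwork, on: set[str] | frozenset[str]) -> "NetworkState":
        unknown = set(on) - set(net.nodes)
        if unknown:
            raise ValueError(f"unknown nodes in ON-set: {sorted(unknown)}")
        return cls.from_dict(net, {v: v in on for v in net.nodes})

    # -- mapping protocol ---------------------------------------------------
    def __getitem__(self, node: str) -> bool:
        try:
            i = self.nodes.index(node)
        except ValueError:
            raise KeyError(node) from None
        return bool((self.bits >> i) & 1)

    def __iter__(self) -> Iterator[str]:
        return iter(self.nodes)

    def __len__(self) -> int:
        return len(self.nodes)

    # -- conversions --------------------------------------------------------
    def to_int(self) -> int:
        return self.bits

    def as_dict(self) -> dict[str, bool]:
        return {v: self[v] for v in self.nodes}

    def on_set(self) -> frozenset[str]:
        return frozenset(v for v in self.nodes if self[v])

    def bitstring(self) -> str:
        """Display string in node order (node 0 leftmost)."""
        return "".join("1" if self[v] else "0" for v in self.nodes)

    def with_values(self, values: Mapping[str, bool]) -> "NetworkState":
        bits = self.bits
        for node, val in values.items():
            i = self.nodes.index(node)
            bits = (bits | (1 << i)) if val else (bits & ~(1 << i))
        return NetworkState(self.nodes, bits)

    def __eq__(self, other) -> bool:
        if isinstance(other, NetworkState):
            return self.nodes == other.nodes and self.bits == other.bits
        return Mapping.__eq__(self, other) if isinstance(other, Mapping) else NotImplemented

    def __hash__(self) -> int:
        return hash((self.nodes, self.bits))

    def __repr__(self) -> str:
        return f"NetworkState({self.bitstring()})"


@dataclass(frozen=True)
class ClampSet:
    """Nodes forced to fixed truth values (OE → true, KO → false)."""

    clamped: Mapping[str, bool] = field(default_factory=dict)

    @staticmethod
    def oe(*nodes: str) -> "ClampSet":
        return ClampSet({n: True for n in nodes})

    @staticmethod
    def ko(*nodes: str) -> "ClampSet":
        return ClampSet({n: False for n in nodes})

    def validate(self, net: BooleanNetwork) -> None:
        unknown = set(self.clamped) - set(net.nodes)
        if unknown:
            raise ValueError(f"clamped nodes not in network: {sorted(unknown)}")

    def apply(self, state: NetworkState) -> NetworkState:
        return state.with_values(self.clamped) if self.clamped else state

    def __bool__(self) -> bool:
        return bool(self.clamped)


_NO_CLAMPS = ClampSet()


# ---------------------------------------------------------------------------
# Update semantics
# ---------------------------------------------------------------------------

def sync_step(
    net: BooleanNetwork, state: NetworkState, clamps: ClampSet = _NO_CLAMPS
) -> NetworkState:
    """Synchronous update: every unclamped node takes f_v(state) simultaneously."""
    clamps.validate(net)
    bits = 0
    for i, node in enumerate(net.nodes):
        if node in clamps.clamped:
            val = clamps.clamped[node]
        else:
            val = evaluate(net.rules[node], state)
        if val:
            bits |= 1 << i
    return NetworkState(net.nodes, bits)


def async_step(
    net: BooleanNetwork,
    state: NetworkState,
    clamps: ClampSet = _NO_CLAMPS,
    rng: np.random.Generator | None = None,
) -> NetworkState:
    """Asynchronous update: one uniformly chosen unclamped node is updated.

    With every node clamped, the state is returned unchanged.  Randomness comes
    exclusively from the caller-supplied ``rng``.
    """
    clamps.validate(net)
    if rng is None:
        raise ValueError("async_step requires a caller-seeded rng")
    free = [v for v in net.nodes if v not in clamps.clamped]
    state = clamps.apply(state)
    if not free:
        return state
    node = free[rng.integers(len(free))]
    val = evaluate(net.rules[node], state)
    return state.with_values({node: val})


def is_fixed_point(
    net: BooleanNetwork, state: NetworkState, clamps: ClampSet = _NO_CLAMPS
) -> bool:
    return sync_step(net, state, clamps) == state
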