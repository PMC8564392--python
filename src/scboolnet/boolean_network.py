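"""Signed Boolean networks with nested canalyzing update rules.

A network is an ordered set of genes, a list of signed directed edges, and
exactly one Boolean rule per gene.  Gene state is a fixed-order bit vector;
rules are pure functions of the current state.  Rules are serialized in a
plain-text dialect, one rule per line::

    # comment
    genes: TP53 MDM2 BAX      # optional canonical gene order
    inputs: EGF               # frozen inputs (rule = identity)
    TP53* = not MDM2
    MDM2* = TP53
    BAX* = TP53 and not MDM2

Operators are ASCII ``and``/``or``/``not``; the unicode connectives
``∧ ∨ ¬`` (and ``⋀ ⋁``, ``& | !``) are accepted as aliases on parse.
A gene with no regulators is a *frozen input*: its rule holds its value.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

__all__ = [
    "GeneNode",
    "SignedEdge",
    "NestedCanalyzingRule",
    "NetworkState",
    "BooleanNetwork",
    "RuleParseError",
    "parse_rules",
    "write_rules",
    "build_ncf",
    "evaluate_rule",
    "evaluate_expression",
]

ACTIVATION = "activation"
INHIBITION = "inhibition"

_SCHEMES = ("inhibitor_dominant", "activator_dominant")


class RuleParseError(ValueError):
    """Raised when rule text violates the dialect."""


@dataclass(frozen=True)
class GeneNode:
    """A network vertex: gene symbol plus its position in the canonical order."""

    symbol: str
    index: int


@dataclass(frozen=True)
class SignedEdge:
    """Directed regulatory edge with sign and provenance."""

    source: str
    target: str
    sign: str  # ACTIVATION | INHIBITION
    provenance: str = "manual"  # interactome | intermediary | tf_table | manual

    def __post_init__(self) -> None:
        if self.sign not in (ACTIVATION, INHIBITION):
            raise ValueError(f"unknown edge sign {self.sign!r}")


class NetworkState:
    """Fixed-length bit vector indexed by gene index."""

    __slots__ = ("bits",)

    def __init__(self, bits: Iterable[int]):
        self.bits = tuple(int(b) for b in bits)
        if any(b not in (0, 1) for b in self.bits):
            raise ValueError("state bits must be 0 or 1")

    def __len__(self) -> int:
        return len(self.bits)

    def __getitem__(self, i: int) -> int:
        return self.bits[i]

    def __iter__(self):
        return iter(self.bits)

    def __eq__(self, other) -> bool:
        return isinstance(other, NetworkState) and self.bits == other.bits

    def __lt__(self, other: "NetworkState") -> bool:
        return self.bits < other.bits

    def __hash__(self) -> int:
        return hash(self.bits)

    def __repr__(self) -> str:
        return f"NetworkState({self.packed()})"

    def packed(self) -> str:
        """State as a compact 0/1 string, gene order."""
        return "".join(str(b) for b in self.bits)

    @classmethod
    def from_packed(cls, s: str) -> "NetworkState":
        return cls(int(c) for c in s)


# ---------------------------------------------------------------------------
# Boolean expression AST: ("var", name) | ("not", node) |
# ("and", (nodes...)) | ("or", (nodes...)).  n-ary and/or are kept flat so
# that parse -> text -> parse is the identity.
# ---------------------------------------------------------------------------

Node = tuple


def _flatten(op: str, nodes: Sequence[Node]) -> Node:
    out: list[Node] = []
    for n in nodes:
        if n[0] == op:
            out.extend(n[1])
        else:
            out.append(n)
    if len(out) == 1:
        return out[0]
    return (op, tuple(out))


def expression_to_text(node: Node) -> str:
    """Render an AST in the canonical minimal-parenthesis form."""
    op = node[0]
    if op == "var":
        return node[1]
    if op == "not":
        child = node[1]
        inner = expression_to_text(child)
        if child[0] != "var":
            inner = f"({inner})"
        return f"not {inner}"
    parts = []
    for child in node[1]:
        text = expression_to_text(child)
        if op == "and" and child[0] == "or":
            text = f"({text})"
        parts.append(text)
    return f" {op} ".join(parts)


def evaluate_expression(node: Node, values: Mapping[str, int]) -> int:
    """Evaluate an AST against a symbol -> bit mapping."""
    op = node[0]
    if op == "var":
        return int(values[node[1]])
    if op == "not":
        return 1 - evaluate_expression(node[1], values)
    if op == "and":
        return int(all(evaluate_expression(c, values) for c in node[1]))
    if op == "or":
        return int(any(evaluate_expression(c, values) for c in node[1]))
    raise ValueError(f"bad node {node!r}")


def expression_symbols(node: Node) -> list[str]:
    """Symbols in token order of first appearance."""
    out: list[str] = []

    def walk(n: Node) -> None:
        if n[0] == "var":
            if n[1] not in out:
                out.append(n[1])
        elif n[0] == "not":
            walk(n[1])
        else:
            for c in n[1]:
                walk(c)

    walk(node)
    return out


def expression_polarities(node: Node) -> dict[str, set[bool]]:
    """Map symbol -> set of polarities (True = appears non-negated)."""
    pol: dict[str, set[bool]] = {}

    def walk(n: Node, positive: bool) -> None:
        if n[0] == "var":
            pol.setdefault(n[1], set()).add(positive)
        elif n[0] == "not":
            walk(n[1], not positive)
        else:
            for c in n[1]:
                walk(c, positive)

    walk(node, True)
    return pol


_ALIASES = {"∧": " and ", "⋀": " and ", "∨": " or ", "⋁": " or ",
            "¬": " not ", "&": " and ", "|": " or ", "!": " not "}

_TOKEN_RE = re.compile(r"\s*(\(|\)|[A-Za-z0-9_.\-]+)")


def _tokenize(text: str, line_no: int) -> list[str]:
    for alias, repl in _ALIASES.items():
        text = text.replace(alias, repl)
    tokens: list[str] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m:
            if text[pos:].strip():
                raise RuleParseError(
                    f"line {line_no}: cannot tokenize {text[pos:].strip()!r}")
            break
        tokens.append(m.group(1))
        pos = m.end()
    return tokens


def parse_expression(text: str, line_no: int = 0) -> Node:
    """Parse a Boolean expression into the AST form."""
    tokens = _tokenize(text, line_no)
    if not tokens:
        raise RuleParseError(f"line {line_no}: empty expression")
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> Node:
        parts = [parse_and()]
        while peek() == "or":
            take()
            parts.append(parse_and())
        return _flatten("or", parts)

    def parse_and() -> Node:
        parts = [parse_not()]
        while peek() == "and":
            take()
            parts.append(parse_not())
        return _flatten("and", parts)

    def parse_not() -> Node:
        if peek() == "not":
            take()
            return ("not", parse_not())
        return parse_atom()

    def parse_atom() -> Node:
        tok = peek()
        if tok is None:
            raise RuleParseError(f"line {line_no}: unexpected end of expression")
        if tok == "(":
            take()
            node = parse_or()
            if peek() != ")":
                raise RuleParseError(f"line {line_no}: missing ')'")
            take()
            return node
        if tok in (")", "and", "or", "not"):
            raise RuleParseError(f"line {line_no}: unexpected token {tok!r}")
        return ("var", take())

    node = parse_or()
    if pos != len(tokens):
        raise RuleParseError(
            f"line {line_no}: trailing tokens {' '.join(tokens[pos:])!r}")
    return node


@dataclass
class NestedCanalyzingRule:
    """Update rule of one gene.

    ``expr`` is the Boolean AST; ``source_text`` its canonical rendering.
    For rules produced by :func:`build_ncf`, ``activators``/``inhibitors``
    record the regulator split and ``scheme`` the dominance convention; for
    parsed free-form rules they are derived from literal polarity.
    """

    target: str
    expr: Node
    source_text: str = ""
    activators: tuple[str, ...] = ()
    inhibitors: tuple[str, ...] = ()
    scheme: str | None = None

    def __post_init__(self) -> None:
        if not self.source_text:
            self.source_text = expression_to_text(self.expr)

    @property
    def regulators(self) -> list[str]:
        return expression_symbols(self.expr)

    @property
    def is_identity(self) -> bool:
        return self.expr == ("var", self.target)

    def clauses(self) -> list[tuple[tuple[str, ...], int]]:
        """Canalyzing clause view: (literal set, forced output) in dominance order.

        For inhibitor_dominant, any inhibitor at 1 forces 0; then any
        activator at 1 yields 1.  For activator_dominant, any activator at 1
        forces 1; then all inhibitors at 0 yields 1.
        """
        if self.scheme == "inhibitor_dominant":
            out = [((i,), 0) for i in self.inhibitors]
            out += [((a,), 1) for a in self.activators]
            return out
        if self.scheme == "activator_dominant":
            out = [((a,), 1) for a in self.activators]
            out += [((i,), 0) for i in self.inhibitors]
            return out
        return []

    def evaluate(self, values: Mapping[str, int]) -> int:
        return evaluate_expression(self.expr, values)


def build_ncf(target: str,
              activators: Sequence[str],
              inhibitors: Sequence[str],
              scheme: str = "inhibitor_dominant") -> NestedCanalyzingRule:
    """Build the nested canalyzing rule for one gene from its signed regulators.

    inhibitor_dominant: ``(not i1 and ... and not im) and (a1 or ... or ak)``
    — any active inhibitor forces the gene off, otherwise any active
    activator turns it on.  activator_dominant: ``(a1 or ...) or not
    (i1 or ...)`` — any active activator wins.  With only one class of
    regulator the rule degenerates to the OR of activators, resp. the AND of
    negated inhibitors.
    """
    activators = tuple(activators)
    inhibitors = tuple(inhibitors)
    if scheme not in _SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {_SCHEMES}")
    if not activators and not inhibitors:
        raise ValueError(
            f"gene {target!r} has no regulators; declare it a frozen input "
            "(rule: identity) instead of building an NCF")
    overlap = set(activators) & set(inhibitors)
    if overlap:
        raise ValueError(
            f"gene {target!r}: regulators {sorted(overlap)} listed as both "
            "activator and inhibitor")

    act_or = _flatten("or", [("var", a) for a in activators]) if activators else None
    if scheme == "inhibitor_dominant":
        inh_and = (_flatten("and", [("not", ("var", i)) for i in inhibitors])
                   if inhibitors else None)
        if inh_and is None:
            expr = act_or
        elif act_or is None:
            expr = inh_and
        else:
            expr = _flatten("and", [inh_and, act_or])
    else:
        inh_not = (("not", _flatten("or", [("var", i) for i in inhibitors]))
                   if inhibitors else None)
        if inh_not is None:
            expr = act_or
        elif act_or is None:
            expr = inh_not
        else:
            expr = _flatten("or", [act_or, inh_not])
    return NestedCanalyzingRule(target=target, expr=expr,
                                activators=activators, inhibitors=inhibitors,
                                scheme=scheme)


class BooleanNetwork:
    """Ordered genes, signed edges, one rule per gene (Boolean transition map)."""

    def __init__(self, genes: Sequence[str],
                 rules: Mapping[str, NestedCanalyzingRule],
                 edges: Sequence[SignedEdge] | None = None):
        self.genes: list[GeneNode] = [GeneNode(g, i) for i, g in enumerate(genes)]
        if len({g.symbol for g in self.genes}) != len(self.genes):
            raise ValueError("duplicate gene symbols")
        self.index: dict[str, int] = {g.symbol: g.index for g in self.genes}
        self.rules: dict[str, NestedCanalyzingRule] = {}
        for g in self.genes:
            if g.symbol not in rules:
                raise ValueError(f"gene {g.symbol!r} has no rule")
            self.rules[g.symbol] = rules[g.symbol]
        for sym, rule in self.rules.items():
            for reg in rule.regulators:
                if reg not in self.index:
                    raise ValueError(
                        f"rule for {sym!r} references unknown gene {reg!r}")
        if edges is None:
            edges = derive_edges(self.rules.values())
        self.edges: list[SignedEdge] = list(edges)
        self._compiled: list[Callable[[tuple], int]] | None = None

    @property
    def n(self) -> int:
        return len(self.genes)

    @property
    def symbols(self) -> list[str]:
        return [g.symbol for g in self.genes]

    @property
    def frozen_inputs(self) -> list[str]:
        return [g.symbol for g in self.genes if self.rules[g.symbol].is_identity]

    def state(self, bits: Iterable[int]) -> NetworkState:
        s = NetworkState(bits)
        if len(s) != self.n:
            raise ValueError(f"state length {len(s)} != network size {self.n}")
        return s

    def _compile(self) -> list[Callable[[tuple], int]]:
        """Compile each rule AST into a closure over the bit tuple (index-resolved)."""
        if self._compiled is not None:
            return self._compiled

        def comp(node: Node) -> Callable[[tuple], int]:
            op = node[0]
            if op == "var":
                i = self.index[node[1]]
                return lambda bits, i=i: bits[i]
            if op == "not":
                f = comp(node[1])
                return lambda bits, f=f: 1 - f(bits)
            subs = tuple(comp(c) for c in node[1])
            if op == "and":
                return lambda bits, subs=subs: int(all(f(bits) for f in subs))
            return lambda bits, subs=subs: int(any(f(bits) for f in subs))

        self._compiled = [comp(self.rules[g.symbol].expr) for g in self.genes]
        return self._compiled

    def step_bits(self, bits: tuple) -> tuple:
        """One synchronous update on a raw bit tuple (all rules see the old state)."""
        fns = self._compile()
        return tuple(f(bits) for f in fns)

    def __eq__(self, other) -> bool:
        if not isinstance(other, BooleanNetwork):
            return NotImplemented
        return (self.symbols == other.symbols and
                {g: r.source_text for g, r in self.rules.items()} ==
                {g: r.source_text for g, r in other.rules.items()})

    def __repr__(self) -> str:
        return f"BooleanNetwork(n={self.n}, edges={len(self.edges)})"

    # -- exports -----------------------------------------------------------
    def to_edge_list(self) -> list[tuple[str, str, str]]:
        return [(e.source, e.target, e.sign) for e in self.edges]

    def to_json(self) -> str:
        return json.dumps({
            "genes": self.symbols,
            "edges": [{"source": e.source, "target": e.target,
                       "sign": e.sign, "provenance": e.provenance}
                      for e in self.edges],
            "rules": {g: self.rules[g].source_text for g in self.symbols},
        }, indent=2, sort_keys=False)


def derive_edges(rules: Iterable[NestedCanalyzingRule]) -> list[SignedEdge]:
    """Infer signed edges from rule literal polarity.

    A regulator appearing under odd negation anywhere in the rule is
    recorded as inhibition, otherwise activation; (source, target) unique.
    """
    edges: list[SignedEdge] = []
    for rule in rules:
        if rule.is_identity:
            continue
        pol = expression_polarities(rule.expr)
        for reg in rule.regulators:
            sign = INHIBITION if False in pol[reg] else ACTIVATION
            edges.append(SignedEdge(reg, rule.target, sign))
    return edges


def evaluate_rule(rule: NestedCanalyzingRule, state: NetworkState,
                  index: Mapping[str, int]) -> int:
    """Evaluate one rule against a network state (pure; state untouched)."""
    values = {sym: state[i] for sym, i in index.items()}
    return rule.evaluate(values)


# ---------------------------------------------------------------------------
# Rule-file dialect
# ---------------------------------------------------------------------------

_RULE_LINE_RE = re.compile(r"^\s*([A-Za-z0-9_.\-]+)\s*\*\s*=\s*(.+)$")


def parse_rules(text: str, frozen_inputs: Iterable[str] = ()) -> BooleanNetwork:
    """Parse rule text into a network; gene order is first appearance.

    Frozen inputs may be declared with an ``inputs:`` line, via the
    ``frozen_inputs`` argument, or as explicit identity rules.  A right-hand
    symbol with neither a rule line nor an input declaration is an error.
    An optional ``genes:`` line fixes the canonical order (written by
    :func:`write_rules` so round-trips preserve order).
    """
    declared_order: list[str] | None = None
    order: list[str] = []
    frozen: list[str] = list(frozen_inputs)
    rule_lines: list[tuple[int, str, str]] = []

    def see(sym: str) -> None:
        if sym not in order:
            order.append(sym)

    any_content = False
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        any_content = True
        low = line.lower()
        if low.startswith("genes:"):
            declared_order = line.split(":", 1)[1].replace(",", " ").split()
            continue
        if low.startswith("inputs:"):
            for sym in line.split(":", 1)[1].replace(",", " ").split():
                frozen.append(sym)
                see(sym)
            continue
        m = _RULE_LINE_RE.match(line)
        if not m:
            raise RuleParseError(f"line {line_no}: not a rule line: {line!r}")
        target, rhs = m.group(1), m.group(2)
        rule_lines.append((line_no, target, rhs))
        see(target)
        for sym in expression_symbols(parse_expression(rhs, line_no)):
            see(sym)
    if not any_content:
        raise RuleParseError("empty rule text")
    if not rule_lines and not frozen:
        raise RuleParseError("no rules found")

    rules: dict[str, NestedCanalyzingRule] = {}
    for line_no, target, rhs in rule_lines:
        if target in rules:
            raise RuleParseError(
                f"line {line_no}: duplicate rule for gene {target!r}")
        expr = parse_expression(rhs, line_no)
        rules[target] = NestedCanalyzingRule(target=target, expr=expr)
    for sym in frozen:
        if sym not in rules:
            rules[sym] = NestedCanalyzingRule(target=sym, expr=("var", sym))

    for line_no, target, rhs in rule_lines:
        for sym in rules[target].regulators:
            if sym not in rules:
                raise RuleParseError(
                    f"line {line_no}: symbol {sym!r} in rule for {target!r} "
                    "has no rule line and is not a declared input")

    if declared_order is not None:
        missing = [s for s in order if s not in declared_order]
        if missing:
            raise RuleParseError(
                f"genes: directive omits symbols {missing}")
        order = [s for s in declared_order if s in rules]
    return BooleanNetwork(order, rules)


def write_rules(net: BooleanNetwork) -> str:
    """Serialize a network to canonical rule text (round-trips via parse_rules)."""
    lines = ["genes: " + " ".join(net.symbols)]
    frozen = net.frozen_inputs
    if frozen:
        lines.append("inputs: " + " ".join(frozen))
    for g in net.symbols:
        rule = net.rules[g]
        if rule.is_identity:
            continue
        lines.append(f"{g}* = {rule.source_text}")
    return "\n".join(lines) + "\n"
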