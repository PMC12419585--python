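"""Boolean network representation and BoolNet-style rule file I/O.

A :class:`BooleanNetwork` stores, for each gene, an ordered parent list and a
truth table of ``2**len(parents)`` output bits.  Truth-table rows are indexed
by binary counting over the parents in listed order, with the *first* parent
as the most significant bit: for parents ``(B, C)`` row order is
``(B,C) = 00, 01, 10, 11``.

Rule files use the BoolNet text convention::

    targets, factors
    A, B & !C
    B, 1
    C, A | B

Expressions are built from gene names, ``!`` (not), ``&`` (and), ``|`` (or),
parentheses and the constants ``0``/``1``.  Genes clamped to a fixed value are
written as constants.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field


class RuleFormatError(ValueError):
    """Raised for malformed rule files; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass
class BooleanNetwork:
    """A synchronous Boolean network over an ordered gene list.

    Parameters
    ----------
    genes
        Ordered gene identifiers.  Bit ``i`` of a packed network state holds
        the state of ``genes[i]``.
    parents
        Map gene -> ordered list of parent genes (empty list = constant gene).
    truth_tables
        Map gene -> tuple of ``2**len(parents)`` output bits, row order as in
        the module docstring.
    clamped
        Map gene -> {0, 1}.  Clamped genes ignore their rule during dynamics.
    """

    genes: list[str]
    parents: dict[str, list[str]]
    truth_tables: dict[str, tuple[int, ...]]
    clamped: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene identifiers")
        for g in self.genes:
            ps = self.parents.get(g)
            tt = self.truth_tables.get(g)
            if ps is None or tt is None:
                raise ValueError(f"gene {g!r} lacks parents or truth table")
            if len(tt) != 2 ** len(ps):
                raise ValueError(
                    f"gene {g!r}: truth table length {len(tt)} != 2^{len(ps)}"
                )
            if any(b not in (0, 1) for b in tt):
                raise ValueError(f"gene {g!r}: truth table entries must be 0/1")
            unknown = set(ps) - set(self.genes)
            if unknown:
                raise ValueError(f"gene {g!r}: unknown parents {sorted(unknown)}")
        for g, v in self.clamped.items():
            if g not in self.parents:
                raise ValueError(f"clamped gene {g!r} not in network")
            if v not in (0, 1):
                raise ValueError(f"clamp value for {g!r} must be 0/1")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def index(self, gene: str) -> int:
        return self.genes.index(gene)

    def with_clamped(self, clamped: dict[str, int]) -> "BooleanNetwork":
        """Return a copy with the given clamp assignments (replacing any)."""
        return BooleanNetwork(
            genes=list(self.genes),
            parents={g: list(p) for g, p in self.parents.items()},
            truth_tables=dict(self.truth_tables),
            clamped=dict(clamped),
        )

    def evaluate_gene(self, gene: str, state: dict[str, int]) -> int:
        """Evaluate one gene's rule on a gene->bit state mapping."""
        ps = self.parents[gene]
        idx = 0
        for p in ps:
            idx = (idx << 1) | state[p]
        return self.truth_tables[gene][idx]

    # -- serialization --------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "genes": self.genes,
                "parents": self.parents,
                "truth_tables": {g: list(t) for g, t in self.truth_tables.items()},
                "clamped": self.clamped,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "BooleanNetwork":
        d = json.loads(text)
        return cls(
            genes=list(d["genes"]),
            parents={g: list(p) for g, p in d["parents"].items()},
            truth_tables={g: tuple(t) for g, t in d["truth_tables"].items()},
            clamped={g: int(v) for g, v in d.get("clamped", {}).items()},
        )


# ---------------------------------------------------------------------------
# Expression parsing (recursive descent: OR < AND < NOT < atom)
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\s*(?:(\()|(\))|(!)|(&)|(\|)|([A-Za-z_][\w.\-]*|[01]))")


def _tokenize(expr: str, line: int | None) -> list[str]:
    tokens: list[str] = []
    pos = 0
    while pos < len(expr):
        m = _TOKEN_RE.match(expr, pos)
        if m is None:
            if expr[pos:].strip():
                raise RuleFormatError(
                    f"unexpected character {expr[pos:].strip()[0]!r}", line
                )
            break
        tokens.append(next(g for g in m.groups() if g is not None))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, tokens: list[str], line: int | None):
        self.tokens = tokens
        self.i = 0
        self.line = line
        self.variables: list[str] = []  # order of first appearance

    def peek(self) -> str | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise RuleFormatError("unexpected end of expression", self.line)
        self.i += 1
        return tok

    def parse(self):
        node = self.parse_or()
        if self.peek() is not None:
            raise RuleFormatError(f"trailing token {self.peek()!r}", self.line)
        return node

    def parse_or(self):
        node = self.parse_and()
        while self.peek() == "|":
            self.next()
            node = ("or", node, self.parse_and())
        return node

    def parse_and(self):
        node = self.parse_not()
        while self.peek() == "&":
            self.next()
            node = ("and", node, self.parse_not())
        return node

    def parse_not(self):
        if self.peek() == "!":
            self.next()
            return ("not", self.parse_not())
        return self.parse_atom()

    def parse_atom(self):
        tok = self.next()
        if tok == "(":
            node = self.parse_or()
            if self.next() != ")":
                raise RuleFormatError("unbalanced parentheses", self.line)
            return node
        if tok in ("0", "1"):
            return ("const", int(tok))
        if tok in (")", "&", "|", "!"):
            raise RuleFormatError(f"unexpected token {tok!r}", self.line)
        if tok not in self.variables:
            self.variables.append(tok)
        return ("var", tok)


def _eval_node(node, env: dict[str, int]) -> int:
    op = node[0]
    if op == "const":
        return node[1]
    if op == "var":
        return env[node[1]]
    if op == "not":
        return 1 - _eval_node(node[1], env)
    if op == "and":
        return _eval_node(node[1], env) & _eval_node(node[2], env)
    if op == "or":
        return _eval_node(node[1], env) | _eval_node(node[2], env)
    raise AssertionError(op)


def parse_rule_expression(
    expr: str, line: int | None = None
) -> tuple[list[str], tuple[int, ...]]:
    """Compile a rule expression into (parents, truth table).

    Parents are ordered by first appearance in the expression; the table is
    built by evaluating the expression on all parent assignments in binary
    counting order (first parent = most significant bit).
    """
    tokens = _tokenize(expr, line)
    if not tokens:
        raise RuleFormatError("empty rule expression", line)
    parser = _Parser(tokens, line)
    node = parser.parse()
    parents = parser.variables
    k = len(parents)
    table = []
    for row in range(2 ** k):
        env = {p: (row >> (k - 1 - j)) & 1 for j, p in enumerate(parents)}
        table.append(_eval_node(node, env))
    return parents, tuple(table)


def format_rule(parents: list[str], table: tuple[int, ...]) -> str:
    """Render a truth table as a rule expression (disjunctive normal form).

    Constant-output tables render as ``0``/``1`` (parent list dropped — the
    function does not depend on them).
    """
    k = len(parents)
    if all(b == 0 for b in table):
        return "0"
    if all(b == 1 for b in table):
        return "1"
    terms = []
    for row in range(2 ** k):
        if table[row]:
            lits = []
            for j, p in enumerate(parents):
                bit = (row >> (k - 1 - j)) & 1
                lits.append(p if bit else f"!{p}")
            terms.append("(" + " & ".join(lits) + ")" if len(lits) > 1 else lits[0])
    return " | ".join(terms)


def write_rules(network: BooleanNetwork, path) -> None:
    """Write a network in BoolNet-style rule text.

    Clamped genes are written as constant rules at their clamped value.
    """
    lines = ["targets, factors"]
    for g in network.genes:
        if g in network.clamped:
            lines.append(f"{g}, {network.clamped[g]}")
        else:
            lines.append(
                f"{g}, {format_rule(network.parents[g], network.truth_tables[g])}"
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_rules(path) -> BooleanNetwork:
    """Parse a BoolNet-style rule file into a :class:`BooleanNetwork`.

    Raises
    ------
    RuleFormatError
        On a malformed header, a malformed expression, or a right-hand-side
        gene that is not itself defined by a rule line (the error names the
        offending line number).
    """
    with open(path) as fh:
        raw = fh.read().splitlines()
    lines = [(i + 1, ln) for i, ln in enumerate(raw) if ln.strip()]
    if not lines:
        raise RuleFormatError("empty rule file")
    header_no, header = lines[0]
    if [w.strip().lower() for w in header.split(",")] != ["targets", "factors"]:
        raise RuleFormatError("expected header 'targets, factors'", header_no)

    genes: list[str] = []
    parents: dict[str, list[str]] = {}
    tables: dict[str, tuple[int, ...]] = {}
    for line_no, ln in lines[1:]:
        if "," not in ln:
            raise RuleFormatError("expected 'target, expression'", line_no)
        target, expr = ln.split(",", 1)
        target = target.strip()
        if not target:
            raise RuleFormatError("missing target gene", line_no)
        if target in parents:
            raise RuleFormatError(f"duplicate rule for gene {target!r}", line_no)
        ps, table = parse_rule_expression(expr, line_no)
        genes.append(target)
        parents[target] = ps
        tables[target] = table

    known = set(genes)
    for line_no, ln in lines[1:]:
        target = ln.split(",", 1)[0].strip()
        for p in parents[target]:
            if p not in known:
                raise RuleFormatError(
                    f"rule for {target!r} references undefined gene {p!r}", line_no
                )
    return BooleanNetwork(genes=genes, parents=parents, truth_tables=tables)
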