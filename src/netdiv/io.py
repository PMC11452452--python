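"""Reading and writing networks: extended Newick and edge-list TSV.

Extended Newick (eNewick) represents a network with reticulations by
tagging hybrid nodes with ``#LABEL``: one occurrence carries the node's
subtree expanded in place, every other occurrence is the bare tag, and
all occurrences with the same tag are merged into a single reticulation
node.  The branch length after each occurrence is the weight of that
occurrence's incoming arc.  Example (a galled tree with reticulation H1)::

    (((x1:2,(x2:0.2)#H1:0.5)p:2,(x3:2,#H1:0.3)q:2)s:1,x4:4)r;

Branch lengths are parsed as exact :class:`fractions.Fraction`; a
missing length defaults to ``default_weight`` (1 by default).

The edge-list format is a TSV with header ``parent<TAB>child<TAB>weight``,
one arc per row; a node that never appears in the ``parent`` column is a
leaf and its label is its node id.
"""

from __future__ import annotations

from fractions import Fraction
from numbers import Real

import networkx as nx

from .network import NetworkValidationError, PhyloNetwork, validate

__all__ = [
    "EnewickParseError",
    "read_enewick",
    "write_enewick",
    "read_edgelist",
    "write_edgelist",
]

_LABEL_END = set(":,();#\t\n ")


class EnewickParseError(ValueError):
    """Syntax error in an eNewick string; carries the character offset."""

    def __init__(self, message: str, offset: int):
        self.offset = offset
        super().__init__(f"{message} (at offset {offset})")


class _Parser:
    def __init__(self, text: str, default_weight: Real):
        self.text = text
        self.i = 0
        self.default = default_weight
        self.g = nx.DiGraph()
        self.n_anon = 0
        # hybrid tag -> node id
        self.hybrids: dict[str, str] = {}
        self.hybrid_expanded: dict[str, bool] = {}

    def error(self, msg: str):
        raise EnewickParseError(msg, self.i)

    def peek(self) -> str:
        return self.text[self.i] if self.i < len(self.text) else ""

    def skip_ws(self):
        while self.peek() in " \t\n\r" and self.peek():
            self.i += 1

    def fresh_id(self) -> str:
        self.n_anon += 1
        return f"_n{self.n_anon}"

    def read_label(self) -> str:
        start = self.i
        while self.peek() and self.peek() not in _LABEL_END:
            self.i += 1
        return self.text[start:self.i]

    def read_number(self) -> Fraction:
        start = self.i
        while self.peek() and self.peek() not in ",();:#\t\n ":
            self.i += 1
        token = self.text[start:self.i]
        try:
            value = Fraction(token)
        except (ValueError, ZeroDivisionError):
            self.i = start
            self.error(f"invalid branch length {token!r}")
        if value < 0:
            self.i = start
            self.error(f"negative branch length {token!r}")
        return value

    def parse(self) -> PhyloNetwork:
        self.skip_ws()
        root, _ = self.parse_node(is_root=True)
        self.skip_ws()
        if self.peek() != ";":
            self.error("expected ';'")
        self.i += 1
        self.skip_ws()
        if self.i != len(self.text):
            self.error("trailing characters after ';'")
        # all hybrid tags must have been expanded exactly once
        for tag, expanded in self.hybrid_expanded.items():
            if not expanded:
                self.error(f"hybrid tag #{tag} never expanded with a subtree")
        self._check_duplicate_leaves()
        problems = validate(self.g)
        if problems:
            raise NetworkValidationError(problems)
        return PhyloNetwork(self.g)

    def _check_duplicate_leaves(self):
        # leaves are identified with their labels; a repeated leaf label
        # collapses into one node, which we must reject explicitly
        seen = [
            v for v in self.g
            if self.g.out_degree(v) == 0 and self.g.nodes[v].get("n_occurrences", 1) > 1
        ]
        if seen:
            raise NetworkValidationError(
                [f"duplicate leaf label {v!r}" for v in sorted(seen)]
            )

    def parse_node(self, is_root: bool = False) -> tuple[str, Fraction | None]:
        """Parse one node clause; returns (node id, incoming-arc weight)."""
        self.skip_ws()
        children: list[tuple[str, Fraction | None]] = []
        has_subtree = False
        if self.peek() == "(":
            has_subtree = True
            self.i += 1
            while True:
                children.append(self.parse_node())
                self.skip_ws()
                if self.peek() == ",":
                    self.i += 1
                    continue
                if self.peek() == ")":
                    self.i += 1
                    break
                self.error("expected ',' or ')'")
        name = self.read_label()
        hybrid_tag = None
        if self.peek() == "#":
            self.i += 1
            hybrid_tag = self.read_label()
            if not hybrid_tag:
                self.error("empty hybrid tag after '#'")
        length: Fraction | None = None
        if self.peek() == ":":
            self.i += 1
            length = self.read_number()

        if hybrid_tag is not None:
            node = self.hybrids.get(hybrid_tag)
            if node is None:
                node = name if name else hybrid_tag
                if node in self.g and not name:
                    node = self.fresh_id()
                self.hybrids[hybrid_tag] = node
                self.hybrid_expanded[hybrid_tag] = False
                self.g.add_node(node)
            if has_subtree:
                if self.hybrid_expanded[hybrid_tag]:
                    self.error(f"hybrid tag #{hybrid_tag} expanded more than once")
                self.hybrid_expanded[hybrid_tag] = True
        elif not has_subtree:
            # leaf: its id is its label
            if not name:
                self.error("leaf without a label")
            node = name
            if node in self.g:
                self.g.nodes[node]["n_occurrences"] = (
                    self.g.nodes[node].get("n_occurrences", 1) + 1
                )
            else:
                self.g.add_node(node, n_occurrences=1)
        else:
            node = name if name else self.fresh_id()
            if name and node in self.g:
                self.error(f"duplicate internal node name {name!r}")
            self.g.add_node(node)

        for child, w in children:
            if self.g.has_edge(node, child):
                if self.g.nodes[child].get("n_occurrences", 1) > 1:
                    raise NetworkValidationError(
                        [f"duplicate leaf label {child!r}"]
                    )
                self.error(f"duplicate arc from {node!r} to {child!r}")
            self.g.add_edge(node, child, weight=w if w is not None else self.default)
        if is_root and length is not None:
            self.error("root must not carry a branch length")
        return node, length


def read_enewick(text: str, default_weight: Real = Fraction(1)) -> PhyloNetwork:
    """Parse a single ``;``-terminated eNewick statement into a network.

    Raises :class:`EnewickParseError` on syntax errors (with character
    offset) and :class:`~netdiv.network.NetworkValidationError` when the
    parsed graph violates the network axioms.
    """
    return _Parser(text, default_weight).parse()


def _fmt_weight(w: Real) -> str:
    if isinstance(w, Fraction):
        if w.denominator == 1:
            return str(w.numerator)
        f = float(w)
        if Fraction(repr(f)) == w:
            return repr(f)
        return f"{w.numerator}/{w.denominator}"
    if isinstance(w, int):
        return str(w)
    return repr(float(w))


def write_enewick(net: PhyloNetwork) -> str:
    """Serialize a network to eNewick.

    The first encounter of each reticulation (children visited in
    sorted order) expands its subtree; later encounters emit the bare
    tag.  Node ids are written as names (a reticulation's id becomes
    its hybrid tag), so the output re-parses to an arc-set- and
    weight-identical network.
    """
    expanded: set[str] = set()

    def visit(v: str) -> str:
        if net.is_reticulation(v):
            if v in expanded:
                return f"#{v}"
            expanded.add(v)
            inner = ",".join(
                visit(c) + ":" + _fmt_weight(net.weight(v, c))
                for c in net.children(v)
            )
            return f"({inner})#{v}"
        if net.graph.out_degree(v) == 0:
            return v
        inner = ",".join(
            visit(c) + ":" + _fmt_weight(net.weight(v, c))
            for c in net.children(v)
        )
        return f"({inner}){v}"

    return visit(net.root) + ";"


def read_edgelist(text: str) -> PhyloNetwork:
    """Parse the ``parent<TAB>child<TAB>weight`` TSV format."""
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise NetworkValidationError(["no root (empty edge list)"])
    header = lines[0].split("\t")
    if [h.strip().lower() for h in header[:3]] != ["parent", "child", "weight"]:
        raise ValueError(
            f"expected header 'parent\\tchild\\tweight', got {lines[0]!r}"
        )
    g = nx.DiGraph()
    for ln in lines[1:]:
        parts = ln.split("\t")
        if len(parts) != 3:
            raise ValueError(f"malformed row (need 3 tab-separated fields): {ln!r}")
        u, v, wtxt = (p.strip() for p in parts)
        try:
            w = Fraction(wtxt)
        except (ValueError, ZeroDivisionError):
            raise ValueError(f"weight is not a number in row {ln!r}")
        if w < 0:
            raise ValueError(f"negative weight in row {ln!r}")
        if g.has_edge(u, v):
            raise ValueError(f"duplicate arc in row {ln!r}")
        g.add_edge(u, v, weight=w)
    problems = validate(g)
    if problems:
        raise NetworkValidationError(problems)
    return PhyloNetwork(g)


def write_edgelist(net: PhyloNetwork) -> str:
    """Serialize to the TSV edge-list format (rows sorted for diffability)."""
    rows = ["parent\tchild\tweight"]
    for u, v in sorted(net.arcs):
        rows.append(f"{u}\t{v}\t{_fmt_weight(net.weight(u, v))}")
    return "\n".join(rows) + "\n"
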