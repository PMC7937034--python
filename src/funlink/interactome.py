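"""Core graph data model for functional interactomes.

An :class:`Interactome` is an undirected simple graph over canonical gene
identifiers (HGNC-style symbols).  Each edge carries a confidence score in
[0, 1] and a provenance tag (``predicted`` or ``experimental``).  The class
is a thin, invariant-enforcing wrapper around :class:`networkx.Graph`; all
set-level edge queries used by the GSLA and guilt-by-association modules
live here.

Edge lists are exchanged as tab-separated text with a header row
(``geneA  geneB  score  source``); lines starting with ``#`` are comments.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Iterator
from pathlib import Path

import networkx as nx

from .errors import ParseError, ValidationError

PREDICTED = "predicted"
EXPERIMENTAL = "experimental"
_SOURCES = (PREDICTED, EXPERIMENTAL)


def _check_gene(g: str) -> str:
    if not isinstance(g, str) or not g:
        raise ValidationError(f"gene id must be a non-empty string, got {g!r}")
    if any(ch.isspace() for ch in g):
        raise ValidationError(f"gene id {g!r} contains whitespace")
    return g


@dataclasses.dataclass(frozen=True, order=True)
class Interaction:
    """One undirected gene-gene association.

    Endpoints are stored in lexicographic order so that ``{a, b}`` and
    ``{b, a}`` compare equal; gene ids are case-sensitive exact strings.
    """

    a: str
    b: str
    score: float = 1.0
    source: str = PREDICTED

    def __post_init__(self) -> None:
        _check_gene(self.a)
        _check_gene(self.b)
        if self.a == self.b:
            raise ValidationError(f"self-pair {self.a!r} is not allowed")
        if not (0.0 <= self.score <= 1.0):
            raise ValidationError(f"score {self.score} outside [0, 1]")
        if self.source not in _SOURCES:
            raise ValidationError(f"source must be one of {_SOURCES}, got {self.source!r}")
        if self.b < self.a:  # canonical endpoint order
            a, b = self.a, self.b
            object.__setattr__(self, "a", b)
            object.__setattr__(self, "b", a)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.a, self.b)


def _canon(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


class Interactome:
    """Undirected simple graph of scored gene-gene functional associations."""

    def __init__(self, interactions: Iterable[Interaction] = (), genes: Iterable[str] = ()):
        self._g = nx.Graph()
        for g in genes:
            self.add_gene(g)
        for it in interactions:
            self.add_interaction(it)

    # -- construction -------------------------------------------------

    def add_gene(self, g: str) -> None:
        self._g.add_node(_check_gene(g))

    def add_edge(self, a: str, b: str, score: float = 1.0, source: str = PREDICTED) -> None:
        """Add one association; a duplicate unordered pair keeps the higher
        score (ties resolved in favour of experimental provenance)."""
        self.add_interaction(Interaction(a, b, score, source))

    def add_interaction(self, it: Interaction) -> None:
        a, b = it.pair
        if self._g.has_edge(a, b):
            old = self._g.edges[a, b]
            if it.score > old["score"] or (
                it.score == old["score"] and it.source == EXPERIMENTAL
            ):
                old["score"] = it.score
                old["source"] = it.source
        else:
            self._g.add_edge(a, b, score=it.score, source=it.source)

    # -- basic queries -------------------------------------------------

    @property
    def genes(self) -> set[str]:
        return set(self._g.nodes)

    @property
    def n_genes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def has_gene(self, g: str) -> bool:
        return self._g.has_node(g)

    def has_edge(self, a: str, b: str) -> bool:
        return self._g.has_edge(a, b)

    def interactions(self) -> Iterator[Interaction]:
        for a, b, d in self._g.edges(data=True):
            x, y = _canon(a, b)
            yield Interaction(x, y, d["score"], d["source"])

    def edge_pairs(self) -> set[tuple[str, str]]:
        """The edge set as canonical (lexicographically ordered) pairs."""
        return {_canon(a, b) for a, b in self._g.edges}

    def degree(self, g: str) -> int:
        """Number of distinct neighbours of ``g``; 0 if ``g`` is absent."""
        return self._g.degree(g) if self._g.has_node(g) else 0

    def neighbors(self, g: str) -> set[str]:
        return set(self._g.neighbors(g)) if self._g.has_node(g) else set()

    def inter_set_edges(self, A: Iterable[str], B: Iterable[str]) -> set[Interaction]:
        """All edges with one endpoint in ``A`` and the other in ``B``.

        An edge with both endpoints in the intersection is returned once.
        Symmetric in (A, B) and always a subset of the edge set.
        """
        sa, sb = set(A), set(B)
        out: set[Interaction] = set()
        small, other_a, other_b = (sa, sa, sb) if len(sa) <= len(sb) else (sb, sb, sa)
        for x in small:
            if not self._g.has_node(x):
                continue
            for y in self._g.neighbors(x):
                in_cross = (x in sa and y in sb) or (x in sb and y in sa)
                if in_cross:
                    d = self._g.edges[x, y]
                    p, q = _canon(x, y)
                    out.add(Interaction(p, q, d["score"], d["source"]))
        return out

    # -- comparison / export ------------------------------------------

    def copy(self) -> "Interactome":
        new = Interactome()
        new._g = self._g.copy()
        return new

    def graph_equal(self, other: "Interactome", score_decimals: int = 6) -> bool:
        """Equality of gene set, edge set, and per-edge scores to the given
        number of decimal places."""
        if self.genes != other.genes:
            return False
        mine = {i.pair: round(i.score, score_decimals) for i in self.interactions()}
        theirs = {i.pair: round(i.score, score_decimals) for i in other.interactions()}
        return mine == theirs

    def to_networkx(self) -> nx.Graph:
        return self._g.copy()

    def to_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self._g, str(path))

    def to_arrays(self):
        """Return (node_list, index_of, u, v) integer edge arrays for the
        rewiring kernel; node order is sorted for determinism."""
        import numpy as np

        nodes = sorted(self._g.nodes)
        idx = {g: i for i, g in enumerate(nodes)}
        m = self._g.number_of_edges()
        u = np.empty(m, dtype=np.int64)
        v = np.empty(m, dtype=np.int64)
        for k, (a, b) in enumerate(sorted(self.edge_pairs())):
            u[k] = idx[a]
            v[k] = idx[b]
        return nodes, idx, u, v

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<Interactome: {self.n_genes} genes, {self.n_edges} edges>"


# ---------------------------------------------------------------------
# Edge-list IO
# ---------------------------------------------------------------------

def read_edge_list(path: str | Path) -> Interactome:
    """Read a TSV edge list into an :class:`Interactome`.

    The file must have a header with at least ``geneA`` and ``geneB``
    columns; ``score`` (default 1.0) and ``source`` (default ``predicted``)
    are optional.  ``#``-prefixed lines are ignored.  Duplicate unordered
    pairs collapse keeping the maximum score; self-pairs raise
    :class:`~funlink.errors.ValidationError` (fail-fast surfaces upstream
    id-mapping bugs).  Malformed rows raise :class:`ParseError` naming the
    line number.
    """
    path = Path(path)
    net = Interactome()
    header: list[str] | None = None
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                if len(header) < 2 or header[0] != "geneA" or header[1] != "geneB":
                    raise ParseError(
                        f"{path}:{lineno}: header must start with 'geneA\\tgeneB', got {fields!r}"
                    )
                continue
            if len(fields) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            row = dict(zip(header, fields))
            a, b = row["geneA"], row["geneB"]
            if a == b:
                raise ValidationError(f"{path}:{lineno}: self-pair {a!r}")
            try:
                score = float(row.get("score", 1.0) or 1.0)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad score {row['score']!r}") from exc
            source = row.get("source", PREDICTED) or PREDICTED
            try:
                net.add_edge(a, b, score=score, source=source)
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return net


def write_edge_list(net: Interactome, path: str | Path) -> None:
    """Write a TSV edge list (header ``geneA geneB score source``).

    Endpoints are written in lexicographic order and rows sorted, so output
    is byte-deterministic; ``read_edge_list`` then ``write_edge_list`` is
    the identity on the graph.  Isolated genes are recorded as ``# gene:``
    comment lines so the gene set round-trips too.
    """
    path = Path(path)
    isolated = sorted(g for g in net.genes if net.degree(g) == 0)
    with path.open("w") as fh:
        for g in isolated:
            fh.write(f"# gene: {g}\n")
        fh.write("geneA\tgeneB\tscore\tsource\n")
        for it in sorted(net.interactions()):
            fh.write(f"{it.a}\t{it.b}\t{it.score:.6f}\t{it.source}\n")


def read_edge_list_with_isolated(path: str | Path) -> Interactome:
    """Like :func:`read_edge_list`, but also restores ``# gene:`` comment
    lines written by :func:`write_edge_list` as isolated genes."""
    net = read_edge_list(path)
    with Path(path).open() as fh:
        for line in fh:
            if line.startswith("# gene: "):
                net.add_gene(line[len("# gene: "):].strip())
    return net
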