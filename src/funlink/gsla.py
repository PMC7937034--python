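"""Gene set linkage analysis (GSLA).

GSLA asks whether a query gene set (typically the observed transcriptomic
change, OTC, of an experiment) is functionally associated with a
reference gene set representing an established biological process.  Two
criteria must both hold:

Q1 (density): the density of interactome edges connecting the two sets —
    inter-set edges divided by distinct unordered cross pairs — exceeds a
    threshold (default 0.01), i.e. the sets are far more connected than
    background gene pairs.

Q2 (specificity of topology): the observed density is higher than what
    degree-preserving random rewirings of the interactome produce.  The
    null model keeps every gene's neighbour count (hubs stay hubs), so Q2
    controls for gene-set composition: a set of hubs connects richly to
    anything, and only the biologically meaningful wiring should beat the
    null.  The p-value is the add-one empirical estimator
    p = (1 + #{null >= observed}) / (1 + n_permutations), so p is never 0
    and "p < 0.001" needs at least 1999 permutations.

Both thresholds follow the conventional defaults (density > 0.01, P < 0.001).
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

from ._rewire import build_adjacency, rewire_arrays
from .errors import ParseError, UndefinedDensityError, ValidationError
from .interactome import Interactome
from .version import __version__

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("gene set name must be non-empty")
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} has no members")
        object.__setattr__(self, "members", frozenset(self.members))

    def __len__(self) -> int:
        return len(self.members)


class GeneSetCollection:
    """Named gene sets with unique names (GMT-file semantics)."""

    def __init__(self, sets: Iterable[GeneSet] = ()):
        self.sets: dict[str, GeneSet] = {}
        for s in sets:
            self.add(s)

    def add(self, s: GeneSet) -> None:
        if s.name in self.sets:
            raise ValidationError(f"duplicate gene set name {s.name!r}")
        self.sets[s.name] = s

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read gene sets from GMT (tab-delimited: name, description, members...)."""
    coll = GeneSetCollection()
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 member"
                )
            coll.add(GeneSet(fields[0], fields[1], frozenset(f for f in fields[2:] if f)))
    return coll


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for name in sorted(coll.sets):
            s = coll.sets[name]
            fh.write("\t".join([s.name, s.description, *sorted(s.members)]) + "\n")


# ---------------------------------------------------------------------
# ID mapping
# ---------------------------------------------------------------------

def read_mapping_table(path: str | Path) -> dict[str, str]:
    """Read an alias -> canonical-id mapping TSV with columns
    (namespace, alias, canonical).  The namespace column is informational;
    conflicting canonical targets for one alias raise an error."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    need = {"namespace", "alias", "canonical"}
    if not need.issubset(df.columns):
        raise ParseError(f"mapping table must have columns {sorted(need)}")
    mapping: dict[str, str] = {}
    for row in df.itertuples(index=False):
        prev = mapping.get(row.alias)
        if prev is not None and prev != row.canonical:
            raise ValidationError(
                f"alias {row.alias!r} maps to both {prev!r} and {row.canonical!r}"
            )
        mapping[row.alias] = row.canonical
    return mapping


def map_ids(ids: Sequence[str], mapping: Mapping[str, str]) -> tuple[list[str], list[str]]:
    """Map tokens to canonical gene ids, order-preserving.

    Canonical ids (values of the mapping) pass through unchanged.
    Duplicates are collapsed after mapping; unmapped tokens are returned,
    never silently dropped.  An empty mapped result for non-empty input is
    a fatal input error.
    """
    canonical = set(mapping.values())
    mapped: list[str] = []
    seen: set[str] = set()
    unmapped: list[str] = []
    for tok in ids:
        if tok in mapping:
            cid = mapping[tok]
        elif tok in canonical:
            cid = tok
        else:
            unmapped.append(tok)
            continue
        if cid not in seen:
            seen.add(cid)
            mapped.append(cid)
    if ids and not mapped:
        raise ValidationError("none of the submitted ids could be mapped")
    return mapped, unmapped


# ---------------------------------------------------------------------
# Q1: inter-set density
# ---------------------------------------------------------------------

def cross_pair_count(A: set[str], B: set[str]) -> int:
    """Distinct unordered cross pairs between A and B:
    |A||B| - k - k(k-1)/2 with k = |A ∩ B| (self-pairs and double-counted
    intersection pairs removed)."""
    k = len(A & B)
    return len(A) * len(B) - k - k * (k - 1) // 2


def q1_density(
    net: Interactome, A: Iterable[str], B: Iterable[str]
) -> tuple[float, int]:
    """Inter-set edge density and edge count.

    density = |edges between A and B| / distinct unordered cross pairs.
    """
    sa, sb = set(A), set(B)
    if not sa or not sb:
        raise ValidationError("gene sets must be non-empty")
    possible = cross_pair_count(sa, sb)
    if possible == 0:
        raise UndefinedDensityError(
            "no distinct cross pairs between the sets (e.g. identical singletons)"
        )
    n_edges = len(net.inter_set_edges(sa, sb))
    return n_edges / possible, n_edges


# ---------------------------------------------------------------------
# Q2: degree-preserving permutation null
# ---------------------------------------------------------------------

def rewire_degree_preserving(
    net: Interactome, swaps_per_edge: int = 10, seed: int = 0
) -> Interactome:
    """Randomise the interactome by repeated double-edge swaps.

    The result has the same gene set and the exact same degree for every
    gene; ``swaps_per_edge * n_edges`` swap attempts are made and invalid
    proposals (self-loop or duplicate) are skipped.  Edge scores do not
    survive rewiring (topology-only null): rewired edges carry score 1.
    """
    if net.n_edges < 2:
        return net.copy()
    nodes, _, u, v = net.to_arrays()
    rng = np.random.default_rng(seed)
    uu, vv, _ = rewire_arrays(u, v, len(nodes), swaps_per_edge, rng)
    out = Interactome(genes=nodes)
    for i, j in zip(uu, vv):
        out.add_edge(nodes[int(i)], nodes[int(j)])
    return out


@dataclasses.dataclass
class GslaConfig:
    """Q1/Q2 thresholds and permutation settings.

    The add-one p-value estimator bounds p >= 1/(n_permutations+1), so
    q2_alpha below that bound is unattainable (validated with a warning).
    """

    q1_min_density: float = 0.01
    q2_alpha: float = 0.001
    n_permutations: int = 1999
    swaps_per_edge: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 1 or self.swaps_per_edge < 1:
            raise ValidationError("n_permutations and swaps_per_edge must be positive")
        if not (0.0 <= self.q1_min_density < 1.0):
            raise ValidationError("q1_min_density must lie in [0, 1)")
        if not (0.0 < self.q2_alpha <= 1.0):
            raise ValidationError("q2_alpha must lie in (0, 1]")
        if self.q2_alpha < 1.0 / (self.n_permutations + 1):
            warnings.warn(
                f"q2_alpha={self.q2_alpha} is below the minimal attainable "
                f"p-value 1/{self.n_permutations + 1}; Q2 can never pass",
                stacklevel=2,
            )


def _null_counts(
    u: np.ndarray,
    v: np.ndarray,
    n_nodes: int,
    in_a: np.ndarray,
    in_b: np.ndarray,
    cfg: GslaConfig,
    seed_seq: np.random.SeedSequence,
) -> np.ndarray:
    """Inter-set edge counts for cfg.n_permutations independent rewired
    networks (each rewired from the observed network with its own stream)."""
    base_adj = build_adjacency(u, v, n_nodes)
    counts = np.empty(cfg.n_permutations, dtype=np.int64)
    children = seed_seq.spawn(cfg.n_permutations)
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        uu, vv, _ = rewire_arrays(
            u, v, n_nodes, cfg.swaps_per_edge, rng, adj=base_adj.copy()
        )
        counts[i] = np.count_nonzero(
            (in_a[uu] & in_b[vv]) | (in_a[vv] & in_b[uu])
        )
    return counts


def q2_pvalue(
    net: Interactome,
    A: Iterable[str],
    B: Iterable[str],
    cfg: GslaConfig,
    _seed_seq: np.random.SeedSequence | None = None,
) -> tuple[float, np.ndarray]:
    """Empirical one-sided p-value of the observed inter-set density
    against degree-preserving rewired null interactomes.

    Returns (p, null_densities).  Ties are counted against the observed
    value; counts (not floating densities) are compared, so tie handling
    is exact.
    """
    sa, sb = set(A), set(B)
    _, observed = q1_density(net, sa, sb)
    possible = cross_pair_count(sa, sb)
    nodes, idx, u, v = net.to_arrays()
    in_a = np.zeros(len(nodes), dtype=np.bool_)
    in_b = np.zeros(len(nodes), dtype=np.bool_)
    for g in sa:
        if g in idx:
            in_a[idx[g]] = True
    for g in sb:
        if g in idx:
            in_b[idx[g]] = True
    seq = _seed_seq if _seed_seq is not None else np.random.SeedSequence(cfg.seed)
    counts = _null_counts(u, v, len(nodes), in_a, in_b, cfg, seq)
    p = (1.0 + int(np.count_nonzero(counts >= observed))) / (1.0 + cfg.n_permutations)
    return p, counts / possible


# ---------------------------------------------------------------------
# The full test
# ---------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class GslaResult:
    """Per-reference-set GSLA record."""

    ref_set: str
    ref_name: str
    set_size: int
    density: float
    n_inter_edges: int
    p_value: float
    passes_q1: bool
    passes_q2: bool
    q2_tested: bool
    connecting_pairs: tuple[tuple[str, str], ...]


class GslaResults:
    """Ordered GSLA results with a summary table and TSV report writer."""

    def __init__(self, results: list[GslaResult], query: GeneSet, cfg: GslaConfig,
                 net: Interactome, unmapped: Sequence[str] = ()):
        self.results = results
        self.query = query
        self.config = cfg
        self._net_genes = net.n_genes
        self._net_edges = net.n_edges
        self.unmapped = list(unmapped)

    def __iter__(self):
        return iter(self.results)

    def __len__(self) -> int:
        return len(self.results)

    def significant(self) -> list[GslaResult]:
        return [r for r in self.results if r.passes_q1 and r.passes_q2]

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "ref_set": r.ref_set,
                    "ref_name": r.ref_name,
                    "set_size": r.set_size,
                    "n_inter_edges": r.n_inter_edges,
                    "density": r.density,
                    "p_value": r.p_value,
                    "passes_q1": r.passes_q1,
                    "passes_q2": r.passes_q2,
                }
                for r in self.results
            ]
        )

    def to_tsv(self, path: str | Path) -> None:
        """Write the report: 10 '#'-prefixed parameter lines, then one row
        per reference set."""
        cfg = self.config
        header = [
            f"# tool: funlink GSLA v{__version__}",
            f"# query_set: {self.query.name}",
            f"# query_size: {len(self.query)}",
            f"# network: {self._net_genes} genes, {self._net_edges} edges",
            f"# q1_min_density: {cfg.q1_min_density}",
            f"# q2_alpha: {cfg.q2_alpha}",
            f"# n_permutations: {cfg.n_permutations}",
            f"# swaps_per_edge: {cfg.swaps_per_edge}",
            f"# seed: {cfg.seed}",
            f"# unmapped_query_ids: {','.join(self.unmapped) if self.unmapped else 'none'}",
        ]
        assert len(header) == 10
        cols = [
            "ref_set", "ref_name", "set_size", "n_inter_edges", "density",
            "p_value", "passes_q1", "passes_q2", "connecting_pairs",
        ]
        with Path(path).open("w") as fh:
            fh.write("\n".join(header) + "\n")
            fh.write("\t".join(cols) + "\n")
            for r in self.results:
                pairs = ";".join(f"{q}-{t}" for q, t in r.connecting_pairs)
                fh.write(
                    f"{r.ref_set}\t{r.ref_name}\t{r.set_size}\t{r.n_inter_edges}\t"
                    f"{r.density:.6g}\t{r.p_value:.6g}\t{r.passes_q1}\t{r.passes_q2}\t{pairs}\n"
                )


class GeneSetLinkageAnalysis:
    """Model object for a GSLA run: network + query + references + config.

    ``fit()`` evaluates Q1 for every reference set, runs the Q2
    permutation test only for Q1-passing sets (Q1 AND Q2 is conjunctive,
    so skipping Q2 for Q1 failures cannot change the reported set), and
    returns a :class:`GslaResults`.
    """

    def __init__(
        self,
        net: Interactome,
        query: GeneSet,
        refs: GeneSetCollection,
        config: GslaConfig | None = None,
        unmapped: Sequence[str] = (),
    ):
        if len(refs) == 0:
            raise ValidationError("reference collection is empty")
        self.net = net
        self.query = query
        self.refs = refs
        self.config = config or GslaConfig()
        self.unmapped = list(unmapped)
        if not (50 <= len(query) <= 200):
            warnings.warn(
                f"query has {len(query)} genes; GSLA works best with the top "
                "50-200 changed genes",
                stacklevel=2,
            )

    def fit(self) -> GslaResults:
        cfg = self.config
        qset = set(self.query.members)
        root = np.random.SeedSequence(cfg.seed)
        # one independent child stream per reference set, by sorted name
        names = sorted(self.refs.sets)
        streams = dict(zip(names, root.spawn(len(names))))
        results: list[GslaResult] = []
        for name in names:
            ref = self.refs[name]
            rset = set(ref.members)
            density, n_edges = q1_density(self.net, qset, rset)
            passes_q1 = density > cfg.q1_min_density
            if passes_q1:
                p, _ = q2_pvalue(self.net, qset, rset, cfg, _seed_seq=streams[name])
                tested = True
            else:
                p, tested = 1.0, False  # flagged "not tested"
            passes_q2 = tested and p < cfg.q2_alpha
            conn = []
            for it in sorted(self.net.inter_set_edges(qset, rset)):
                a, b = it.pair
                conn.append((a, b) if a in qset else (b, a))
            results.append(
                GslaResult(
                    ref_set=name,
                    ref_name=ref.description,
                    set_size=len(ref),
                    density=density,
                    n_inter_edges=n_edges,
                    p_value=p,
                    passes_q1=passes_q1,
                    passes_q2=passes_q2,
                    q2_tested=tested,
                    connecting_pairs=tuple(conn),
                )
            )
        results.sort(
            key=lambda r: (
                -(r.passes_q1 and r.passes_q2),
                r.p_value,
                -r.density,
                r.ref_set,
            )
        )
        return GslaResults(results, self.query, cfg, self.net, self.unmapped)


def gsla_run(
    net: Interactome,
    query: GeneSet,
    refs: GeneSetCollection,
    cfg: GslaConfig | None = None,
) -> GslaResults:
    """Functional wrapper around :class:`GeneSetLinkageAnalysis`."""
    return GeneSetLinkageAnalysis(net, query, refs, cfg).fit()
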