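"""Per-pair evidence features and ROC-AUC based feature selection.

Six categories of functional-association evidence are turned into a
numeric feature vector per gene pair:

==================  ==========================================================
category            evidence table
==================  ==========================================================
interolog           unordered gene pairs whose orthologs interact elsewhere
phylo_profile       gene x species presence/absence (or weighted) matrix
domain_interaction  gene -> protein-domain sets plus interacting domain pairs
colocalization      gene -> subcellular-compartment sets
coexpression        gene x condition expression matrix
shared_annotation   gene -> functional-term sets
==================  ==========================================================

The default registry carries 36 named features with the census
1 / 3 / 23 / 4 / 2 / 3 across the categories above; the 23 domain features
are a parameterised family (score aggregation x set-size normalisation).
The exact functional forms are this package's own documented choices — the
pipeline contract is the category census and the AUC gate, not any one
formula.  Features are symmetric in the pair, always finite, and missing
evidence scores 0 ("no evidence of association").

A feature is kept when its ROC AUC against gold-standard labels is
strictly greater than the gate (default 0.6).  AUC uses the tie-aware
Mann-Whitney form, so it is invariant under monotone rescaling.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from collections.abc import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import SchemaError, UndefinedAUCError, ValidationError

logger = logging.getLogger(__name__)

CATEGORIES = (
    "interolog",
    "phylo_profile",
    "domain_interaction",
    "colocalization",
    "coexpression",
    "shared_annotation",
)

PairKey = tuple[str, str]


def pair_key(a: str, b: str) -> PairKey:
    """Canonical unordered pair key (lexicographic)."""
    return (a, b) if a <= b else (b, a)


# ---------------------------------------------------------------------
# Evidence container
# ---------------------------------------------------------------------

@dataclasses.dataclass
class EvidenceBundle:
    """The six per-category evidence tables, keyed by canonical gene id.

    ``expression`` and ``phylo_profiles`` are DataFrames indexed by gene;
    set-valued evidence is ``dict[str, set[str]]``;
    ``domain_interactions`` maps canonical domain pairs to a score in (0, 1];
    ``interologs`` is a set of canonical gene pairs.
    """

    expression: pd.DataFrame | None = None
    annotations: dict[str, set[str]] = dataclasses.field(default_factory=dict)
    localizations: dict[str, set[str]] = dataclasses.field(default_factory=dict)
    domains: dict[str, set[str]] = dataclasses.field(default_factory=dict)
    domain_interactions: dict[PairKey, float] = dataclasses.field(default_factory=dict)
    phylo_profiles: pd.DataFrame | None = None
    interologs: set[PairKey] = dataclasses.field(default_factory=set)

    def __post_init__(self) -> None:
        if self.expression is not None and self.expression.shape[1] < 2:
            raise ValidationError(
                "expression matrix needs >= 2 conditions for coexpression features"
            )
        self.domain_interactions = {
            pair_key(*k): float(v) for k, v in self.domain_interactions.items()
        }
        self.interologs = {pair_key(*p) for p in self.interologs}


# ---------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class FeatureDef:
    name: str
    category: str


class FeatureRegistry:
    """Ordered collection of named features grouped into the six categories.

    The registry is pluggable: the category census is configurable, and the
    default census (1+3+23+4+2+3 = 36) mirrors the standard multi-evidence
    setup this package implements.
    """

    def __init__(self, entries: Sequence[FeatureDef]):
        names = [e.name for e in entries]
        if len(set(names)) != len(names):
            raise ValidationError("feature names must be unique")
        for e in entries:
            if e.category not in CATEGORIES:
                raise ValidationError(f"unknown category {e.category!r}")
        self.entries: tuple[FeatureDef, ...] = tuple(entries)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def census(self) -> dict[str, int]:
        out = {c: 0 for c in CATEGORIES}
        for e in self.entries:
            out[e.category] += 1
        return out

    def total(self) -> int:
        return len(self.entries)

    def subset(self, names: Iterable[str]) -> "FeatureRegistry":
        keep = set(names)
        return FeatureRegistry([e for e in self.entries if e.name in keep])


_DOMAIN_AGGS = ("count", "sum", "max", "mean")
_DOMAIN_NORMS = ("none", "min", "max", "geom", "pairs")


def default_registry() -> FeatureRegistry:
    """The 36-feature default registry (census 1/3/23/4/2/3)."""
    entries: list[FeatureDef] = [FeatureDef("interolog_indicator", "interolog")]
    for n in ("phylo_pearson", "phylo_jaccard", "phylo_mutual_info"):
        entries.append(FeatureDef(n, "phylo_profile"))
    # 23 domain features: 4 aggregations x 5 normalisations + 3 extras
    for agg in _DOMAIN_AGGS:
        for norm in _DOMAIN_NORMS:
            entries.append(FeatureDef(f"domain_{agg}_{norm}", "domain_interaction"))
    for n in ("domain_any_interaction", "domain_shared_count", "domain_shared_jaccard"):
        entries.append(FeatureDef(n, "domain_interaction"))
    for n in ("coloc_jaccard", "coloc_overlap_count", "coloc_overlap_min_norm", "coloc_any_shared"):
        entries.append(FeatureDef(n, "colocalization"))
    for n in ("coexpr_pearson", "coexpr_spearman"):
        entries.append(FeatureDef(n, "coexpression"))
    for n in ("annot_shared_count", "annot_jaccard", "annot_min_shared_ic"):
        entries.append(FeatureDef(n, "shared_annotation"))
    reg = FeatureRegistry(entries)
    assert reg.total() == 36
    return reg


# ---------------------------------------------------------------------
# Feature computation
# ---------------------------------------------------------------------

@dataclasses.dataclass
class FeatureMatrix:
    """Pairs x features matrix with aligned names; rows follow input order."""

    pairs: list[PairKey]
    values: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.pairs), len(self.feature_names)):
            raise SchemaError(
                f"feature matrix shape {self.values.shape} does not match "
                f"{len(self.pairs)} pairs x {len(self.feature_names)} features"
            )

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.feature_names.index(name)
        except ValueError as exc:
            raise SchemaError(f"no feature named {name!r}") from exc
        return self.values[:, j]

    def subset(self, names: Sequence[str]) -> "FeatureMatrix":
        idx = [self.feature_names.index(n) for n in names]
        return FeatureMatrix(list(self.pairs), self.values[:, idx], list(names))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "geneA", [p[0] for p in self.pairs])
        df.insert(1, "geneB", [p[1] for p in self.pairs])
        return df


def _jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    """Center and L2-normalise rows so Pearson correlation is a dot
    product; constant rows become zero vectors (correlation 0)."""
    c = x - x.mean(axis=1, keepdims=True)
    norms = np.sqrt((c * c).sum(axis=1, keepdims=True))
    norms[norms == 0] = 1.0
    return c / norms


class _EvidenceContext:
    """Pre-indexed evidence for fast per-pair feature evaluation.

    Expression and profile rows are pre-standardised (correlation becomes a
    dot product) and binary profiles are packed into ints (set statistics
    become popcounts), so all-pairs scoring stays tractable.
    """

    def __init__(self, ev: EvidenceBundle):
        self.ev = ev
        self._warned: set[tuple[str, str]] = set()

        if ev.expression is not None:
            self.expr_idx = {g: i for i, g in enumerate(ev.expression.index)}
            expr = np.asarray(ev.expression.values, dtype=float)
            self.expr_std = _standardize_rows(expr)
            self.expr_rank_std = _standardize_rows(rankdata(expr, axis=1))
        else:
            self.expr_idx = {}

        if ev.phylo_profiles is not None:
            self.phylo_idx = {g: i for i, g in enumerate(ev.phylo_profiles.index)}
            phylo = np.asarray(ev.phylo_profiles.values, dtype=float)
            self.phylo_std = _standardize_rows(phylo)
            bits = (phylo > 0)
            self.n_species = phylo.shape[1]
            weights = 1 << np.arange(self.n_species, dtype=object)
            self.phylo_packed = [int((row * weights).sum()) for row in bits]
            self.phylo_ones = bits.sum(axis=1).astype(int)
        else:
            self.phylo_idx = {}

        # information content of terms: -log2(frequency among annotated genes)
        n_annotated = sum(1 for s in ev.annotations.values() if s)
        counts: dict[str, int] = {}
        for terms in ev.annotations.values():
            for t in terms:
                counts[t] = counts.get(t, 0) + 1
        self.term_ic = {
            t: -math.log2(c / n_annotated) for t, c in counts.items()
        } if n_annotated else {}

    def warn_missing(self, gene: str, table: str) -> None:
        key = (gene, table)
        if key not in self._warned:
            self._warned.add(key)
            logger.warning("gene %s absent from %s evidence; features default to 0", gene, table)


def _domain_family(ctx: _EvidenceContext, a: str, b: str) -> dict[str, float]:
    ev = ctx.ev
    da = ev.domains.get(a)
    db = ev.domains.get(b)
    out: dict[str, float] = {}
    if da is None:
        ctx.warn_missing(a, "domains")
    if db is None:
        ctx.warn_missing(b, "domains")
    da = da or set()
    db = db or set()
    scores = [
        ev.domain_interactions[pair_key(x, y)]
        for x in da
        for y in db
        if pair_key(x, y) in ev.domain_interactions
    ]
    aggs = {
        "count": float(len(scores)),
        "sum": float(sum(scores)),
        "max": float(max(scores)) if scores else 0.0,
        "mean": float(sum(scores) / len(scores)) if scores else 0.0,
    }
    na, nb = len(da), len(db)
    norms = {
        "none": 1.0,
        "min": float(min(na, nb)) or 1.0,
        "max": float(max(na, nb)) or 1.0,
        "geom": math.sqrt(na * nb) or 1.0,
        "pairs": float(na * nb) or 1.0,
    }
    for agg in _DOMAIN_AGGS:
        for norm in _DOMAIN_NORMS:
            out[f"domain_{agg}_{norm}"] = aggs[agg] / norms[norm]
    out["domain_any_interaction"] = 1.0 if scores else 0.0
    out["domain_shared_count"] = float(len(da & db))
    out["domain_shared_jaccard"] = _jaccard(da, db)
    return out


def _category_values(ctx: _EvidenceContext, category: str, a: str, b: str) -> dict[str, float]:
    ev = ctx.ev
    if category == "interolog":
        return {"interolog_indicator": 1.0 if pair_key(a, b) in ev.interologs else 0.0}

    if category == "phylo_profile":
        ia, ib = ctx.phylo_idx.get(a), ctx.phylo_idx.get(b)
        if ia is None or ib is None:
            for g, i in ((a, ia), (b, ib)):
                if i is None:
                    ctx.warn_missing(g, "phylo_profiles")
            return {"phylo_pearson": 0.0, "phylo_jaccard": 0.0, "phylo_mutual_info": 0.0}
        n = ctx.n_species
        ca, cb = ctx.phylo_ones[ia], ctx.phylo_ones[ib]
        n11 = (ctx.phylo_packed[ia] & ctx.phylo_packed[ib]).bit_count()
        union = ca + cb - n11
        pear = float(np.clip(ctx.phylo_std[ia] @ ctx.phylo_std[ib], -1.0, 1.0))
        # mutual information (bits) from the 2x2 presence table
        mi = 0.0
        for nxy, nx, ny in (
            (n11, ca, cb),
            (ca - n11, ca, n - cb),
            (cb - n11, n - ca, cb),
            (n - union, n - ca, n - cb),
        ):
            if nxy > 0 and nx > 0 and ny > 0:
                mi += (nxy / n) * math.log2(n * nxy / (nx * ny))
        return {
            "phylo_pearson": pear,
            "phylo_jaccard": (n11 / union) if union else 0.0,
            "phylo_mutual_info": max(mi, 0.0),
        }

    if category == "domain_interaction":
        return _domain_family(ctx, a, b)

    if category == "colocalization":
        la, lb = ev.localizations.get(a), ev.localizations.get(b)
        for g, s in ((a, la), (b, lb)):
            if s is None:
                ctx.warn_missing(g, "localizations")
        la = la or set()
        lb = lb or set()
        inter = len(la & lb)
        return {
            "coloc_jaccard": _jaccard(la, lb),
            "coloc_overlap_count": float(inter),
            "coloc_overlap_min_norm": inter / min(len(la), len(lb)) if la and lb else 0.0,
            "coloc_any_shared": 1.0 if inter else 0.0,
        }

    if category == "coexpression":
        ia, ib = ctx.expr_idx.get(a), ctx.expr_idx.get(b)
        if ia is None or ib is None:
            for g, i in ((a, ia), (b, ib)):
                if i is None:
                    ctx.warn_missing(g, "expression")
            return {"coexpr_pearson": 0.0, "coexpr_spearman": 0.0}
        return {
            "coexpr_pearson": float(np.clip(ctx.expr_std[ia] @ ctx.expr_std[ib], -1.0, 1.0)),
            "coexpr_spearman": float(
                np.clip(ctx.expr_rank_std[ia] @ ctx.expr_rank_std[ib], -1.0, 1.0)
            ),
        }

    if category == "shared_annotation":
        ta, tb = ev.annotations.get(a), ev.annotations.get(b)
        for g, s in ((a, ta), (b, tb)):
            if s is None:
                ctx.warn_missing(g, "annotations")
        ta = ta or set()
        tb = tb or set()
        shared = ta & tb
        min_ic = min((ctx.term_ic.get(t, 0.0) for t in shared), default=0.0)
        return {
            "annot_shared_count": float(len(shared)),
            "annot_jaccard": _jaccard(ta, tb),
            "annot_min_shared_ic": float(min_ic),
        }

    raise ValidationError(f"unknown category {category!r}")


def compute_features(
    pairs: Sequence[tuple[str, str]],
    ev: EvidenceBundle,
    reg: FeatureRegistry | None = None,
) -> FeatureMatrix:
    """Compute the registry's features for each pair, one row per pair in
    input order.  Genes absent from an evidence table contribute 0 for
    that category's features (with a once-per-gene logged warning)."""
    reg = reg or default_registry()
    if not reg.entries:
        raise ValidationError("feature registry is empty")
    ctx = _EvidenceContext(ev)
    cats_needed = sorted({e.category for e in reg.entries}, key=CATEGORIES.index)
    names = reg.names
    values = np.zeros((len(pairs), len(names)))
    col = {n: j for j, n in enumerate(names)}
    for i, (a, b) in enumerate(pairs):
        row: dict[str, float] = {}
        for cat in cats_needed:
            row.update(_category_values(ctx, cat, a, b))
        for n in names:
            values[i, col[n]] = row[n]
    if not np.all(np.isfinite(values)):
        raise ValidationError("non-finite feature value produced")  # pragma: no cover
    return FeatureMatrix(list(pair_key(a, b) for a, b in pairs), values, names)


# ---------------------------------------------------------------------
# ROC AUC and feature selection
# ---------------------------------------------------------------------

def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Tie-aware ROC AUC: P(score_pos > score_neg) + 0.5 * P(tie).

    Computed with the Mann-Whitney rank statistic; raises
    :class:`UndefinedAUCError` unless both classes are present.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise SchemaError("scores and labels must be equal-length vectors")
    npos = int(np.count_nonzero(y == 1))
    nneg = int(np.count_nonzero(y == 0))
    if npos == 0 or nneg == 0 or npos + nneg != y.size:
        raise UndefinedAUCError("labels must contain both classes (0 and 1)")
    ranks = rankdata(s)
    rpos = float(ranks[y == 1].sum())
    return (rpos - npos * (npos + 1) / 2.0) / (npos * nneg)


def feature_aucs(fm: FeatureMatrix, labels: Sequence[int]) -> dict[str, float]:
    """ROC AUC of every feature column against binary labels, in registry
    (column) order."""
    return {n: roc_auc(fm.column(n), labels) for n in fm.feature_names}


def select_features(aucs: Mapping[str, float], threshold: float = 0.6) -> list[str]:
    """Names with AUC strictly greater than ``threshold``, preserving the
    input (registry) order."""
    return [n for n, a in aucs.items() if a > threshold]
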