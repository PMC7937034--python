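"""Guilt-by-association interactome-quality benchmark.

The quality of an interactome can be scored by how well a gene's
functional annotations can be predicted from the annotations of its
first-degree network neighbours.  For each gene, candidate terms are
those annotated to at least one neighbour, scored by a one-sided
hypergeometric over-representation p-value against the annotated-gene
universe.  Sweeping the p-value cutoff produces a precision-recall curve:

* recall  — fraction of *new* (held-out) gene-term annotations recovered;
* precision — fraction of emitted predictions consistent with any known
  annotation (old or new).  Counting old annotations as hits reproduces
  the standard evaluation's acknowledged optimism when shared annotation
  was itself an input feature of the network; the report documents this.

A higher area under the precision-recall curve indicates an interactome
that better groups functionally related genes.
"""

from __future__ import annotations

import dataclasses
import logging
from collections import Counter
from collections.abc import Sequence
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .errors import ValidationError
from .interactome import Interactome

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------
# Annotation corpus
# ---------------------------------------------------------------------

@dataclasses.dataclass
class AnnotationCorpus:
    """Gene -> term annotations split into an ``old`` (known at network
    construction time) and a ``new`` (held-out, later-reported) layer.

    The universe is the set of genes bearing at least one annotation;
    per gene, new and old term sets are disjoint.
    """

    old: dict[str, set[str]]
    new: dict[str, set[str]]
    universe: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for g in set(self.old) & set(self.new):
            overlap = self.old[g] & self.new[g]
            if overlap:
                raise ValidationError(
                    f"gene {g}: terms {sorted(overlap)} appear in both old and new"
                )
        annotated = {g for g, t in self.old.items() if t} | {
            g for g, t in self.new.items() if t
        }
        if not self.universe:
            self.universe = frozenset(annotated)
        elif not annotated <= set(self.universe):
            raise ValidationError("universe must contain every annotated gene")

    def term_counts_old(self) -> Counter:
        c: Counter = Counter()
        for terms in self.old.values():
            c.update(terms)
        return c

    def pairs(self, which: str) -> set[tuple[str, str]]:
        table = self.old if which == "old" else self.new
        return {(g, t) for g, terms in table.items() for t in terms}


def read_annotation_table(path: str | Path) -> dict[str, set[str]]:
    """Two-column TSV (gene, term) -> gene -> term-set dict."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if not {"gene", "term"}.issubset(df.columns):
        raise ValidationError("annotation table must have 'gene' and 'term' columns")
    out: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.gene, set()).add(row.term)
    return out


def write_annotation_table(ann: dict[str, set[str]], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("gene\tterm\n")
        for g in sorted(ann):
            for t in sorted(ann[g]):
                fh.write(f"{g}\t{t}\n")


# ---------------------------------------------------------------------
# Neighbour enrichment
# ---------------------------------------------------------------------

def neighbor_enrichment(
    net: Interactome, g: str, corpus: AnnotationCorpus
) -> list[tuple[str, float]]:
    """One-sided hypergeometric over-representation p-value for every term
    annotated (old layer) to at least one neighbour of ``g``.

    With N annotated genes in the universe, K of them carrying term t,
    and n annotated neighbours of g of which k carry t:
    p = P(X >= k), X ~ Hypergeom(N, K, n).  The gene itself never counts
    towards its own neighbour statistics.  Sorted by ascending p.
    """
    if not net.has_gene(g):
        raise ValidationError(f"gene {g!r} is not in the network")
    term_k = corpus.term_counts_old()
    nall = len(corpus.universe)
    neighbors = [x for x in net.neighbors(g) if x != g and corpus.old.get(x)]
    n = len(neighbors)
    if n == 0:
        return []
    counts: Counter = Counter()
    for x in neighbors:
        counts.update(corpus.old[x])
    terms = sorted(counts)
    ks = np.array([counts[t] for t in terms])
    Ks = np.array([term_k[t] for t in terms])
    ps = hypergeom.sf(ks - 1, nall, Ks, n)
    out = [(t, float(p)) for t, p in zip(terms, ps)]
    out.sort(key=lambda tp: (tp[1], tp[0]))
    return out


# ---------------------------------------------------------------------
# Precision-recall evaluation
# ---------------------------------------------------------------------

@dataclasses.dataclass
class PrCurve:
    """Precision-recall curve over an increasing p-value cutoff sweep."""

    points: list[tuple[float, float, float]]  # (cutoff, precision, recall)
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=["cutoff", "precision", "recall"])


def pr_eval(
    net: Interactome, corpus: AnnotationCorpus, cutoffs: Sequence[float]
) -> PrCurve:
    """Evaluate guilt-by-association prediction quality of ``net``.

    At each cutoff a (gene, term) prediction is emitted when the
    neighbour-enrichment p-value is <= cutoff.  Recall is measured
    against the new annotations only; precision against old plus new.
    Cutoffs must be sorted ascending; predictions at a smaller cutoff are
    a subset of those at a larger one, so recall is monotone.  AUC is the
    trapezoid over recall.  Cutoffs with zero predictions are skipped
    with a log note (precision undefined there).
    """
    cutoffs = [float(c) for c in cutoffs]
    if sorted(cutoffs) != cutoffs:
        raise ValidationError("cutoffs must be sorted ascending")
    new_pairs = corpus.pairs("new")
    if not new_pairs:
        raise ValidationError("corpus has no new annotations; recall undefined")
    known_pairs = new_pairs | corpus.pairs("old")

    # score every (gene, term) candidate once
    scored: list[tuple[float, tuple[str, str]]] = []
    for g in sorted(net.genes):
        for t, p in neighbor_enrichment(net, g, corpus):
            scored.append((p, (g, t)))

    points: list[tuple[float, float, float]] = []
    n_new = len(new_pairs)
    for cut in cutoffs:
        preds = {gt for p, gt in scored if p <= cut}
        if not preds:
            logger.info("cutoff %g: no predictions; point skipped", cut)
            continue
        hit_new = len(preds & new_pairs)
        hit_known = len(preds & known_pairs)
        points.append((cut, hit_known / len(preds), hit_new / n_new))

    if len(points) >= 2:
        pts = sorted(points, key=lambda p: p[2])
        rec = np.array([p[2] for p in pts])
        prec = np.array([p[1] for p in pts])
        auc = float(np.trapezoid(prec, rec))
    else:
        auc = 0.0
    return PrCurve(points=points, auc=auc)


def plot_pr_curves(curves: dict[str, PrCurve], path: str | Path) -> None:
    """Plot one or more PR curves to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for name, curve in curves.items():
        df = curve.to_frame().sort_values("recall")
        ax.plot(df["recall"], df["precision"], marker="o", label=f"{name} (AUC={curve.auc:.3f})")
    ax.set_xlabel("recall (new annotations recovered)")
    ax.set_ylabel("precision (consistent with known annotations)")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1.05)
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
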