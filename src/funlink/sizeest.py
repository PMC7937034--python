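"""Interactome-size estimation and coverage bookkeeping.

The size equation balances true and false positive calls over all gene
pairs.  With N_int the unknown number of true interactions among
N_all-pairs gene pairs, a predictor with the given sensitivity and
specificity is expected to emit

    N_int * sensitivity + (N_all-pairs - N_int) * (1 - specificity)

positive calls.  Setting this equal to the observed number of predictions
N_predict and solving gives

    N_int = (N_predict - (1 - specificity) * N_all-pairs)
            / (sensitivity - (1 - specificity)).

The equation is well posed only when sensitivity exceeds the false
positive rate (1 - specificity); a negative solution is reported as an
infeasibility diagnosis rather than clamped.  N_all-pairs is never
defaulted silently: the caller must supply it (or a gene-universe size).
"""

from __future__ import annotations

import dataclasses
import logging
from decimal import ROUND_HALF_UP, Decimal

from .errors import IllPosedEquationError, ValidationError
from .interactome import EXPERIMENTAL, Interactome

logger = logging.getLogger(__name__)


def all_pairs_count(n_genes: int) -> int:
    """Number of unordered gene pairs in a universe of ``n_genes`` genes."""
    if n_genes < 0:
        raise ValidationError("n_genes must be non-negative")
    return n_genes * (n_genes - 1) // 2


@dataclasses.dataclass(frozen=True)
class SizeEstimateInputs:
    """Inputs to the size equation.

    ``sensitivity`` should be the conservative choice when several
    estimates exist (see :func:`conservative_sensitivity`).
    """

    n_predict: float
    n_all_pairs: float
    sensitivity: float
    specificity: float

    def __post_init__(self) -> None:
        if self.n_predict < 0 or self.n_all_pairs <= 0:
            raise ValidationError("counts must be positive")
        if self.n_predict > self.n_all_pairs:
            raise ValidationError("n_predict cannot exceed n_all_pairs")
        if not (0.0 < self.sensitivity <= 1.0):
            raise ValidationError("sensitivity must lie in (0, 1]")
        if not (0.0 <= self.specificity <= 1.0):
            raise ValidationError("specificity must lie in [0, 1]")
        if self.sensitivity <= 1.0 - self.specificity:
            raise IllPosedEquationError(
                "sensitivity must exceed the false-positive rate "
                f"(sens={self.sensitivity}, 1-spec={1.0 - self.specificity})"
            )


@dataclasses.dataclass(frozen=True)
class SizeEstimate:
    """Solution of the size equation plus derived coverage quantities.

    expected_covered = sensitivity * n_interactome: interactions expected
    among the predictions; expected_precision = expected_covered /
    n_predict: the fraction of predictions expected to be true
    interactions.  ``feasible`` is False when the solved size is negative
    (inputs inconsistent with the equation's premises).
    """

    n_interactome: float
    pairs_per_interaction: float
    expected_covered: float
    expected_precision: float
    feasible: bool


def estimate_interactome_size(inputs: SizeEstimateInputs) -> SizeEstimate:
    """Solve the size equation for the true interactome size."""
    fpr = 1.0 - inputs.specificity
    n_int = (inputs.n_predict - fpr * inputs.n_all_pairs) / (inputs.sensitivity - fpr)
    feasible = n_int >= 0.0
    if not feasible:
        logger.warning(
            "size equation yields a negative interactome size (%.3g): "
            "the assumed specificity implies more false positives than "
            "there are predictions",
            n_int,
        )
    covered = inputs.sensitivity * n_int
    return SizeEstimate(
        n_interactome=n_int,
        pairs_per_interaction=inputs.n_all_pairs / n_int if n_int > 0 else float("inf"),
        expected_covered=covered,
        expected_precision=covered / inputs.n_predict if inputs.n_predict else 0.0,
        feasible=feasible,
    )


def conservative_sensitivity(training: float, evaluation: float) -> float:
    """The conservative estimate when both a training-stage and an
    evaluation-stage sensitivity exist: the minimum of the two."""
    return min(training, evaluation)


def assemble_interactome(
    predicted: Interactome, experimental: Interactome
) -> tuple[Interactome, dict[str, int]]:
    """Union of a predicted and an experimentally reported interactome.

    The report counts both inputs, their edge collisions, and the total;
    for disjoint inputs the total is the plain sum.  On collision the
    higher score wins (ties prefer experimental provenance).
    """
    merged = predicted.copy()
    pred_pairs = predicted.edge_pairs()
    collisions = 0
    for it in experimental.interactions():
        if it.pair in pred_pairs:
            collisions += 1
        merged.add_interaction(it)
    for g in experimental.genes:
        merged.add_gene(g)
    report = {
        "n_predicted": predicted.n_edges,
        "n_experimental": experimental.n_edges,
        "n_collisions": collisions,
        "n_total": merged.n_edges,
    }
    if collisions:
        logger.warning("%d edges present in both inputs", collisions)
    return merged, report


def overlap_fraction(a: Interactome, b: Interactome) -> tuple[int, float]:
    """Shared-edge count and percentage of ``a``'s edges shared with ``b``
    (unordered-pair identity; percentage rounded to one decimal)."""
    if a.n_edges == 0:
        raise ValidationError("overlap_fraction: first interactome has no edges")
    shared = len(a.edge_pairs() & b.edge_pairs())
    pct = float(
        Decimal(100 * shared) / Decimal(a.n_edges)
    )
    return shared, float(Decimal(str(pct)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def support_rate(n_supported: int, n_reported: int) -> float:
    """100 * n_supported / n_reported, rounded half-up to two decimals."""
    if n_reported <= 0:
        raise ValidationError("n_reported must be positive")
    if not (0 <= n_supported <= n_reported):
        raise ValidationError("need 0 <= n_supported <= n_reported")
    rate = Decimal(100) * Decimal(n_supported) / Decimal(n_reported)
    return float(rate.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
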