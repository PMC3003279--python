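"""Accuracy algebra for base-pair level evaluation.

Exact confusion counts between two structures, the standard measures
(SEN, PPV, MCC, F-score) over base pairs, expected counts under a
base-pairing probability matrix, expected accuracy (exact via enumeration,
approximate via stochastic sampling), and the pseudo-expected accuracy —
the measure evaluated *at* the expected counts rather than the expectation
of the measure.  The pseudo-expected form needs only {p_ij} and is the
quantity the prediction rules in :mod:`peafold.estimators` maximize.

Zero-denominator convention: every measure returns 0.0 when its denominator
vanishes (e.g. PPV of a pairless prediction, MCC with a zero factor);
:func:`score_defined` reports whether the value was genuinely defined.
This keeps selection procedures total and conservative.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Sequence

from .ensemble import (
    BasePairProbabilityMatrix,
    SecondaryStructure,
    StructureSample,
)
from .errors import EmptySampleError, LengthMismatchError, UnnormalizedEnsembleError


class Measure(str, enum.Enum):
    """The four base-pair accuracy measures."""

    SEN = "sen"
    PPV = "ppv"
    MCC = "mcc"
    F = "f"

    @classmethod
    def coerce(cls, value: "Measure | str") -> "Measure":
        if isinstance(value, cls):
            return value
        return cls(str(value).lower())


@dataclass(frozen=True)
class AccuracyCounts:
    """A TP/TN/FP/FN quadruple, exact (integer-valued) or expected (real).

    When the counts come from a full comparison over a length-L sequence
    they sum to L(L−1)/2 — the number of candidate pairs — but conservation
    is a property of the producing functions, not a constructor constraint,
    so free-standing quadruples can be scored too.
    """

    tp: float
    tn: float
    fp: float
    fn: float
    length: int | None = None

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> float:
        return self.tp + self.tn + self.fp + self.fn


def confusion_counts(
    theta: SecondaryStructure, sigma: SecondaryStructure
) -> AccuracyCounts:
    """Exact TP/TN/FP/FN of prediction σ against reference θ, over base pairs.

    TP counts pairs present in both, FP pairs predicted but absent from the
    reference, FN reference pairs missed, and TN the remaining candidate
    pairs of the L(L−1)/2 upper triangle.
    """
    if theta.length != sigma.length:
        raise LengthMismatchError(
            f"reference length {theta.length} != prediction length {sigma.length}"
        )
    L = theta.length
    tp = len(theta.pairs & sigma.pairs)
    fp = len(sigma.pairs - theta.pairs)
    fn = len(theta.pairs - sigma.pairs)
    tn = L * (L - 1) // 2 - tp - fp - fn
    return AccuracyCounts(tp=tp, tn=tn, fp=fp, fn=fn, length=L)


def _score(counts: AccuracyCounts, measure: Measure) -> tuple[float, bool]:
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    if measure is Measure.SEN:
        den = tp + fn
        return (tp / den, True) if den > 0 else (0.0, False)
    if measure is Measure.PPV:
        den = tp + fp
        return (tp / den, True) if den > 0 else (0.0, False)
    if measure is Measure.F:
        den = 2 * tp + fp + fn
        return (2 * tp / den, True) if den > 0 else (0.0, False)
    # MCC = (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if den <= 0:
        return 0.0, False
    return (tp * tn - fp * fn) / math.sqrt(den), True


def score(counts: AccuracyCounts, measure: Measure | str) -> float:
    """Evaluate one measure on a counts quadruple (0.0 when undefined)."""
    return _score(counts, Measure.coerce(measure))[0]


def score_defined(counts: AccuracyCounts, measure: Measure | str) -> bool:
    """Whether the measure's denominator is nonzero for these counts."""
    return _score(counts, Measure.coerce(measure))[1]


def expected_counts(
    sigma: SecondaryStructure, P: BasePairProbabilityMatrix
) -> AccuracyCounts:
    """Expected TP/TN/FP/FN of σ under the ensemble, from {p_ij} alone.

    TP̂ = Σ_{(i,j)∈σ} p_ij, FP̂ = Σ_{(i,j)∈σ} (1 − p_ij),
    FN̂ = Σ_{i<j} p_ij − TP̂ and
    TN̂ = L(L−1)/2 − |σ| − Σ_{i<j} p_ij + TP̂, so the quadruple sums to
    L(L−1)/2 exactly like the exact counts do.
    """
    if sigma.length != P.length:
        raise LengthMismatchError(
            f"structure length {sigma.length} != matrix length {P.length}"
        )
    L = sigma.length
    total_p = P.total()
    tp = sum(P.get(i, j) for i, j in sigma.pairs)
    fp = len(sigma.pairs) - tp
    fn = total_p - tp
    tn = L * (L - 1) / 2 - len(sigma.pairs) - total_p + tp
    # clamp away negative float dust so AccuracyCounts stays valid
    return AccuracyCounts(
        tp=tp, tn=max(tn, 0.0), fp=max(fp, 0.0), fn=max(fn, 0.0), length=L
    )


def pseudo_expected_accuracy(
    sigma: SecondaryStructure,
    P: BasePairProbabilityMatrix,
    measure: Measure | str,
) -> float:
    """Measure evaluated at the expected counts: Acc(TP̂, TN̂, FP̂, FN̂).

    For SEN this reduces to Σ_{σ} p_ij / Σ_{i<j} p_ij and for PPV to
    Σ_{σ} p_ij / |σ|; for MCC and F it is the cheap surrogate for the
    (intractable) expected accuracy that the M1/M2 predictors maximize.
    """
    return score(expected_counts(sigma, P), measure)


def pseudo_expected_accuracy_defined(
    sigma: SecondaryStructure,
    P: BasePairProbabilityMatrix,
    measure: Measure | str,
) -> bool:
    return score_defined(expected_counts(sigma, P), measure)


def sampled_expected_accuracy(
    sigma: SecondaryStructure,
    sample: StructureSample,
    measure: Measure | str,
) -> float:
    """Monte-Carlo estimate of the expected accuracy from a structure sample.

    The arithmetic mean of Acc(θ(n), σ) over the sample; converges to the
    exact expectation as the sample grows.  Per-term zero denominators
    follow the global 0.0 convention.
    """
    if sample.n == 0 or not sample.structures:
        raise EmptySampleError("cannot average over an empty sample")
    m = Measure.coerce(measure)
    if sample.structures[0].length != sigma.length:
        raise LengthMismatchError(
            f"sample length {sample.structures[0].length} != σ length {sigma.length}"
        )
    return sum(
        _score(confusion_counts(theta, sigma), m)[0] for theta in sample.structures
    ) / sample.n


def exact_expected_accuracy(
    sigma: SecondaryStructure,
    structure_ensemble: Sequence[tuple[SecondaryStructure, float]],
    measure: Measure | str,
) -> float:
    """Exact expected accuracy Σ_θ Acc(θ, σ)·p(θ|x) over an enumerated ensemble.

    Feasible only for short sequences (the enumeration oracle); the general
    problem has no known polynomial algorithm.
    """
    total = sum(p for _, p in structure_ensemble)
    if abs(total - 1.0) > 1e-6:
        raise UnnormalizedEnsembleError(
            f"ensemble probabilities sum to {total!r}, expected 1"
        )
    m = Measure.coerce(measure)
    return sum(
        _score(confusion_counts(theta, sigma), m)[0] * p
        for theta, p in structure_ensemble
    )
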