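"""Prediction rules built on the base-pairing probability matrix.

* the γ-centroid estimator: argmax of γ·TP̂(σ) + TN̂(σ), computed by a
  Nussinov-style dynamic program over per-pair gains (γ+1)·p_ij − 1;
* the 1/(γ+1) thresholding shortcut, exact for γ ≤ 1;
* closed-form maximizers of pseudo-expected SEN (max-sum-of-probabilities
  structure) and PPV (the single highest-probability pair);
* Method M1: maximize pseudo-expected MCC/F over a stochastic sample;
* Method M2: maximize pseudo-expected MCC/F over the γ-centroid predictions
  of a 17-value γ grid — one balanced structure with small overhead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .accuracy import (
    Measure,
    expected_counts,
    score,
    score_defined,
)
from .ensemble import (
    DEFAULT_MIN_HAIRPIN,
    BasePairProbabilityMatrix,
    PairScoringModel,
    RnaSequence,
    SecondaryStructure,
    base_pair_probabilities,
    sample_structures,
)
from .errors import ConflictingPairsError, InvalidStructureError


@dataclass(frozen=True)
class GammaGrid:
    """Ordered positive γ values scanned by Method M2."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.values or any(v <= 0 for v in self.values):
            raise ValueError("grid must be a nonempty list of positive γ values")
        object.__setattr__(self, "values", tuple(sorted(self.values)))

    def __iter__(self):
        return iter(self.values)

    def __len__(self) -> int:
        return len(self.values)


def default_gamma_grid() -> GammaGrid:
    """The standard 17-value grid {2^k : −5 ≤ k ≤ 10} ∪ {6}.

    Spans the full SEN–PPV trade-off from near-empty (γ = 1/32) to
    near-maximal (γ = 1024) predictions.
    """
    return GammaGrid(tuple(sorted({2.0**k for k in range(-5, 11)} | {6.0})))


@dataclass(frozen=True)
class Candidate:
    """One structure in a candidate pool, with provenance and its score."""

    structure: SecondaryStructure
    provenance: float | int  # γ value (M2) or first sample index (M1)
    pseudo_score: float


@dataclass(frozen=True)
class CandidateSet:
    """The pool of structures a selection rule chooses from."""

    entries: tuple[Candidate, ...]

    def __post_init__(self) -> None:
        lengths = {c.structure.length for c in self.entries}
        if len(lengths) > 1:
            raise ValueError("all candidates must share one sequence length")


@dataclass(frozen=True)
class PredictionResult:
    """A predicted structure with its selection score and run diagnostics."""

    structure: SecondaryStructure
    method: str
    score: float
    diagnostics: dict = field(default_factory=dict, compare=False)


# ---------------------------------------------------------------------------
# γ-centroid dynamic programming
# ---------------------------------------------------------------------------


def _maximize_gain(
    length: int,
    gains: dict[tuple[int, int], float],
    min_hairpin: int,
) -> SecondaryStructure:
    """Nussinov-style DP maximizing Σ_{(i,j)∈σ} g_ij over pseudoknot-free σ.

    Only strictly positive gains are eligible.  Recurrence over spans:
    M[i][j] = max(M[i+1][j], M[i][j−1], M[i+1][j−1] + g_ij, max_k M[i][k] +
    M[k+1][j]); the traceback tries the cases in exactly that order (and k
    ascending), which fixes a deterministic argmax among ties.
    """
    g = {ij: v for ij, v in gains.items() if v > 0 and ij[1] - ij[0] - 1 >= min_hairpin}
    n = length
    M = np.zeros((n + 2, n + 2))
    for span in range(min_hairpin + 2, n + 1):
        for i in range(1, n - span + 2):
            j = i + span - 1
            best = max(M[i + 1, j], M[i, j - 1])
            gij = g.get((i, j))
            if gij is not None:
                best = max(best, M[i + 1, j - 1] + gij)
            for k in range(i, j):
                cand = M[i, k] + M[k + 1, j]
                if cand > best:
                    best = cand
            M[i, j] = best
    pairs: list[tuple[int, int]] = []
    stack = [(1, n)]
    while stack:
        i, j = stack.pop()
        if j - i - 1 < min_hairpin:
            continue
        target = M[i, j]
        if target == M[i + 1, j]:
            stack.append((i + 1, j))
            continue
        if target == M[i, j - 1]:
            stack.append((i, j - 1))
            continue
        gij = g.get((i, j))
        if gij is not None and target == M[i + 1, j - 1] + gij:
            pairs.append((i, j))
            stack.append((i + 1, j - 1))
            continue
        for k in range(i, j):
            if target == M[i, k] + M[k + 1, j]:
                stack.append((i, k))
                stack.append((k + 1, j))
                break
        else:  # pragma: no cover - the fill and traceback use identical arithmetic
            raise AssertionError("traceback failed to reproduce the DP optimum")
    return SecondaryStructure(length, frozenset(pairs), min_hairpin=min_hairpin)


def gamma_centroid(
    P: BasePairProbabilityMatrix,
    gamma: float,
    min_hairpin: int = DEFAULT_MIN_HAIRPIN,
) -> SecondaryStructure:
    """The γ-centroid prediction: argmax_σ [γ·TP̂(σ) + TN̂(σ)].

    Up to a σ-independent constant that objective equals
    Σ_{(i,j)∈σ} [(γ+1)·p_ij − 1], so the argmax is found by the Nussinov-style
    DP over per-pair gains; γ tunes the SEN–PPV balance (small γ → few,
    confident pairs; large γ → many pairs).  Pairs with exactly zero gain are
    excluded, mirroring the strict p_ij > 1/(γ+1) rule.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    gains = {ij: (gamma + 1.0) * p - 1.0 for ij, p in P.entries.items()}
    return _maximize_gain(P.length, gains, min_hairpin)


def threshold_structure(
    P: BasePairProbabilityMatrix,
    gamma: float,
    min_hairpin: int = DEFAULT_MIN_HAIRPIN,
) -> SecondaryStructure:
    """γ-centroid shortcut for γ ≤ 1: keep exactly the pairs with p_ij > 1/(γ+1).

    The threshold is then ≥ 1/2 and two pairs with marginals each above 1/2
    cannot conflict in a matrix derived from a pseudoknot-free ensemble, so
    no dynamic programming is needed; the result equals
    :func:`gamma_centroid` at the same γ.  A conflicting selection (possible
    only for a broken external matrix) raises :class:`ConflictingPairsError`.
    """
    if not (0 < gamma <= 1):
        raise ValueError("the thresholding shortcut requires 0 < gamma <= 1")
    cutoff = 1.0 / (gamma + 1.0)
    picked = frozenset(ij for ij, p in P.entries.items() if p > cutoff)
    try:
        return SecondaryStructure(P.length, picked, min_hairpin=min_hairpin)
    except InvalidStructureError as exc:
        raise ConflictingPairsError(
            f"pairs above threshold {cutoff:.6g} are mutually incompatible "
            f"(broken probability matrix): {exc}"
        ) from exc


def max_pseudo_sen(
    P: BasePairProbabilityMatrix,
    min_hairpin: int = DEFAULT_MIN_HAIRPIN,
) -> SecondaryStructure:
    """Structure maximizing pseudo-expected SEN.

    Pseudo-SEN is Σ_{σ} p_ij / Σ_{i<j} p_ij with a σ-independent denominator,
    so the maximizer is the structure with maximal total pair probability —
    the γ-centroid limit for large γ, computed here exactly by the same DP
    with gains p_ij.
    """
    return _maximize_gain(P.length, dict(P.entries.items()), min_hairpin)


def max_pseudo_ppv(
    P: BasePairProbabilityMatrix,
    min_hairpin: int = DEFAULT_MIN_HAIRPIN,
) -> SecondaryStructure:
    """Structure maximizing pseudo-expected PPV.

    Pseudo-PPV is the mean probability of the predicted pairs, so the
    maximizer contains only the single highest-probability pair (ties broken
    by smallest i, then j); empty if the matrix is all zero.
    """
    best = P.max_entry()
    pairs = frozenset() if best is None else frozenset([best[0]])
    return SecondaryStructure(P.length, pairs, min_hairpin=min_hairpin)


# ---------------------------------------------------------------------------
# selection rules
# ---------------------------------------------------------------------------


def _select_first_wins(
    candidates: Sequence[Candidate],
    P: BasePairProbabilityMatrix,
    measure: Measure,
) -> tuple[Candidate, bool]:
    """Argmax by pseudo-score; ties keep the earliest candidate in supply
    order (ascending γ for M2)."""
    best = candidates[0]
    for cand in candidates[1:]:
        if cand.pseudo_score > best.pseudo_score:
            best = cand
    defined = score_defined(expected_counts(best.structure, P), measure)
    return best, defined


def _select_smallest_structure(
    candidates: Sequence[Candidate],
    P: BasePairProbabilityMatrix,
    measure: Measure,
) -> tuple[Candidate, bool]:
    """Argmax by pseudo-score; ties → fewer pairs, then lexicographic pairs."""
    best = None
    best_key = None
    for cand in candidates:
        key = (
            -cand.pseudo_score,
            cand.structure.n_pairs,
            cand.structure.sorted_pairs,
        )
        if best is None or key < best_key:
            best, best_key = cand, key
    defined = score_defined(expected_counts(best.structure, P), measure)
    return best, defined


def method_m1(
    seq: RnaSequence,
    model: PairScoringModel | None = None,
    n: int = 1000,
    measure: Measure | str = Measure.MCC,
    seed: int = 0,
) -> PredictionResult:
    """Maximize pseudo-expected MCC/F over a stochastic structure sample.

    Draws n structures from p(θ|x), deduplicates them, scores each
    candidate's pseudo-expected accuracy against the sequence's probability
    matrix and returns the argmax.  With a sufficiently large sample this
    approximates the (intractable) global maximizer of the pseudo-expected
    measure.  SEN and PPV have closed-form maximizers and are rejected here.
    """
    m = Measure.coerce(measure)
    if m not in (Measure.MCC, Measure.F):
        raise ValueError(
            "M1 applies to MCC or F; use max_pseudo_sen / max_pseudo_ppv instead"
        )
    model = model or PairScoringModel()
    P = base_pair_probabilities(seq, model)
    sample = sample_structures(seq, model, n=n, seed=seed)
    first_index: dict[frozenset, int] = {}
    distinct: list[SecondaryStructure] = []
    for idx, theta in enumerate(sample.structures):
        if theta.pairs not in first_index:
            first_index[theta.pairs] = idx
            distinct.append(theta)
    candidates = [
        Candidate(s, first_index[s.pairs], score(expected_counts(s, P), m))
        for s in distinct
    ]
    best, defined = _select_smallest_structure(candidates, P, m)
    return PredictionResult(
        structure=best.structure,
        method="m1",
        score=best.pseudo_score,
        diagnostics={
            "measure": m.value,
            "n": n,
            "seed": seed,
            "n_distinct": len(distinct),
            "sample_index": best.provenance,
            "score_defined": defined,
            "candidates": CandidateSet(tuple(candidates)),
        },
    )


def method_m2(
    P: BasePairProbabilityMatrix,
    measure: Measure | str = Measure.MCC,
    grid: GammaGrid | None = None,
    min_hairpin: int = DEFAULT_MIN_HAIRPIN,
) -> PredictionResult:
    """Maximize pseudo-expected MCC/F over the γ-centroid grid predictions.

    Computes the γ-centroid structure for every grid value (thresholding for
    γ ≤ 1, DP otherwise), deduplicates keeping the smallest generating γ as
    provenance, and selects the candidate with the best pseudo-expected
    measure (ties → smaller γ).  The selected structure's score dominates
    every individual grid prediction by construction.
    """
    m = Measure.coerce(measure)
    if m not in (Measure.MCC, Measure.F):
        raise ValueError("M2 applies to MCC or F")
    grid = grid or default_gamma_grid()
    by_pairs: dict[frozenset, Candidate] = {}
    order: list[frozenset] = []
    for gamma in grid:  # ascending, so the first γ producing a structure wins
        if gamma <= 1.0:
            s = threshold_structure(P, gamma, min_hairpin)
        else:
            s = gamma_centroid(P, gamma, min_hairpin)
        if s.pairs not in by_pairs:
            by_pairs[s.pairs] = Candidate(s, gamma, score(expected_counts(s, P), m))
            order.append(s.pairs)
    candidates = [by_pairs[k] for k in order]
    best, defined = _select_first_wins(candidates, P, m)
    return PredictionResult(
        structure=best.structure,
        method="m2",
        score=best.pseudo_score,
        diagnostics={
            "measure": m.value,
            "gamma": best.provenance,
            "grid": tuple(grid),
            "n_distinct": len(candidates),
            "score_defined": defined,
            "candidates": CandidateSet(tuple(candidates)),
        },
    )
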