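"""Boltzmann-like ensemble of pseudoknot-free RNA secondary structures.

The distribution p(θ|x) over the structure space S(x) of a sequence x is
defined by a multiplicative pair-scoring model: each structure's weight is
the product of per-pair weights (default GC=3, AU=2, GU=1, other pair types
forbidden) and the empty structure has weight 1.  The partition value
Z = Σ_θ weight(θ) normalizes weights into probabilities.  This self-contained
model plays the role that full thermodynamic engines (McCaskill-style nearest
neighbour models) play in production pipelines: the downstream estimators
consume only the base-pairing probability matrix {p_ij}, which can also be
loaded from any external model through :mod:`peafold.io`.

Coordinates are 1-based inclusive with i < j throughout, matching the CT
file convention.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np

from .errors import (
    InvalidCompositionError,
    InvalidSequenceError,
    InvalidStructureError,
    SequenceTooLongError,
)

RNA_ALPHABET = "ACGU"

#: default multiplicative pair weights (unordered pair type -> weight)
DEFAULT_PAIR_WEIGHTS: dict[str, float] = {"CG": 3.0, "AU": 2.0, "GU": 1.0}

#: minimum number of unpaired bases enclosed by a hairpin-closing pair
DEFAULT_MIN_HAIRPIN = 3

#: longest sequence accepted by the exhaustive-enumeration oracle
DEFAULT_ENUMERATION_CAP = 18


def normalize_residues(raw: str) -> str:
    """Uppercase, map T→U, and reject anything outside {A, C, G, U}."""
    out = []
    for pos, ch in enumerate(raw.upper(), start=1):
        if ch == "T":
            ch = "U"
        if ch not in RNA_ALPHABET:
            raise InvalidSequenceError(
                f"illegal residue {ch!r} at position {pos} (expected A/C/G/U/T)"
            )
        out.append(ch)
    return "".join(out)


@dataclass(frozen=True)
class RnaSequence:
    """An RNA sequence: an identifier plus residues over {A, C, G, U}.

    DNA-style input is accepted (T is folded to U); any other residue code
    raises :class:`InvalidSequenceError`.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise InvalidSequenceError("sequence must contain at least one residue")
        object.__setattr__(self, "residues", normalize_residues(self.residues))

    def __len__(self) -> int:
        return len(self.residues)


def _canonical_pairs(pairs: Iterable[tuple[int, int]]) -> frozenset[tuple[int, int]]:
    out = set()
    for i, j in pairs:
        i, j = int(i), int(j)
        if i == j:
            raise InvalidStructureError(f"position {i} cannot pair with itself")
        if i > j:
            i, j = j, i
        out.add((i, j))
    return frozenset(out)


@dataclass(frozen=True)
class SecondaryStructure:
    """A pseudoknot-free set of base pairs on a sequence of known length.

    Invariants enforced at construction: all positions in [1, length], every
    position in at most one pair, no two pairs cross (i < k < j < l is
    forbidden), and every pair encloses at least ``min_hairpin`` unpaired
    bases.  ``min_hairpin`` participates in validation only, never in
    equality or hashing.
    """

    length: int
    pairs: frozenset[tuple[int, int]] = frozenset()
    min_hairpin: int = field(default=DEFAULT_MIN_HAIRPIN, compare=False, repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", _canonical_pairs(self.pairs))
        if self.length < 1:
            raise InvalidStructureError("length must be positive")
        seen: set[int] = set()
        for i, j in self.pairs:
            if i < 1 or j > self.length:
                raise InvalidStructureError(
                    f"pair ({i},{j}) outside positions 1..{self.length}"
                )
            if j - i - 1 < self.min_hairpin:
                raise InvalidStructureError(
                    f"pair ({i},{j}) encloses fewer than {self.min_hairpin} bases"
                )
            for p in (i, j):
                if p in seen:
                    raise InvalidStructureError(f"position {p} pairs more than once")
                seen.add(p)
        sp = self.sorted_pairs
        for (i, j), (k, l) in itertools.combinations(sp, 2):
            if i < k < j < l:
                raise InvalidStructureError(
                    f"pairs ({i},{j}) and ({k},{l}) cross (pseudoknot)"
                )

    @property
    def sorted_pairs(self) -> list[tuple[int, int]]:
        return sorted(self.pairs)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class PairScoringModel:
    """Multiplicative pair-weight model defining p(θ|x).

    ``pair_weights`` maps unordered residue pair types (e.g. ``"GC"``) to
    non-negative multiplicative weights; a weight of zero (or absence)
    forbids that pair type.  A structure's weight is the product of its pair
    weights, the empty structure has weight one.
    """

    pair_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PAIR_WEIGHTS)
    )
    min_hairpin: int = DEFAULT_MIN_HAIRPIN

    def __post_init__(self) -> None:
        canon: dict[str, float] = {}
        for key, w in self.pair_weights.items():
            if w < 0:
                raise ValueError(f"pair weight for {key!r} must be non-negative")
            a, b = normalize_residues(key)
            canon["".join(sorted((a, b)))] = float(w)
        object.__setattr__(self, "pair_weights", canon)
        if self.min_hairpin < 0:
            raise ValueError("min_hairpin must be non-negative")

    def weight(self, a: str, b: str) -> float:
        """Weight of the residue pair (a, b); 0 forbids the pair."""
        return self.pair_weights.get("".join(sorted((a, b))), 0.0)


def uniform_model(min_hairpin: int = DEFAULT_MIN_HAIRPIN) -> PairScoringModel:
    """All canonical pair types (GC/AU/GU wobble) weighted equally."""
    return PairScoringModel({"CG": 1.0, "AU": 1.0, "GU": 1.0}, min_hairpin)


@dataclass(frozen=True)
class BasePairProbabilityMatrix:
    """Upper-triangular base-pairing probability matrix {p_ij}.

    p_ij is the marginal probability that positions i < j are paired under
    p(θ|x); entries absent from ``entries`` are zero.  Because each base
    pairs with at most one partner, Σ_j p_kj + Σ_i p_ik ≤ 1 for every k —
    validated here with a small tolerance.
    """

    length: int
    entries: Mapping[tuple[int, int], float] = field(default_factory=dict)
    tolerance: float = field(default=1e-6, compare=False, repr=False)

    def __post_init__(self) -> None:
        clean: dict[tuple[int, int], float] = {}
        partner_sum = np.zeros(self.length + 1)
        for (i, j), p in self.entries.items():
            i, j = int(i), int(j)
            if not (1 <= i < j <= self.length):
                raise InvalidStructureError(
                    f"entry ({i},{j}) outside the upper triangle of 1..{self.length}"
                )
            if p < -self.tolerance or p > 1 + self.tolerance:
                raise InvalidStructureError(
                    f"probability {p} for pair ({i},{j}) outside [0, 1]"
                )
            if p > 0:
                clean[(i, j)] = float(min(p, 1.0))
                partner_sum[i] += p
                partner_sum[j] += p
        bad = np.nonzero(partner_sum > 1 + self.tolerance)[0]
        if bad.size:
            raise InvalidStructureError(
                f"position {bad[0]} has total pairing probability "
                f"{partner_sum[bad[0]]:.9g} > 1"
            )
        object.__setattr__(self, "entries", clean)

    def get(self, i: int, j: int) -> float:
        if i > j:
            i, j = j, i
        return self.entries.get((i, j), 0.0)

    def total(self) -> float:
        """Σ_{i<j} p_ij, the expected number of base pairs in the ensemble."""
        return float(sum(self.entries.values()))

    def items(self) -> Iterator[tuple[tuple[int, int], float]]:
        return iter(sorted(self.entries.items()))

    def max_entry(self) -> tuple[tuple[int, int], float] | None:
        """Highest-probability pair, ties broken by smallest (i, j); None if empty."""
        if not self.entries:
            return None
        return min(self.entries.items(), key=lambda kv: (-kv[1], kv[0]))


@dataclass(frozen=True)
class StructureSample:
    """An ordered stochastic sample {θ(n)} from p(θ|x)."""

    structures: tuple[SecondaryStructure, ...]
    seed: int
    n: int

    def __post_init__(self) -> None:
        if self.n < 1 or len(self.structures) != self.n:
            raise ValueError("sample must contain exactly n >= 1 structures")
        lengths = {s.length for s in self.structures}
        if len(lengths) > 1:
            raise ValueError("all sampled structures must share one length")


# ---------------------------------------------------------------------------
# inside (partition) computation
# ---------------------------------------------------------------------------


def _pair_weight_matrix(seq: RnaSequence, model: PairScoringModel) -> np.ndarray:
    """w[i, j] = weight of pairing positions i and j (0 if forbidden), 1-based."""
    n = len(seq)
    w = np.zeros((n + 2, n + 2))
    res = seq.residues
    for i in range(1, n + 1):
        for j in range(i + model.min_hairpin + 1, n + 1):
            w[i, j] = model.weight(res[i - 1], res[j - 1])
    return w


def inside_partition(
    seq: RnaSequence, model: PairScoringModel | None = None
) -> tuple[float, np.ndarray]:
    """Compute the partition value Z and the inside table.

    The inside table ``Zt[i, j]`` holds the weight-sum over all structures of
    the subsequence i..j (1-based inclusive); spans with j < i are empty and
    carry value 1.  The recursion cases on the leftmost position i: either
    unpaired, or paired with some k (k − i − 1 ≥ min_hairpin), so each
    structure is generated exactly once.  O(|x|³) time.

    Returns ``(Z, table)`` with Z = Zt[1, |x|].
    """
    model = model or PairScoringModel()
    n = len(seq)
    w = _pair_weight_matrix(seq, model)
    Zt = np.ones((n + 2, n + 2))
    for span in range(1, n + 1):
        for i in range(1, n - span + 2):
            j = i + span - 1
            total = Zt[i + 1, j]  # i unpaired
            for k in range(i + model.min_hairpin + 1, j + 1):
                if w[i, k] > 0:
                    total += w[i, k] * Zt[i + 1, k - 1] * Zt[k + 1, j]
            Zt[i, j] = total
    return float(Zt[1, n]), Zt


def base_pair_probabilities(
    seq: RnaSequence, model: PairScoringModel | None = None
) -> BasePairProbabilityMatrix:
    """Base-pairing probabilities p_ij by the inside–outside algorithm.

    p_ij is the total weight of structures containing pair (i, j) divided by
    Z.  The outside pass propagates context weights O[i, j] (the weight-sum
    of all completions outside span i..j) down the same recursion the inside
    pass used, accumulating for each pair (i, k) the term
    O[i, j]·w_ik·Z[i+1, k−1]·Z[k+1, j] over enclosing spans.  O(|x|³).
    """
    model = model or PairScoringModel()
    n = len(seq)
    w = _pair_weight_matrix(seq, model)
    Z, Zt = inside_partition(seq, model)
    Ot = np.zeros((n + 2, n + 2))
    Ot[1, n] = 1.0
    pair_weight: dict[tuple[int, int], float] = {}
    for span in range(n, 0, -1):
        for i in range(1, n - span + 2):
            j = i + span - 1
            o = Ot[i, j]
            if o == 0.0:
                continue
            if i + 1 <= j:
                Ot[i + 1, j] += o  # i unpaired
            for k in range(i + model.min_hairpin + 1, j + 1):
                if w[i, k] == 0:
                    continue
                wk = o * w[i, k]
                pair_weight[(i, k)] = (
                    pair_weight.get((i, k), 0.0)
                    + wk * Zt[i + 1, k - 1] * Zt[k + 1, j]
                )
                if i + 1 <= k - 1:
                    Ot[i + 1, k - 1] += wk * Zt[k + 1, j]
                if k + 1 <= j:
                    Ot[k + 1, j] += wk * Zt[i + 1, k - 1]
    entries = {ij: pw / Z for ij, pw in pair_weight.items() if pw > 0}
    return BasePairProbabilityMatrix(n, entries, tolerance=1e-9)


# ---------------------------------------------------------------------------
# stochastic traceback sampling
# ---------------------------------------------------------------------------


class _Sampler:
    """Precomputed per-span decompositions for fast repeated traceback.

    For every span (i, j) that admits a pair, the decomposition cases of the
    inside recursion ("i unpaired" or "i pairs k") and their cumulative
    weights are frozen once; each traceback then only draws uniforms and
    binary-searches.
    """

    def __init__(self, seq: RnaSequence, model: PairScoringModel):
        self.n = len(seq)
        self.h = model.min_hairpin
        w = _pair_weight_matrix(seq, model)
        self.Z, Zt = inside_partition(seq, model)
        self.tables: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
        for i in range(1, self.n + 1):
            for j in range(i + self.h + 1, self.n + 1):
                opts = [0]  # 0 encodes "i unpaired"
                weights = [Zt[i + 1, j]]
                for k in range(i + self.h + 1, j + 1):
                    if w[i, k] > 0:
                        opts.append(k)
                        weights.append(w[i, k] * Zt[i + 1, k - 1] * Zt[k + 1, j])
                self.tables[(i, j)] = (
                    np.asarray(opts, dtype=np.int64),
                    np.cumsum(weights),
                )

    def draw(self, rng: np.random.Generator) -> frozenset[tuple[int, int]]:
        pairs: list[tuple[int, int]] = []
        stack = [(1, self.n)]
        h = self.h
        while stack:
            i, j = stack.pop()
            tab = self.tables.get((i, j))
            if tab is None:  # span too short to hold any pair
                continue
            opts, cum = tab
            k = int(opts[np.searchsorted(cum, rng.random() * cum[-1], side="right")])
            if k == 0:
                if j - (i + 1) > h:
                    stack.append((i + 1, j))
            else:
                pairs.append((i, k))
                if (k - 1) - (i + 1) > h:
                    stack.append((i + 1, k - 1))
                if j - (k + 1) > h:
                    stack.append((k + 1, j))
        return frozenset(pairs)


def sample_structures(
    seq: RnaSequence,
    model: PairScoringModel | None = None,
    n: int = 1000,
    seed: int = 0,
) -> StructureSample:
    """Draw n i.i.d. structures from p(θ|x) by stochastic traceback.

    The whole sample is governed by one integer seed and a single sequential
    random stream, so identical (seq, model, n, seed) reproduce the identical
    sample and the first m draws of a size-n sample (m < n) equal the size-m
    sample with the same seed.
    """
    if n < 1:
        raise ValueError("sample size must be at least 1")
    model = model or PairScoringModel()
    sampler = _Sampler(seq, model)
    rng = np.random.default_rng(seed)
    structures = tuple(
        SecondaryStructure(len(seq), sampler.draw(rng), min_hairpin=model.min_hairpin)
        for _ in range(n)
    )
    return StructureSample(structures, seed=seed, n=n)


# ---------------------------------------------------------------------------
# exhaustive enumeration oracle
# ---------------------------------------------------------------------------


def enumerate_structures(
    seq: RnaSequence,
    model: PairScoringModel | None = None,
    cap: int = DEFAULT_ENUMERATION_CAP,
) -> list[tuple[SecondaryStructure, float]]:
    """List every structure in S(x) with its exact probability weight(θ)/Z.

    The structure space grows exponentially with |x| (roughly 1.8^|x|), so
    sequences longer than ``cap`` (default 18) are refused — the cap guards
    against oracle misuse, it is not a correctness bound.
    """
    model = model or PairScoringModel()
    n = len(seq)
    if n > cap:
        raise SequenceTooLongError(
            f"enumeration refused for length {n} > cap {cap}; "
            "the structure space grows exponentially"
        )
    w = _pair_weight_matrix(seq, model)
    h = model.min_hairpin
    memo: dict[tuple[int, int], list[tuple[frozenset, float]]] = {}

    def rec(i: int, j: int) -> list[tuple[frozenset, float]]:
        if j - i <= h:  # no pair fits
            return [(frozenset(), 1.0)]
        key = (i, j)
        if key in memo:
            return memo[key]
        out = list(rec(i + 1, j))  # i unpaired
        for k in range(i + h + 1, j + 1):
            if w[i, k] == 0:
                continue
            for left, wl in rec(i + 1, k - 1):
                for right, wr in rec(k + 1, j):
                    out.append(
                        (left | right | {(i, k)}, w[i, k] * wl * wr)
                    )
        memo[key] = out
        return out

    raw = rec(1, n)
    Z = sum(wt for _, wt in raw)
    return [
        (SecondaryStructure(n, pairs, min_hairpin=h), wt / Z) for pairs, wt in raw
    ]


def structure_probability(
    seq: RnaSequence,
    model: PairScoringModel | None = None,
    sigma: SecondaryStructure | None = None,
) -> float:
    """Exact probability weight(σ)/Z of one structure under the ensemble."""
    model = model or PairScoringModel()
    if sigma is None:
        raise InvalidStructureError("a structure must be supplied")
    if sigma.length != len(seq):
        raise InvalidStructureError(
            f"structure length {sigma.length} != sequence length {len(seq)}"
        )
    res = seq.residues
    weight = 1.0
    for i, j in sigma.pairs:
        if j - i - 1 < model.min_hairpin:
            raise InvalidStructureError(
                f"pair ({i},{j}) violates the model's hairpin constraint"
            )
        wij = model.weight(res[i - 1], res[j - 1])
        if wij == 0:
            raise InvalidStructureError(
                f"pair ({i},{j}) = {res[i-1]}-{res[j-1]} is forbidden by the model"
            )
        weight *= wij
    Z, _ = inside_partition(seq, model)
    return weight / Z


def random_sequence(
    length: int,
    composition: Mapping[str, float] | None = None,
    seed: int = 0,
) -> RnaSequence:
    """Deterministic i.i.d. random sequence, a seeded test-fixture generator."""
    if length < 1:
        raise ValueError("length must be positive")
    if composition is None:
        composition = {b: 0.25 for b in RNA_ALPHABET}
    bases, freqs = zip(*sorted(composition.items()))
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs < 0) or abs(freqs.sum() - 1.0) > 1e-6:
        raise InvalidCompositionError(
            f"residue frequencies must be non-negative and sum to 1, got {composition}"
        )
    for b in bases:
        if b not in RNA_ALPHABET:
            raise InvalidCompositionError(f"unknown residue {b!r} in composition")
    rng = np.random.default_rng(seed)
    residues = "".join(rng.choice(list(bases), size=length, p=freqs / freqs.sum()))
    return RnaSequence(id=f"random-{length}nt-seed{seed}", residues=residues)
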