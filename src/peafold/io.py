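"""Readers and writers for the formats the tool touches.

FASTA sequences (via Biopython), Vienna-style dot-bracket structures,
Zuker-style 6-column CT files, and a plain-text dialect for base-pairing
probability matrices (a ``length L`` header followed by 1-based ``i j p``
records) so posteriors from any external thermodynamic model can be plugged
into the estimators.

Structure readers are permissive about hairpin size (external reference
structures may close loops shorter than the folding default of three
unpaired bases); all other structural invariants are enforced on read.
"""

from __future__ import annotations

import io as _stdio
from os import PathLike
from typing import IO, Iterable, Union

from Bio import SeqIO

from .ensemble import BasePairProbabilityMatrix, RnaSequence, SecondaryStructure
from .errors import FormatError, LengthMismatchError

Source = Union[str, PathLike, IO[str]]


def _as_handle(source: Source) -> tuple[IO[str], bool]:
    if hasattr(source, "read"):
        return source, False
    return open(source, "r"), True


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(source: Source) -> list[RnaSequence]:
    """Read all records of a FASTA file as RNA sequences.

    Identifiers are the header up to the first whitespace; residues are
    uppercased with T folded to U.  An empty file and illegal residues are
    errors.
    """
    handle, close = _as_handle(source)
    try:
        records = list(SeqIO.parse(handle, "fasta"))
    finally:
        if close:
            handle.close()
    if not records:
        raise FormatError("FASTA source contains no records")
    return [RnaSequence(id=rec.id, residues=str(rec.seq)) for rec in records]


def write_fasta(sequences: Iterable[RnaSequence]) -> str:
    return "".join(f">{s.id}\n{s.residues}\n" for s in sequences)


# ---------------------------------------------------------------------------
# dot-bracket
# ---------------------------------------------------------------------------


def parse_dotbracket(text: str) -> SecondaryStructure:
    """Parse a nested dot-bracket string into a structure.

    Only ``.``, ``(`` and ``)`` are accepted (the structure space is
    pseudoknot-free, so no extra bracket alphabets); unbalanced brackets are
    reported with their position.
    """
    text = text.strip()
    if not text:
        raise FormatError("empty dot-bracket string")
    pairs = []
    open_stack: list[int] = []
    for pos, ch in enumerate(text, start=1):
        if ch == "(":
            open_stack.append(pos)
        elif ch == ")":
            if not open_stack:
                raise FormatError(f"unbalanced ')' at position {pos}")
            pairs.append((open_stack.pop(), pos))
        elif ch != ".":
            raise FormatError(f"illegal character {ch!r} at position {pos}")
    if open_stack:
        raise FormatError(f"unbalanced '(' at position {open_stack[-1]}")
    return SecondaryStructure(len(text), frozenset(pairs), min_hairpin=0)


def write_dotbracket(structure: SecondaryStructure) -> str:
    chars = ["."] * structure.length
    for i, j in structure.pairs:
        chars[i - 1] = "("
        chars[j - 1] = ")"
    return "".join(chars)


# ---------------------------------------------------------------------------
# CT (connectivity table)
# ---------------------------------------------------------------------------


def read_ct(source: Source) -> tuple[RnaSequence, SecondaryStructure]:
    """Read a 6-column CT file: index, residue, i−1, i+1, partner (0 =
    unpaired), index.  Pairing must be symmetric; pairs are recorded once as
    (min, max)."""
    handle, close = _as_handle(source)
    try:
        lines = [ln for ln in handle.read().splitlines() if ln.strip()]
    finally:
        if close:
            handle.close()
    if not lines:
        raise FormatError("empty CT source")
    residues: list[str] = []
    partner: list[int] = []
    for lineno, line in enumerate(lines, start=1):
        cols = line.split()
        if len(cols) < 6:
            raise FormatError(f"CT line {lineno}: expected 6 columns, got {len(cols)}")
        try:
            idx, pair_col = int(cols[0]), int(cols[4])
        except ValueError as exc:
            raise FormatError(f"CT line {lineno}: non-integer index column") from exc
        if idx != lineno:
            raise FormatError(f"CT line {lineno}: index {idx} out of order")
        residues.append(cols[1])
        partner.append(pair_col)
    n = len(partner)
    pairs = set()
    for i, j in enumerate(partner, start=1):
        if j == 0:
            continue
        if not (1 <= j <= n):
            raise FormatError(f"CT position {i}: partner {j} outside 1..{n}")
        if partner[j - 1] != i:
            raise FormatError(
                f"CT inconsistent partners: {i} pairs {j} but {j} pairs {partner[j-1]}"
            )
        pairs.add((min(i, j), max(i, j)))
    seq = RnaSequence(id="ct", residues="".join(residues))
    return seq, SecondaryStructure(n, frozenset(pairs), min_hairpin=0)


def write_ct(seq: RnaSequence, structure: SecondaryStructure) -> str:
    if structure.length != len(seq):
        raise LengthMismatchError(
            f"structure length {structure.length} != sequence length {len(seq)}"
        )
    partner = [0] * (len(seq) + 1)
    for i, j in structure.pairs:
        partner[i], partner[j] = j, i
    rows = []
    for i, res in enumerate(seq.residues, start=1):
        nxt = i + 1 if i < len(seq) else 0
        rows.append(f"{i} {res} {i - 1} {nxt} {partner[i]} {i}")
    return "\n".join(rows) + "\n"


# ---------------------------------------------------------------------------
# base-pairing probability matrix text
# ---------------------------------------------------------------------------


def read_bpp(source: Source) -> BasePairProbabilityMatrix:
    """Read the plain-text probability-matrix dialect.

    First line ``length <L>``; then whitespace-separated ``i j p`` records
    (1-based, i < j).  Unlisted entries are zero; duplicates, out-of-range
    coordinates or probabilities, and single-partner-bound violations are
    errors.
    """
    handle, close = _as_handle(source)
    try:
        lines = [ln for ln in handle.read().splitlines() if ln.strip()]
    finally:
        if close:
            handle.close()
    if not lines:
        raise FormatError("empty probability-matrix source")
    head = lines[0].split()
    if len(head) != 2 or head[0].lower() != "length":
        raise FormatError(f"expected 'length <L>' header, got {lines[0]!r}")
    try:
        n = int(head[1])
    except ValueError as exc:
        raise FormatError(f"non-integer length {head[1]!r}") from exc
    if n < 1:
        raise FormatError("length must be positive")
    entries: dict[tuple[int, int], float] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        cols = line.split()
        if len(cols) != 3:
            raise FormatError(f"line {lineno}: expected 'i j p', got {line!r}")
        try:
            i, j, p = int(cols[0]), int(cols[1]), float(cols[2])
        except ValueError as exc:
            raise FormatError(f"line {lineno}: malformed record {line!r}") from exc
        if not (1 <= i < j <= n):
            raise FormatError(f"line {lineno}: pair ({i},{j}) outside 1..{n}")
        if not (0.0 <= p <= 1.0):
            raise FormatError(f"line {lineno}: probability {p} outside [0, 1]")
        if (i, j) in entries:
            raise FormatError(f"line {lineno}: duplicate entry for pair ({i},{j})")
        entries[(i, j)] = p
    try:
        return BasePairProbabilityMatrix(n, entries, tolerance=1e-6)
    except Exception as exc:
        raise FormatError(f"invalid probability matrix: {exc}") from exc


def write_bpp(P: BasePairProbabilityMatrix, floor: float = 0.0) -> str:
    """Serialize a probability matrix; entries ≤ ``floor`` are omitted.

    Probabilities are written with 12 significant digits so a read-back
    reproduces the matrix to well below every tolerance used here.
    """
    out = _stdio.StringIO()
    out.write(f"length {P.length}\n")
    for (i, j), p in P.items():
        if p > floor:
            out.write(f"{i} {j} {p:.12g}\n")
    return out.getvalue()
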