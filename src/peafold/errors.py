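"""Exception hierarchy.

Every public error carries a distinct ``exit_code`` so the command-line
interface can map each named failure mode to its own nonzero status.
"""


class PeafoldError(Exception):
    """Base class for all peafold errors."""

    exit_code = 1


class InvalidSequenceError(PeafoldError):
    """A residue outside {A, C, G, U} (after T→U folding) was encountered."""

    exit_code = 3


class InvalidStructureError(PeafoldError):
    """A base-pair set violates the secondary-structure invariants."""

    exit_code = 4


class LengthMismatchError(PeafoldError):
    """Two objects that must share a sequence length do not."""

    exit_code = 5


class SequenceTooLongError(PeafoldError):
    """Exhaustive enumeration requested beyond the safety cap."""

    exit_code = 6


class FormatError(PeafoldError):
    """A file does not conform to its documented dialect."""

    exit_code = 7


class EmptySampleError(PeafoldError):
    """A structure sample with no members was supplied."""

    exit_code = 8


class UnnormalizedEnsembleError(PeafoldError):
    """Enumerated structure probabilities do not sum to one."""

    exit_code = 9


class InvalidCompositionError(PeafoldError):
    """Residue frequencies are negative or do not sum to one."""

    exit_code = 10


class ConflictingPairsError(PeafoldError):
    """Probability thresholding selected mutually incompatible base pairs.

    Cannot happen for a matrix derived from a pseudoknot-free ensemble
    (incompatible pairs have marginals summing to at most one); raised only
    for broken externally supplied matrices.
    """

    exit_code = 11
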