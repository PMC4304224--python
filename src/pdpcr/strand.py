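"""Core sequence types and the complementarity/orientation transforms.

DNA duplexes come in two geometries.  In the familiar antiparallel
(Watson-Crick) duplex the two strands run in opposite 5'->3' directions and
a strand pairs with its *reverse complement*.  In a parallel-stranded
(reverse Watson-Crick) duplex both strands run 5'->3' in the same direction
and a strand pairs with its base-wise complement *without* reversal -- its
*parallel complement*.  Everything else in this package (site search, the
thermocycler, primer design) is built from the four transforms defined here:

* :func:`reverse` -- order reversal, no complementation
* :func:`complement_base` / base-wise complement
* :func:`antiparallel_complement` -- the standard reverse complement
* :func:`parallel_complement` -- base-wise complement, order preserved

All three sequence transforms are involutions and satisfy the identity
``antiparallel_complement == reverse . parallel_complement``.

Sequences are always stored reading 5'->3'.  Polarity ("which way does this
strand run relative to that one") is metadata carried by containers such as
duplexes and reports, never encoded by reversing the stored string.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

__all__ = [
    "SequenceError",
    "NucleotideSequence",
    "Strand",
    "StrandOrigin",
    "validate_sequence",
    "complement_base",
    "antiparallel_complement",
    "parallel_complement",
    "reverse",
]

_ALPHABET = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_WHITESPACE = str.maketrans("", "", " \t\r\n")


class SequenceError(ValueError):
    """Raised when raw input cannot be validated as a DNA sequence."""


class NucleotideSequence(str):
    """A validated DNA string over {A, C, G, T}, stored uppercase, 5'->3'.

    Subclasses :class:`str`, so it compares equal to a plain string with the
    same characters and supports all string operations.  Construction
    validates: whitespace is stripped, case is normalised, and any character
    outside the strict four-letter alphabet raises :class:`SequenceError`
    naming the offending (1-based) position.

    IUPAC ambiguity codes are deliberately rejected; the pairing semantics
    of parallel duplexes are only defined here for unambiguous bases.
    """

    def __new__(cls, raw: str) -> "NucleotideSequence":
        if isinstance(raw, NucleotideSequence):
            return raw
        cleaned = raw.translate(_WHITESPACE).upper()
        if not cleaned:
            raise SequenceError("empty sequence after stripping whitespace")
        for pos, base in enumerate(cleaned, start=1):
            if base not in _ALPHABET:
                raise SequenceError(
                    f"invalid character {base!r} at position {pos}: "
                    "only A/C/G/T are accepted"
                )
        return super().__new__(cls, cleaned)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"NucleotideSequence({str.__repr__(self)})"


def validate_sequence(raw: str) -> NucleotideSequence:
    """Normalise and validate raw input into a :class:`NucleotideSequence`.

    Whitespace (spaces, tabs, newlines) is removed and lowercase letters are
    upper-cased before the alphabet check, so spaced, mixed-case input such
    as ``"gcg cgc ATG"`` validates to ``"GCGCGCATG"``.

    Raises
    ------
    SequenceError
        If the input is empty after stripping, or contains a character
        outside {A, C, G, T} (case-insensitive); the error message reports
        the 1-based position of the first offender within the cleaned
        sequence.
    """
    return NucleotideSequence(raw)


class StrandOrigin(str, enum.Enum):
    """How a strand entered a reaction: supplied, or made by extension."""

    INPUT = "input"
    PRIMER_EXTENSION = "primer_extension"


@dataclass(frozen=True)
class Strand:
    """A labelled single strand.  ``seq`` always reads 5'->3'."""

    seq: NucleotideSequence
    label: str = ""
    origin: StrandOrigin = StrandOrigin.INPUT

    def __post_init__(self) -> None:
        if not isinstance(self.seq, NucleotideSequence):
            object.__setattr__(self, "seq", NucleotideSequence(self.seq))
        if not isinstance(self.origin, StrandOrigin):
            object.__setattr__(self, "origin", StrandOrigin(self.origin))

    def __len__(self) -> int:
        return len(self.seq)


def complement_base(b: str) -> str:
    """Watson-Crick partner of a single base: A<->T, G<->C."""
    if b not in _ALPHABET:
        raise SequenceError(f"invalid base {b!r}: only A/C/G/T are accepted")
    return b.translate(_COMPLEMENT)


def antiparallel_complement(s: str | NucleotideSequence) -> NucleotideSequence:
    """Reverse complement: the partner strand in an antiparallel duplex.

    Both strands of a Watson-Crick duplex read 5'->3' in opposite physical
    directions, so the partner of ``s``, written 5'->3', is the base-wise
    complement in reverse order.
    """
    s = NucleotideSequence(s)
    return NucleotideSequence(str(s).translate(_COMPLEMENT)[::-1])


def parallel_complement(s: str | NucleotideSequence) -> NucleotideSequence:
    """Base-wise complement with order preserved: the parallel-duplex partner.

    In a parallel-stranded duplex both strands run 5'->3' in the same
    direction, position ``i`` pairing with position ``i`` under reverse
    Watson-Crick geometry, so no reversal is applied.
    """
    s = NucleotideSequence(s)
    return NucleotideSequence(str(s).translate(_COMPLEMENT))


def reverse(s: str | NucleotideSequence) -> NucleotideSequence:
    """Characters in reverse order, no complementation.

    This is *not* a physical strand operation on its own; it appears because
    the parallel-amplification scheme yields products whose sequence is the
    reversed template (opposite polarity, same base identities).
    """
    s = NucleotideSequence(s)
    return NucleotideSequence(str(s)[::-1])
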