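"""Primer-pair design for the conventional and PD-PCR schemes.

Design is purely positional/algebraic: given a single-stranded template
(5'->3'), a pair is read off the template's ends (optionally offset
inward).

Conventional scheme
    * reverse primer (primer1) = antiparallel complement of the template's
      3'-end segment; it anneals directly to the template.
    * forward primer (primer2) = the template's 5'-end segment verbatim; it
      anneals to the complementary strand made in the first cycle.

PD-PCR scheme
    * primer1 = parallel complement of the template's 5'-end segment; it
      anneals to the single-stranded template in parallel orientation and
      starts synthesis of the opposite-polarity strand.
    * primer2 = the template's 3'-end segment in reversed reading order; it
      anneals antiparallel to the newly synthesised strand.

The two schemes are algebraic mirrors: designing a PD-PCR pair for T gives
the same primers, roles swapped, as designing a conventional pair for
reverse(T).  That identity is the formal content of the claim that PD-PCR
amplifies a product of opposite polarity.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .hybridization import TmModel, melting_temperature, PairingMode
from .strand import (
    NucleotideSequence,
    Strand,
    antiparallel_complement,
    parallel_complement,
    reverse,
)
from .thermocycler import AmpliconReport, CycleProtocol, run_pcr

__all__ = [
    "Scheme",
    "PrimerPair",
    "VerificationReport",
    "design_conventional_pair",
    "design_pdpcr_pair",
    "verify_pair",
]


class Scheme(str, enum.Enum):
    CONVENTIONAL = "conventional"
    PDPCR = "pdpcr"


@dataclass(frozen=True)
class PrimerPair:
    """A scheme-labelled primer pair with its template footprints.

    Footprints are 0-based half-open intervals on the template's 5'->3'
    coordinates giving the segment each primer was derived from;
    ``predicted_product_length`` spans from the leftmost footprint start to
    the rightmost footprint end.
    """

    scheme: Scheme
    primer1: NucleotideSequence
    primer2: NucleotideSequence
    footprint1: tuple[int, int]
    footprint2: tuple[int, int]
    predicted_product_length: int


def _check_lengths(template: NucleotideSequence, len1: int, len2: int,
                   offset1: int, offset2: int) -> None:
    if len1 < 1 or len2 < 1:
        raise ValueError("primer lengths must be >= 1")
    if offset1 < 0 or offset2 < 0:
        raise ValueError("offsets must be >= 0")
    n = len(template)
    if offset1 + len1 + len2 + offset2 > n:
        raise ValueError(
            f"primer footprints ({offset1}+{len1} and {len2}+{offset2}) "
            f"exceed or overlap on template of length {n}"
        )


def design_conventional_pair(
    template: str | NucleotideSequence,
    fwd_len: int = 21,
    rev_len: int = 22,
    fwd_offset: int = 0,
    rev_offset: int = 0,
) -> PrimerPair:
    """Conventional antiparallel pair read off the template ends.

    ``primer2`` (forward) is the template segment starting ``fwd_offset``
    from the 5' end; ``primer1`` (reverse) is the antiparallel complement
    of the segment ending ``rev_offset`` from the 3' end.
    """
    template = NucleotideSequence(template)
    _check_lengths(template, fwd_len, rev_len, fwd_offset, rev_offset)
    n = len(template)
    f1 = (n - rev_offset - rev_len, n - rev_offset)
    f2 = (fwd_offset, fwd_offset + fwd_len)
    primer1 = antiparallel_complement(template[f1[0] : f1[1]])
    primer2 = NucleotideSequence(template[f2[0] : f2[1]])
    return PrimerPair(
        scheme=Scheme.CONVENTIONAL,
        primer1=primer1,
        primer2=primer2,
        footprint1=f1,
        footprint2=f2,
        predicted_product_length=f1[1] - f2[0],
    )


def design_pdpcr_pair(
    template: str | NucleotideSequence,
    p1_len: int = 22,
    p2_len: int = 20,
    p1_offset: int = 0,
    p2_offset: int = 0,
) -> PrimerPair:
    """PD-PCR pair: parallel-complement 5'-end primer plus reversed
    3'-end primer.

    ``primer1`` is the parallel complement of the template segment starting
    ``p1_offset`` from the 5' end; ``primer2`` is the reversal of the
    segment ending ``p2_offset`` from the 3' end.
    """
    template = NucleotideSequence(template)
    _check_lengths(template, p1_len, p2_len, p1_offset, p2_offset)
    n = len(template)
    f1 = (p1_offset, p1_offset + p1_len)
    f2 = (n - p2_offset - p2_len, n - p2_offset)
    primer1 = parallel_complement(template[f1[0] : f1[1]])
    primer2 = reverse(template[f2[0] : f2[1]])
    return PrimerPair(
        scheme=Scheme.PDPCR,
        primer1=primer1,
        primer2=primer2,
        footprint1=f1,
        footprint2=f2,
        predicted_product_length=f2[1] - f1[0],
    )


@dataclass(frozen=True)
class VerificationReport:
    """Outcome of re-simulating a pair on its template."""

    verified: bool
    scheme: Scheme
    n_amplicons: int
    product_length: int | None
    product_strands: tuple[str, str] | None
    expected_length: int
    report: AmpliconReport


def verify_pair(
    template: str | NucleotideSequence,
    pair: PrimerPair,
    scheme: Scheme | str | None = None,
    protocol: CycleProtocol | None = None,
    model: TmModel | None = None,
) -> VerificationReport:
    """Re-run the thermocycler with ``pair`` on ``template`` and check that
    exactly one amplicon of the predicted length results.

    ``scheme`` defaults to the pair's own scheme; passing a different one
    checks cross-scheme behaviour (a PD-PCR pair simulated with parallel
    annealing disabled yields no product).  Unless a protocol is supplied,
    the annealing temperature is set to the coolest Tm the scheme requires
    (the parallel-mode Tm of a PD-PCR first primer is 15 deg C below its
    Wallace value), so verification probes the pairing logic rather than
    annealing stringency.
    """
    template = NucleotideSequence(template)
    scheme = Scheme(scheme) if scheme is not None else pair.scheme
    model = model if model is not None else TmModel()
    allow_parallel = scheme is Scheme.PDPCR
    if protocol is None:
        tms = []
        for p in (pair.primer1, pair.primer2):
            tms.append(melting_temperature(p, PairingMode.ANTIPARALLEL, model))
            if allow_parallel:
                tms.append(melting_temperature(p, PairingMode.PARALLEL, model))
        anneal = max(min(tms), 0.5)  # protocol requires a positive temperature
        protocol = CycleProtocol(anneal_celsius=min(anneal, 99.0))
    report = run_pcr(
        templates=[Strand(template, label="template")],
        primers=[pair.primer1, pair.primer2],
        protocol=protocol,
        allow_parallel=allow_parallel,
        model=model,
    )
    n = len(report.amplicons)
    if n == 1:
        amp = report.amplicons[0]
        length: int | None = amp.length
        strands: tuple[str, str] | None = (str(amp.top_strand), str(amp.bottom_strand))
    else:
        length = None
        strands = None
    verified = n == 1 and length == pair.predicted_product_length
    return VerificationReport(
        verified=verified,
        scheme=scheme,
        n_amplicons=n,
        product_length=length,
        product_strands=strands,
        expected_length=pair.predicted_product_length,
        report=report,
    )
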