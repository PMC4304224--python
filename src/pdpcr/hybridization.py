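"""Primer-site search and duplex-mode-aware melting temperatures.

A primer can anneal to a single strand in two orientations:

* **antiparallel** (Watson-Crick): the primer matches the reverse
  complement of the template window; its 3' end faces the template's
  5' end, so extension proceeds toward the template 5' end.
* **parallel** (reverse Watson-Crick): the primer matches the base-wise
  complement of the window with no reversal; primer position ``i`` pairs
  with window position ``i``, both strands reading 5'->3' left to right,
  and extension proceeds toward the template 3' end.

Melting temperatures use the Wallace 2-4 rule, ``2*(A+T) + 4*(G+C)`` deg C,
the standard rough estimate for short oligonucleotides.  Parallel duplexes
are less stable than their antiparallel counterparts; thermal-denaturation
measurements place the gap at about 15 deg C over a wide range of salt
concentrations, which this module models as a constant subtractive penalty.
No nearest-neighbour parameter set exists for parallel duplexes, so a
sequence-dependent model is deliberately out of scope.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .strand import (
    NucleotideSequence,
    Strand,
    antiparallel_complement,
    parallel_complement,
)

__all__ = [
    "PairingMode",
    "TmModel",
    "BindingSite",
    "melting_temperature",
    "find_binding_sites",
]

#: Default destabilisation of a parallel (reverse Watson-Crick) duplex
#: relative to the antiparallel duplex of the same sequence, in deg C.
DEFAULT_PS_PENALTY_CELSIUS = 15.0


class PairingMode(str, enum.Enum):
    """Orientation of a primer-template duplex."""

    ANTIPARALLEL = "antiparallel"
    PARALLEL = "parallel"


@dataclass(frozen=True)
class TmModel:
    """Melting-temperature model: Wallace rule plus a parallel-duplex penalty.

    Parameters
    ----------
    rule:
        Name of the base rule.  Only ``"wallace"`` is supported.
    ps_penalty_celsius:
        Constant subtracted from the antiparallel Tm when the duplex is
        parallel-stranded.  Must be >= 0.  Default 15 deg C.
    """

    rule: str = "wallace"
    ps_penalty_celsius: float = DEFAULT_PS_PENALTY_CELSIUS

    def __post_init__(self) -> None:
        if self.rule != "wallace":
            raise ValueError(f"unsupported Tm rule: {self.rule!r}")
        if self.ps_penalty_celsius < 0:
            raise ValueError("ps_penalty_celsius must be >= 0")


@dataclass(frozen=True)
class BindingSite:
    """A primer aligned to a template window.

    Coordinates are 0-based, half-open, on the bound strand's own 5'->3'
    axis; ``end - start`` equals the primer length in both pairing modes.
    """

    template_label: str
    start: int
    end: int
    mode: PairingMode
    mismatches: int
    tm_celsius: float

    @property
    def length(self) -> int:
        return self.end - self.start


def melting_temperature(
    primer: str | NucleotideSequence,
    mode: PairingMode | str = PairingMode.ANTIPARALLEL,
    model: TmModel | None = None,
) -> float:
    """Predicted duplex Tm of ``primer`` in the given pairing mode, in deg C.

    Wallace rule ``2*(A+T) + 4*(G+C)``; parallel mode subtracts the model's
    parallel-stranded penalty.  The antiparallel value depends only on the
    primer's base composition, not on any template.
    """
    primer = NucleotideSequence(primer)
    mode = PairingMode(mode)
    model = model if model is not None else TmModel()
    at = primer.count("A") + primer.count("T")
    gc = primer.count("G") + primer.count("C")
    tm = 2.0 * at + 4.0 * gc
    if mode is PairingMode.PARALLEL:
        tm -= model.ps_penalty_celsius
    return tm


def _mismatches(primer: str, expected: str) -> int:
    return sum(a != b for a, b in zip(primer, expected))


def find_binding_sites(
    primer: str | NucleotideSequence,
    strand: Strand | str | NucleotideSequence,
    mode: PairingMode | str | None = None,
    max_mismatches: int = 0,
    min_anchor: int | None = None,
    model: TmModel | None = None,
) -> list[BindingSite]:
    """All windows of ``strand`` where ``primer`` can anneal.

    For each length-``len(primer)`` window ``w`` of the strand (taken on the
    strand's 5'->3' coordinates):

    * antiparallel mode: the primer is compared position-wise against
      ``antiparallel_complement(w)``;
    * parallel mode: against ``parallel_complement(w)``, the primer's 5' end
      aligned with the window's template-5' side.

    A window is a site when it has at most ``max_mismatches`` mismatched
    positions *and* the primer's 3'-terminal ``min_anchor`` bases match
    exactly (polymerases do not extend a frayed 3' end).  Defaults are the
    strictest setting: no mismatches, fully anchored.

    Parameters
    ----------
    mode:
        A :class:`PairingMode`, or ``None`` / ``"both"`` to search both
        orientations.
    min_anchor:
        Number of exactly-matching 3'-terminal primer bases required;
        defaults to the primer length (perfect match).
    model:
        Tm model used to score sites; defaults to :class:`TmModel`.

    Returns
    -------
    list of :class:`BindingSite`
        Sorted by descending Tm, then ascending start position.
    """
    primer = NucleotideSequence(primer)
    if not isinstance(strand, Strand):
        strand = Strand(NucleotideSequence(strand))
    if mode is None or mode == "both":
        modes = [PairingMode.ANTIPARALLEL, PairingMode.PARALLEL]
    else:
        modes = [PairingMode(mode)]
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    k = len(primer)
    if min_anchor is None:
        min_anchor = k
    if not 0 <= min_anchor <= k:
        raise ValueError("min_anchor must lie in [0, primer length]")
    seq = str(strand.seq)
    n = len(seq)
    if k > n:
        raise ValueError(
            f"primer length {k} exceeds strand length {n}"
        )
    model = model if model is not None else TmModel()

    sites: list[BindingSite] = []
    for m in modes:
        tm = melting_temperature(primer, m, model)
        for start in range(n - k + 1):
            window = seq[start : start + k]
            if m is PairingMode.ANTIPARALLEL:
                expected = str(antiparallel_complement(window))
            else:
                expected = str(parallel_complement(window))
            if _mismatches(primer, expected) > max_mismatches:
                continue
            # 3'-anchor: the last min_anchor primer bases must pair exactly.
            if min_anchor and primer[k - min_anchor :] != expected[k - min_anchor :]:
                continue
            sites.append(
                BindingSite(
                    template_label=strand.label,
                    start=start,
                    end=start + k,
                    mode=m,
                    mismatches=_mismatches(primer, expected),
                    tm_celsius=tm,
                )
            )
    sites.sort(key=lambda s: (-s.tm_celsius, s.start))
    return sites
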