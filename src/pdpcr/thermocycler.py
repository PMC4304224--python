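"""In-silico thermocycler for conventional and parallel-primed PCR.

The simulator tracks a pool of single strands with exact integer copy
counts.  Each cycle, every strand in the pool denatures into an available
template; each primer picks its best feasible binding site on each strand
(highest Tm wins, leftmost breaks ties, and a site is feasible only when
its Tm is at or above the annealing temperature) and produces one run-off
extension product per template copy.  Strands are never destroyed.

Two amplification schemes fall out of the same rules:

* **conventional**: both primers anneal antiparallel; the product duplex
  consists of a template segment and its reverse complement -- the template
  is amplified without any change of polarity.
* **PD-PCR** (parallel-DNA PCR): parallel annealing is enabled, the first
  primer anneals to the single-stranded template in parallel orientation
  and synthesises a parallel-complement copy; from the second cycle on both
  primers work conventionally on the new strands, and the final product
  duplex is {parallel_complement(T), reverse(T)} -- opposite polarity to
  the input template.

An *amplicon* is a structural notion: a duplex whose two strands are
mutual antiparallel complements and both begin (5') with one of the
supplied primers.  Linear run-off strands are reported separately, never
as products.  Because in the conventional scheme the input template itself
is one of the amplicon strands while in PD-PCR the first cycle must first
manufacture a new template, the PD-PCR copy-number trajectory trails the
conventional one by exactly one cycle under ideal efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hybridization import (
    BindingSite,
    PairingMode,
    TmModel,
    find_binding_sites,
)
from .strand import (
    NucleotideSequence,
    Strand,
    StrandOrigin,
    antiparallel_complement,
    parallel_complement,
    reverse,
)

__all__ = [
    "CycleProtocol",
    "StrandPool",
    "Amplicon",
    "AmpliconReport",
    "QPCRResult",
    "extend_primer",
    "run_pcr",
    "threshold_cycle",
    "relative_quantity",
]

DEFAULT_INITIAL_COPIES = 100
DEFAULT_THRESHOLD_FOLD = 2**10


@dataclass(frozen=True)
class CycleProtocol:
    """Thermal protocol.  Only ``cycles`` and ``anneal_celsius`` affect the
    simulation; denaturation and extension temperatures are recorded for
    provenance only."""

    cycles: int = 30
    anneal_celsius: float = 55.0
    denature_celsius: float = 95.0
    extend_celsius: float = 72.0

    def __post_init__(self) -> None:
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")
        if not 0.0 < self.anneal_celsius < 100.0:
            raise ValueError("anneal_celsius must lie in (0, 100)")


class StrandPool:
    """Multiset of single strands with non-negative integer copy counts.

    Keyed by sequence: two strands with identical sequence are the same
    species regardless of how they were made (the first-seen label and
    origin are kept).  Total copy count never decreases across a cycle.
    """

    def __init__(self, initial_copies: int = DEFAULT_INITIAL_COPIES) -> None:
        if initial_copies < 1:
            raise ValueError("initial_copies must be >= 1")
        self.initial_copies = initial_copies
        self._strands: dict[str, Strand] = {}
        self._counts: dict[str, int] = {}

    def add(self, strand: Strand, copies: int) -> None:
        if copies < 0:
            raise ValueError("copy count must be non-negative")
        key = str(strand.seq)
        if key not in self._strands:
            self._strands[key] = strand
            self._counts[key] = 0
        self._counts[key] += copies

    def count(self, seq: str) -> int:
        return self._counts.get(str(seq), 0)

    def total(self) -> int:
        return sum(self._counts.values())

    def species(self) -> list[tuple[Strand, int]]:
        """(strand, count) pairs in insertion order."""
        return [(self._strands[k], self._counts[k]) for k in self._strands]

    def labelled_counts(self) -> dict[str, int]:
        return {self._strands[k].label: self._counts[k] for k in self._strands}

    def __len__(self) -> int:
        return len(self._strands)


@dataclass(frozen=True)
class Amplicon:
    """A duplex product: two primer-initiated, mutually reverse-complementary
    strands.  ``same_polarity_as_template`` / ``opposite_polarity`` record
    whether a strand matches a segment of an input template as-is or in
    reversed (opposite-polarity) reading order."""

    top_strand: NucleotideSequence
    bottom_strand: NucleotideSequence
    length: int
    same_polarity_as_template: bool
    opposite_polarity: bool


@dataclass
class AmpliconReport:
    """Outcome of a simulated run.

    Attributes
    ----------
    amplicons:
        Distinct duplex products (see :class:`Amplicon`).
    runoff_strands:
        Labels of synthesised strands that are not part of any amplicon
        (linear, primer-bounded on one side only).
    strands:
        Label -> sequence for every species seen in the run.
    origins:
        Label -> ``"input"`` or ``"primer_extension"``.
    trajectory:
        Label -> per-cycle copy counts; index 0 is the pre-cycling state,
        index ``c`` the state after cycle ``c``.
    threshold_cycle:
        First cycle at which the total amplicon-strand count reaches
        ``DEFAULT_THRESHOLD_FOLD * initial_copies`` (None if never).
    """

    amplicons: list[Amplicon]
    runoff_strands: list[str]
    strands: dict[str, str]
    origins: dict[str, str]
    trajectory: dict[str, list[int]]
    initial_copies: int
    protocol: CycleProtocol
    allow_parallel: bool
    primers: list[str]
    threshold_cycle: int | None = None
    schema_version: int = field(default=1)

    def amplicon_strand_counts(self) -> list[int]:
        """Total copies of amplicon strands after each cycle (index 0 =
        before cycling)."""
        seqs = set()
        for a in self.amplicons:
            seqs.add(str(a.top_strand))
            seqs.add(str(a.bottom_strand))
        n_points = 1 + self.protocol.cycles
        totals = [0] * n_points
        for label, counts in self.trajectory.items():
            if self.strands[label] in seqs:
                for i, c in enumerate(counts):
                    totals[i] += c
        return totals


@dataclass(frozen=True)
class QPCRResult:
    """Threshold cycles of a target and a reference reaction, and the
    2^-dCt relative quantity derived from them."""

    ct_target: float
    ct_reference: float
    relative_quantity: float

    def __post_init__(self) -> None:
        if not self.relative_quantity > 0:
            raise ValueError("relative_quantity must be positive")


def extend_primer(
    site: BindingSite,
    template: Strand,
    primer: NucleotideSequence | None = None,
) -> Strand:
    """Run-off extension product of a primer annealed at ``site``.

    Antiparallel site: the primer's 3' end faces the template 5' end, so
    polymerisation copies ``template[0:site.end]`` and the product is its
    antiparallel complement.  Parallel site: the primer lies with its 5'
    end at the window's template-5' side and synthesis proceeds toward the
    template 3' end, appending order-preserving complements, so the product
    is ``parallel_complement(template[site.start:])``.

    The product strand is returned 5'->3' with origin ``primer_extension``.
    When ``primer`` is given it must match the site window exactly (the
    simulator only extends zero-mismatch-anchored sites).
    """
    seq = str(template.seq)
    if not (0 <= site.start < site.end <= len(seq)):
        raise ValueError("binding site does not lie on the template")
    window = seq[site.start : site.end]
    if site.mode is PairingMode.ANTIPARALLEL:
        expected = antiparallel_complement(window)
        product = antiparallel_complement(seq[: site.end])
    else:
        expected = parallel_complement(window)
        product = parallel_complement(seq[site.start :])
    if primer is not None and str(primer) != str(expected):
        raise ValueError("primer does not match the site window exactly")
    return Strand(
        seq=product,
        label=f"ext({template.label or 'strand'})@{site.start}:{site.end}:{site.mode.value[:3]}",
        origin=StrandOrigin.PRIMER_EXTENSION,
    )


def _best_site(
    primer: NucleotideSequence,
    strand: Strand,
    anneal_celsius: float,
    allow_parallel: bool,
    model: TmModel,
) -> BindingSite | None:
    mode = None if allow_parallel else PairingMode.ANTIPARALLEL
    if len(primer) > len(strand.seq):
        return None
    sites = find_binding_sites(primer, strand, mode=mode, max_mismatches=0, model=model)
    for site in sites:  # already sorted by descending Tm, then start
        if site.tm_celsius >= anneal_celsius:
            return site
    return None


def run_pcr(
    templates: list[Strand],
    primers: list[NucleotideSequence],
    protocol: CycleProtocol | None = None,
    allow_parallel: bool = False,
    model: TmModel | None = None,
    initial_copies: int = DEFAULT_INITIAL_COPIES,
    efficiency: float = 1.0,
    seed: int | None = None,
) -> AmpliconReport:
    """Simulate ``protocol.cycles`` rounds of denature/anneal/extend.

    Every strand in the pool is available as a single-stranded template
    each cycle (products made during a cycle join the pool for the *next*
    cycle).  Each primer extends from its best feasible site per strand
    species -- highest Tm, ties broken by leftmost position, parallel sites
    considered only when ``allow_parallel`` -- producing one product per
    template copy at ``efficiency`` 1.0.  With ``efficiency`` < 1 the
    number of products per species is Binomial(copies, efficiency), drawn
    from a generator seeded with ``seed`` for reproducibility.

    Parameters
    ----------
    templates:
        Input strands; may be empty (no-template control).
    primers:
        At least one primer sequence.
    allow_parallel:
        Permit parallel (reverse Watson-Crick) annealing.  Required for the
        PD-PCR scheme; the parallel Tm penalty still applies, so stringent
        annealing temperatures can make parallel sites infeasible.

    Returns
    -------
    AmpliconReport
    """
    if not primers:
        raise ValueError("at least one primer is required")
    protocol = protocol if protocol is not None else CycleProtocol()
    model = model if model is not None else TmModel()
    primers = [NucleotideSequence(p) for p in primers]
    if not 0.0 < efficiency <= 1.0:
        raise ValueError("efficiency must lie in (0, 1]")
    rng = np.random.default_rng(seed) if efficiency < 1.0 else None

    pool = StrandPool(initial_copies=initial_copies)
    for i, t in enumerate(templates):
        label = t.label or f"template_{i + 1}"
        pool.add(Strand(t.seq, label=label, origin=t.origin), initial_copies)

    # Best feasible site per (primer, strand sequence) is deterministic, so
    # cache it; the pool gains only a handful of distinct species.
    site_cache: dict[tuple[str, str], BindingSite | None] = {}
    product_labels: dict[str, str] = {}

    trajectory: list[dict[str, int]] = [pool.labelled_counts()]
    for _cycle in range(protocol.cycles):
        additions: list[tuple[Strand, int]] = []
        for strand, copies in pool.species():
            if copies == 0:
                continue
            for primer in primers:
                key = (str(primer), str(strand.seq))
                if key not in site_cache:
                    site_cache[key] = _best_site(
                        primer, strand, protocol.anneal_celsius, allow_parallel, model
                    )
                site = site_cache[key]
                if site is None:
                    continue
                if rng is None:
                    n_new = copies
                else:
                    n_new = int(rng.binomial(copies, efficiency))
                if n_new == 0:
                    continue
                product = extend_primer(site, strand, primer)
                pseq = str(product.seq)
                if pseq not in product_labels and pool.count(pseq) == 0:
                    product_labels[pseq] = f"synth_{len(product_labels) + 1}"
                label = product_labels.get(pseq)
                if label is not None:
                    product = Strand(product.seq, label=label, origin=product.origin)
                else:  # product sequence coincides with an existing species
                    existing = {str(s.seq): s for s, _ in pool.species()}
                    product = existing[pseq]
                additions.append((product, n_new))
        for product, n_new in additions:
            pool.add(product, n_new)
        trajectory.append(pool.labelled_counts())

    # Normalise trajectory: one row per label across all cycles.
    all_labels = sorted({lbl for frame in trajectory for lbl in frame})
    per_label = {
        lbl: [frame.get(lbl, 0) for frame in trajectory] for lbl in all_labels
    }

    strands = {s.label: str(s.seq) for s, _ in pool.species()}
    origins = {s.label: s.origin.value for s, _ in pool.species()}

    amplicons = _detect_amplicons(pool, primers, templates)
    synthesised = {
        s.label for s, _ in pool.species() if s.origin is StrandOrigin.PRIMER_EXTENSION
    }
    amplicon_seqs = {
        str(x) for a in amplicons for x in (a.top_strand, a.bottom_strand)
    }
    runoff = sorted(
        lbl for lbl in synthesised if strands[lbl] not in amplicon_seqs
    )

    report = AmpliconReport(
        amplicons=amplicons,
        runoff_strands=runoff,
        strands=strands,
        origins=origins,
        trajectory=per_label,
        initial_copies=initial_copies,
        protocol=protocol,
        allow_parallel=allow_parallel,
        primers=[str(p) for p in primers],
    )
    report.threshold_cycle = threshold_cycle(report, DEFAULT_THRESHOLD_FOLD)
    return report


def _detect_amplicons(
    pool: StrandPool,
    primers: list[NucleotideSequence],
    templates: list[Strand],
) -> list[Amplicon]:
    """Pairs of present strands that are mutual antiparallel complements and
    both 5'-initiated by a supplied primer."""
    primer_strs = [str(p) for p in primers]
    present = {str(s.seq) for s, c in pool.species() if c > 0}
    primed = {
        seq for seq in present if any(seq.startswith(p) for p in primer_strs)
    }
    template_seqs = [str(t.seq) for t in templates]
    seen: set[frozenset[str]] = set()
    amplicons: list[Amplicon] = []
    for seq in sorted(primed):
        partner = str(antiparallel_complement(seq))
        if partner not in primed:
            continue
        key = frozenset((seq, partner))
        if key in seen:
            continue
        seen.add(key)
        top, bottom = sorted((seq, partner))
        same_pol = any(top in t or bottom in t for t in template_seqs)
        opp_pol = any(
            top in str(reverse(t)) or bottom in str(reverse(t))
            for t in template_seqs
        )
        amplicons.append(
            Amplicon(
                top_strand=NucleotideSequence(top),
                bottom_strand=NucleotideSequence(bottom),
                length=len(top),
                same_polarity_as_template=same_pol,
                opposite_polarity=opp_pol,
            )
        )
    amplicons.sort(key=lambda a: (-a.length, str(a.top_strand)))
    return amplicons


def threshold_cycle(
    report: AmpliconReport, threshold_fold: int = DEFAULT_THRESHOLD_FOLD
) -> int | None:
    """First cycle at which the amplicon-strand count reaches
    ``threshold_fold * initial_copies``; ``None`` if never crossed.

    Cycle 0 is the pre-cycling state, so a run whose input template is
    itself an amplicon strand (the conventional scheme) can cross a
    ``threshold_fold`` of 1 at cycle 0.
    """
    if threshold_fold < 1:
        raise ValueError("threshold_fold must be >= 1")
    threshold = threshold_fold * report.initial_copies
    for cycle, total in enumerate(report.amplicon_strand_counts()):
        if total >= threshold:
            return cycle
    return None


def relative_quantity(ct_target: float, ct_reference: float) -> float:
    """Relative template abundance by the 2^-dCt method.

    ``2 ** -(ct_target - ct_reference)``: each threshold-cycle unit that the
    target lags the reference halves its inferred starting quantity.
    """
    return float(2.0 ** -(float(ct_target) - float(ct_reference)))
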