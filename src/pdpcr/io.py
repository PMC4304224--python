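"""FASTA input/output, report serialisation and run configuration.

FASTA handling goes through Biopython's ``SeqIO``; sequences are validated
against the strict {A, C, G, T} alphabet on read, with the offending
position reported.  Amplicon reports round-trip through a versioned JSON
schema; trajectories export to TSV (one row per cycle and strand) for
plotting.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from pathlib import Path
from typing import Iterable, TextIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .strand import NucleotideSequence, SequenceError
from .thermocycler import Amplicon, AmpliconReport, CycleProtocol

__all__ = [
    "read_fasta",
    "write_fasta",
    "load_demo",
    "write_report",
    "read_report",
    "report_to_dict",
    "report_from_dict",
    "trajectory_rows",
    "RunConfig",
]

REPORT_SCHEMA_VERSION = 1

#: Records in the packaged demo FASTA: a 120-nt single-stranded template
#: plus the two conventional primers (PCR-1 reverse, PCR-2 forward) and the
#: two PD-PCR primers (PD-PCR-1 parallel-annealing, PD-PCR-2 reversed).
DEMO_FASTA = Path(__file__).parent / "data" / "pdpcr_demo.fasta"


def read_fasta(path: str | Path | TextIO) -> list[tuple[str, NucleotideSequence]]:
    """Read a FASTA file into (label, validated sequence) pairs.

    Multi-line (wrapped) records are supported transparently.  Raises
    :class:`SequenceError` for empty records or characters outside the
    strict DNA alphabet, naming the record and position.
    """
    records = list(SeqIO.parse(path, "fasta"))
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    out: list[tuple[str, NucleotideSequence]] = []
    for rec in records:
        raw = str(rec.seq)
        if not raw.strip():
            raise SequenceError(f"record {rec.id!r} is empty")
        try:
            out.append((rec.id, NucleotideSequence(raw)))
        except SequenceError as exc:
            raise SequenceError(f"record {rec.id!r}: {exc}") from exc
    return out


def write_fasta(
    records: Iterable[tuple[str, str | NucleotideSequence]],
    path: str | Path | TextIO,
) -> None:
    """Write (label, sequence) pairs as FASTA (60-column wrapping)."""
    seqrecords = [
        SeqRecord(Seq(str(NucleotideSequence(seq))), id=label, description="")
        for label, seq in records
    ]
    SeqIO.write(seqrecords, path, "fasta")


def load_demo() -> dict[str, NucleotideSequence]:
    """The bundled worked-example strand set as a label -> sequence dict.

    Contains ``template`` (120 nt single-stranded), ``PCR-1``/``PCR-2``
    (conventional reverse/forward primers) and ``PD-PCR-1``/``PD-PCR-2``
    (the parallel-annealing primer and the reversed-segment primer).
    """
    return dict(read_fasta(DEMO_FASTA))


# ---------------------------------------------------------------------------
# Report serialisation


def report_to_dict(report: AmpliconReport) -> dict:
    d = dataclasses.asdict(report)
    d["schema_version"] = REPORT_SCHEMA_VERSION
    d["amplicons"] = [
        {**dataclasses.asdict(a),
         "top_strand": str(a.top_strand),
         "bottom_strand": str(a.bottom_strand)}
        for a in report.amplicons
    ]
    d["protocol"] = dataclasses.asdict(report.protocol)
    return d


def report_from_dict(d: dict) -> AmpliconReport:
    if d.get("schema_version") != REPORT_SCHEMA_VERSION:
        raise ValueError(f"unsupported report schema: {d.get('schema_version')!r}")
    amplicons = [
        Amplicon(
            top_strand=NucleotideSequence(a["top_strand"]),
            bottom_strand=NucleotideSequence(a["bottom_strand"]),
            length=a["length"],
            same_polarity_as_template=a["same_polarity_as_template"],
            opposite_polarity=a["opposite_polarity"],
        )
        for a in d["amplicons"]
    ]
    return AmpliconReport(
        amplicons=amplicons,
        runoff_strands=list(d["runoff_strands"]),
        strands=dict(d["strands"]),
        origins=dict(d["origins"]),
        trajectory={k: list(v) for k, v in d["trajectory"].items()},
        initial_copies=d["initial_copies"],
        protocol=CycleProtocol(**d["protocol"]),
        allow_parallel=d["allow_parallel"],
        primers=list(d["primers"]),
        threshold_cycle=d["threshold_cycle"],
    )


def trajectory_rows(report: AmpliconReport) -> list[tuple[int, str, int]]:
    """(cycle, strand label, copies) rows; cycle 0 is the input state."""
    rows = []
    for label in sorted(report.trajectory):
        for cycle, count in enumerate(report.trajectory[label]):
            rows.append((cycle, label, count))
    rows.sort(key=lambda r: (r[0], r[1]))
    return rows


def write_report(
    report: AmpliconReport, path: str | Path, format: str = "json"
) -> None:
    """Serialise a report to ``path`` as JSON (full, round-trippable) or
    TSV (trajectory only: cycle, strand, copies)."""
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(report_to_dict(report), indent=2, sort_keys=True) + "\n")
    elif format == "tsv":
        lines = ["cycle\tstrand\tcopies"]
        lines += [f"{c}\t{lbl}\t{n}" for c, lbl, n in trajectory_rows(report)]
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown report format: {format!r}")


def read_report(path: str | Path) -> AmpliconReport:
    """Parse a JSON report written by :func:`write_report`."""
    return report_from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Run configuration


@dataclasses.dataclass
class RunConfig:
    """Flat, fully serialisable description of a simulation run.

    A run is reproducible from its config alone: the scheme, thermal
    protocol, Tm-model parameters and the single seed that controls every
    source of randomness are all here.  Stored as flat ``key = value``
    pairs (TOML semantics); command-line flags override file values.
    """

    scheme: str = "conventional"
    cycles: int = 30
    anneal_celsius: float = 55.0
    denature_celsius: float = 95.0
    extend_celsius: float = 72.0
    ps_penalty_celsius: float = 15.0
    initial_copies: int = 100
    efficiency: float = 1.0
    seed: int = 0
    template_path: str = ""
    primers_path: str = ""
    output_path: str = ""

    def protocol(self) -> CycleProtocol:
        return CycleProtocol(
            cycles=self.cycles,
            anneal_celsius=self.anneal_celsius,
            denature_celsius=self.denature_celsius,
            extend_celsius=self.extend_celsius,
        )

    def to_toml(self) -> str:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, str):
                lines.append(f'{f.name} = "{v}"')
            else:
                lines.append(f"{f.name} = {v}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_toml(cls, text: str) -> "RunConfig":
        data = tomllib.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
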