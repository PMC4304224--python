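"""Seeded synthetic single-stranded templates for tests and demos.

Generates random DNA templates with a target GC fraction, deterministic
given a seed.  Literal-string palindromes (sequences equal to their own
reversal) are excluded: on such a template the conventional product duplex
and the opposite-polarity PD-PCR product duplex coincide, which would make
scheme-comparison property tests degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .strand import NucleotideSequence

__all__ = ["FixtureSpec", "generate_template"]

#: Shortest template accepted: room for two non-overlapping ~18-25 nt
#: primer footprints.
MIN_TEMPLATE_LENGTH = 40

#: Attained GC fraction is guaranteed within this distance of the target.
GC_TOLERANCE = 0.05


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for synthetic templates.

    Parameters
    ----------
    template_length:
        Exact length of every generated sequence, >= 40 nt.
    gc_fraction:
        Target GC content; the generated sequences hit it within +/- 5
        percentage points (the number of G/C positions is the rounded
        target count).
    seed:
        Seeds all randomness; identical specs generate identical output.
    count:
        Number of distinct templates to generate.
    """

    template_length: int = 120
    gc_fraction: float = 0.5
    seed: int = 0
    count: int = 1

    def __post_init__(self) -> None:
        if self.template_length < MIN_TEMPLATE_LENGTH:
            raise ValueError(
                f"template_length must be >= {MIN_TEMPLATE_LENGTH} "
                "for PCR-compatible fixtures"
            )
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must lie in [0, 1]")
        if self.count < 1:
            raise ValueError("count must be >= 1")


def _one_template(rng: np.random.Generator, length: int, gc: float) -> str:
    n_gc = round(length * gc)
    if not abs(n_gc / length - gc) <= GC_TOLERANCE:  # pragma: no cover
        raise ValueError("GC target unreachable at this length")
    bases = np.array(["A"] * (length - n_gc) + ["G"] * n_gc)
    rng.shuffle(bases)
    # Pick strand identity per position: A/T among the AT slots, G/C among GC.
    flips = rng.integers(0, 2, size=length)
    swap = {"A": "T", "G": "C"}
    out = [swap[b] if f else b for b, f in zip(bases, flips)]
    return "".join(out)


def generate_template(spec: FixtureSpec) -> list[NucleotideSequence]:
    """Generate ``spec.count`` distinct random templates.

    Deterministic given the spec (including seed).  Sequences equal to
    their own reversal are rejected and resampled, as are duplicates.
    """
    rng = np.random.default_rng(spec.seed)
    out: list[NucleotideSequence] = []
    seen: set[str] = set()
    attempts = 0
    while len(out) < spec.count:
        attempts += 1
        if attempts > 100 * spec.count:  # pragma: no cover - safety valve
            raise RuntimeError("could not generate enough distinct templates")
        s = _one_template(rng, spec.template_length, spec.gc_fraction)
        if s == s[::-1] or s in seen:
            continue
        seen.add(s)
        out.append(NucleotideSequence(s))
    return out
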