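# pdpcr — in-silico PCR on parallel-stranded DNA

`pdpcr` is a library (plus a thin command-line tool) for the sequence logic
of **parallel-DNA PCR (PD-PCR)**: amplification of a single-stranded DNA
template in which the first primer anneals in *parallel* (reverse
Watson-Crick) orientation rather than the usual antiparallel one, so that
the final double-stranded product has polarity *opposite* to the template.
It is aimed at molecular biologists and bioinformaticians who want to
design, check or reason about primer sets for either scheme before going
to the bench.

## The model

DNA strands are written 5′→3′ over {A, C, G, T}. Two complementarity
operations drive everything:

* **antiparallel complement** (reverse complement):
  `ap(s)ᵢ = comp(s_{n+1−i})` — the partner strand in a Watson-Crick duplex;
* **parallel complement**: `pc(s)ᵢ = comp(sᵢ)` — the partner in a
  parallel-stranded (reverse Watson-Crick) duplex, order preserved.

They satisfy `ap = rev ∘ pc = pc ∘ rev`, and each of `rev`, `ap`, `pc` is an
involution.

A primer *p* binds a strand window *w* antiparallel when `p = ap(w)`, or
parallel when `p = pc(w)` (primer position *i* pairing with window position
*i*). Duplex stability uses the Wallace rule
`Tm = 2·(A+T) + 4·(G+C) °C`, with a constant **15 °C penalty** for parallel
duplexes (parallel-stranded DNA melts about 15 °C below its antiparallel
counterpart across salt concentrations).

The thermocycler simulator tracks exact integer copy numbers. Each cycle,
every pooled strand is available as a template; each primer extends from
its best feasible site (highest Tm ≥ annealing temperature, leftmost on
ties; parallel sites only when enabled), producing one run-off product per
template copy. Antiparallel extension copies `template[0:end]` into its
reverse complement; parallel extension copies `template[start:]` into its
parallel complement. An **amplicon** is a duplex whose two strands are
mutual reverse complements, each beginning with one of the supplied
primers; run-off strands are reported separately.

* Conventional scheme: product duplex `{T, ap(T)}` — no polarity change.
* PD-PCR scheme: cycle 1 makes `pc(T)`, cycle 2 makes `rev(T)` from it, and
  from cycle 3 both primers amplify conventionally; product duplex
  `{pc(T), rev(T)}` — opposite polarity. Because the first PD-PCR cycle
  only manufactures the new template, its copy-number trajectory crosses
  any power-of-two threshold exactly one cycle after the conventional run.

Primer design is positional: conventional pairs are the template's 5′
prefix and the reverse complement of its 3′ suffix; PD-PCR pairs are the
parallel complement of the prefix and the reversal of the suffix.
`design_pdpcr_pair(T)` equals `design_conventional_pair(rev(T))` with
primer roles swapped — the algebraic form of the opposite-polarity claim.

## Worked example

The package ships a 120-nt single-stranded demo template with both primer
sets (`pdpcr.io.load_demo()`). Running
`python examples/03_simulate_schemes.py` prints:

```
conventional: 1 amplicon, 120 bp, same polarity, threshold cycle 10
PD-PCR: 1 amplicon, 120 bp, opposite polarity, threshold cycle 11

PD-PCR product strands are the template's parallel complement and reversal: True
conventional product strands are the template and its reverse complement: True
```

Both schemes amplify exactly one 120-bp product, but the two duplexes are
different molecules: the conventional product contains the template strand
itself, the PD-PCR product its parallel complement and its reversal. With
100 starting copies and ideal doubling, the conventional run reaches the
1024-fold threshold at cycle 10 and the PD-PCR run at cycle 11 — the
one-cycle lag of the parallel scheme. Single-primer and no-template
control runs yield zero amplicons (linear run-off only, no primer dimers
are modelled).

The other scripts in `examples/` cover strand transforms, binding-site
search, primer design/verification and 2^−ΔCt relative quantification.

The same operations are available from a shell:

```sh
pdpcr simulate --template t.fasta --primers p.fasta --scheme pdpcr --json report.json
pdpcr design --template t.fasta --scheme pdpcr
pdpcr sites --primers p.fasta --template t.fasta --mode both
```

## Layout

* `src/pdpcr/strand.py` — sequence validation and the orientation transforms
* `src/pdpcr/hybridization.py` — binding-site search, Tm model
* `src/pdpcr/thermocycler.py` — cycle simulation, amplicon calling, 2^−ΔCt
* `src/pdpcr/design.py` — positional primer design and verification
* `src/pdpcr/io.py`, `fixtures.py`, `cli.py` — FASTA/report I/O, synthetic
  templates, command line
* `docs/methods.md` — model assumptions, parameter choices, limitations
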