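# Methods

## Scope and model

`pdpcr` models the *sequence logic* of PCR on single-stranded templates
under two pairing geometries — antiparallel (Watson-Crick) and parallel
(reverse Watson-Crick) — not the enzymology or kinetics of amplification.
Everything reduces to string algebra over {A, C, G, T} plus a small,
deterministic bookkeeping model of cycling.

### Strand representation

Every sequence is stored 5′→3′. Polarity is never encoded by reversing a
stored string; it is metadata of containers (binding sites, amplicons,
reports). This single-representation rule is deliberate: the parallel
scheme is exactly the place where informal "flip the strand" reasoning
breeds double-reversal bugs. The alphabet is strict; IUPAC ambiguity codes
are rejected because reverse Watson-Crick pairing is defined here only for
unambiguous bases.

### Pairing and binding sites

A primer of length *k* binds a template window `w = t[start:start+k]`
(coordinates 0-based, half-open, on the bound strand's own 5′→3′ axis):

* antiparallel: primer position *j* pairs with window position *k−1−j*;
  a perfect site satisfies `primer = antiparallel_complement(w)`.
* parallel: primer position *j* pairs with window position *j* (both
  strands read 5′→3′ left-to-right); a perfect site satisfies
  `primer = parallel_complement(w)`.

Search is an exhaustive window scan (templates here are ≤ a few hundred
nt; no indexing is warranted). Defaults are the strictest setting —
`max_mismatches = 0`, `min_anchor = primer length` — because the modelled
chemistry reports only perfectly matched priming. Mismatch tolerance and a
shorter exact 3′ anchor are configurable; note that allowing mismatches is
only meaningful with `min_anchor < k`, since the anchor requires exact
pairing over the primer's 3′-terminal bases (polymerases do not extend a
frayed 3′ end).

### Melting temperature

`Tm = 2·(A+T) + 4·(G+C)` (Wallace rule), the standard rough estimate for
short oligos, with a constant `ps_penalty_celsius` (default **15 °C**)
subtracted for parallel duplexes, reflecting thermal-denaturation
measurements that place parallel-stranded DNA ~15 °C below its
antiparallel counterpart at matched salt. The penalty-constant model is a
simplification: no nearest-neighbour parameter set exists for parallel
duplexes, so sequence-context dependence beyond base composition is out of
scope, as are salt/Mg²⁺ corrections and ΔG-based duplex models. A site's
Tm is the primer's composition Tm for its mode; mismatches do not further
reduce it (with the zero-mismatch defaults this never matters).

## Thermocycler

State is a multiset of strand species with exact integer copy counts
(`initial_copies` default 100 per input template — small integers keep the
arithmetic exact and fast). Each cycle:

1. every pooled strand is available single-stranded (denaturation is
   assumed complete; its temperature is recorded but has no effect);
2. each primer takes its **best feasible site** per strand species:
   feasible means site Tm ≥ annealing temperature; best means highest Tm,
   ties broken by leftmost start; parallel sites are considered only when
   `allow_parallel` is set;
3. each (species, primer) with a site yields one run-off product per
   template copy (ideal efficiency). Products join the pool for the *next*
   cycle. Strands are never destroyed.

Extension rules: an antiparallel-annealed primer at `[start, end)` copies
the template's 5′ side, product `= antiparallel_complement(t[0:end])`; a
parallel-annealed primer copies toward the template's 3′ end, product
`= parallel_complement(t[start:])`, i.e. order-preserving complements
appended from the primer's 3′ end. The second rule is this package's
operational reading of the parallel scheme; the chemistry of extension on
a parallel-annealed primer (which hydroxyl attacks which phosphate) is not
modelled.

Parallel annealing is allowed on *any* strand when enabled — it is not
forbidden by fiat anywhere; instead the 15 °C penalty makes antiparallel
sites outcompete at stringent annealing temperatures, which encodes the
stability ordering without hard-coding the scheme.

With `efficiency < 1`, each (species, primer, cycle) event draws
Binomial(copies, efficiency) products from a NumPy generator seeded by the
caller; this exists for property tests (monotonicity, bounds) and is off
by default. With the default `efficiency = 1` the run is fully
deterministic and bit-identical across invocations.

### Amplicons, run-offs, threshold cycle

An amplicon is structural: a pair of pooled sequences that are mutual
antiparallel complements, each of whose 5′ ends equals one of the supplied
primers. Synthesised strands not in any amplicon are reported as linear
run-offs, never as products. This definition makes the negative controls
(single primer, no template) yield zero amplicons without special-casing.

`threshold_cycle(report, threshold_fold)` returns the first cycle (cycle 0
= pre-cycling input) at which the summed copies of amplicon strands reach
`threshold_fold × initial_copies`; default fold 2¹⁰.

One-cycle lag: starting from *n* template copies under ideal doubling, the
conventional amplicon-strand count after cycle *k* is `n·2^k` — the input
template is itself one of the product strands — while the PD-PCR count is
`n·(2^k − 1)`, because cycle 1 only manufactures the new template. For any
power-of-two fold ≥ 2 the PD-PCR crossing is therefore exactly one cycle
later; for non-power-of-two folds the two crossings can coincide, which is
why the default and the tests use powers of two. The simulator reports
this one-cycle model lag only; it does not attempt to fit experimentally
observed ΔCt gaps (≈14 cycles), which reflect bench efficiencies far
outside this ideal model — as do absolute Ct magnitudes, gel intensities
and chromatograms. The `2^−ΔCt` helper is plain arithmetic for comparing
threshold cycles between reactions.

## Primer design and verification

Design is purely positional — primers are read off the template ends
(optionally offset inward); no Tm balancing, GC clamps, dimer or
specificity screening. Defaults (21/22 conventional, 22/20 PD-PCR) mirror
the bundled demo set. `verify_pair` re-runs the thermocycler under the
pair's scheme and requires exactly one amplicon of the designed span.
Unless given a protocol, it sets the annealing temperature to the coolest
Tm its scheme requires, so verification probes pairing logic rather than
annealing stringency; since protocol temperatures must be positive, PD
pairs whose parallel-mode Tm is non-positive (Wallace Tm ≤ penalty, i.e.
very short primers) can legitimately fail.

## Synthetic templates

`generate_template` emulates a commercially synthesised random
single-stranded template: exact requested length (≥ 40 nt so two realistic
primer footprints fit), GC content hit by construction within ±5
percentage points (the G/C position count is the rounded target), fully
determined by one seed. Literal-string palindromes (`s == reverse(s)`) are
resampled because on them the two schemes' products coincide and
scheme-comparison tests degenerate. What it does *not* emulate: real
sequence composition bias, repeats, secondary structure, hairpins, or
synthesis errors — so passing property tests demonstrate the algebra and
the simulator's bookkeeping, not robustness to structured genomic
sequence.

## Problem sizes and numerical notes

Tests and the acceptance script run templates of 60–150 nt, primer
lengths 18–25, 6–30 cycles, 50–200 random cases per property — the scale
the method itself targets (short synthetic templates); all arithmetic is
exact-integer or small-float, with no tolerances beyond float equality on
Wallace sums. Site ordering is deterministic (descending Tm, then
ascending start), and reports serialise to a versioned JSON schema that
round-trips bit-identically.

## Known limitations

* No enzymology: whether a polymerase actually extends parallel-annealed
  primers is outside the model; the simulator encodes the scheme's
  sequence consequences only.
* Constant Tm penalty; no nearest-neighbour, salt, or ΔG modelling.
* No primer-dimer or hairpin screening (none are modelled to form).
* Ideal or uniform-Bernoulli efficiency only; no per-sequence bias, no
  plateau phase, no fluorescence chemistry.
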