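"""Both amplification schemes on the same single-stranded template.

A conventional run copies the template without changing its polarity.  A
PD-PCR run -- first primer annealing in parallel orientation -- yields a
product of opposite polarity: its strands are the parallel complement and
the reversal of the template.  One template, two different 120-bp products.
"""

from pdpcr import (
    CycleProtocol,
    Strand,
    antiparallel_complement,
    parallel_complement,
    reverse,
    run_pcr,
)
from pdpcr.io import load_demo

demo = load_demo()
T = demo["template"]
template = Strand(T, label="template")
protocol = CycleProtocol(cycles=30, anneal_celsius=55.0)

conv = run_pcr([template], [demo["PCR-1"], demo["PCR-2"]], protocol)
pd = run_pcr([template], [demo["PD-PCR-1"], demo["PD-PCR-2"]], protocol,
             allow_parallel=True)

for name, rep in (("conventional", conv), ("PD-PCR", pd)):
    amp = rep.amplicons[0]
    pol = "same" if amp.same_polarity_as_template else "opposite"
    print(f"{name}: {len(rep.amplicons)} amplicon, {amp.length} bp, "
          f"{pol} polarity, threshold cycle {rep.threshold_cycle}")

amp = pd.amplicons[0]
print()
print("PD-PCR product strands are the template's parallel complement and reversal:",
      {str(amp.top_strand), str(amp.bottom_strand)}
      == {str(parallel_complement(T)), str(reverse(T))})
conv_amp = conv.amplicons[0]
print("conventional product strands are the template and its reverse complement:",
      {str(conv_amp.top_strand), str(conv_amp.bottom_strand)}
      == {str(T), str(antiparallel_complement(T))})
print()
print("The PD-PCR threshold cycle is one later than the conventional one:")
print("the first PD-PCR cycle only manufactures the new template, so the")
print("exponential phase starts one cycle behind.")
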