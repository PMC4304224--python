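"""Strand algebra: the three orientation transforms on the demo template.

Each primer in the bundled demo set is a transform of one end of the
120-nt single-stranded template, so applying the transforms reproduces the
primers exactly.
"""

from pdpcr import antiparallel_complement, parallel_complement, reverse
from pdpcr.io import load_demo

demo = load_demo()
T = demo["template"]

print(f"template ({len(T)} nt): {T[:30]}...{T[-20:]}")
print(f"antiparallel_complement(3'-end 22 nt) = {antiparallel_complement(T[-22:])}")
print(f"  -> equals PCR-1 (conventional reverse primer): "
      f"{antiparallel_complement(T[-22:]) == demo['PCR-1']}")
print(f"parallel_complement(5'-end 22 nt)     = {parallel_complement(T[:22])}")
print(f"  -> equals PD-PCR-1 (parallel-annealing primer): "
      f"{parallel_complement(T[:22]) == demo['PD-PCR-1']}")
print(f"reverse(3'-end 20 nt)                 = {reverse(T[-20:])}")
print(f"  -> equals PD-PCR-2 (opposite-polarity primer):  "
      f"{reverse(T[-20:]) == demo['PD-PCR-2']}")
print()
print("The reverse complement pairs antiparallel (Watson-Crick); the")
print("order-preserving complement pairs parallel (reverse Watson-Crick);")
print("reversal alone gives the opposite-polarity reading of a strand.")
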