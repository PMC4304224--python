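"""Relative quantification from threshold cycles (2^-dCt).

Comparing two reactions' threshold cycles: every cycle the target lags the
reference halves its inferred relative abundance.  The in-silico model's
one-cycle PD-PCR lag corresponds to a relative quantity of 0.5; much larger
experimental dCt values reflect bench efficiencies the simulator does not
model.
"""

from pdpcr import relative_quantity

for ct_target, ct_reference in ((11.0, 10.0), (23.29, 9.26)):
    q = relative_quantity(ct_target, ct_reference)
    print(f"Ct(target)={ct_target:6.2f}  Ct(reference)={ct_reference:6.2f}  "
          f"2^-dCt = {q:.3g}")

print()
print("A dCt of 1 cycle means half the reference quantity; a dCt of ~14")
print("cycles corresponds to ~6e-5 of it.")
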