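"""Formula arithmetic: masses, unsaturation, aromaticity and class labels.

Parses a few formulas reported from macroalgal extracts and prints the
descriptors the profiling workflow is built on.
"""

from massdiv import compound_class, descriptors, heteroatomic_group, parse_formula

for text in ("C6H8O6", "C7H6O5", "C18H34O5", "C20H24O8", "C10H18N2O3"):
    f = parse_formula(text)
    d = descriptors(f)
    print(f"{text:>12}  M={d.monoisotopic_mass:.6f} Da  [M-H]-={d.mz_deprotonated:.6f}  "
          f"DBE={d.dbe:.0f}  AImod={d.aimod:.3f}  H/C={d.h_c:.2f}  O/C={d.o_c:.2f}  "
          f"{heteroatomic_group(f):>6}  {compound_class(f)}")

# DBE counts rings+double bonds; AImod > 0.5 marks aromatic character
# (gallic acid C7H6O5 classifies as a polyphenol, the fatty acid
# C18H34O5 as aliphatic unsaturated).
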