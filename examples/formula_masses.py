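"""Monoisotopic masses from Hill-notation formulas.

The masses printed here are the neutral-formula monoisotopic values used to
verify high-resolution mass spectra of synthesized inhibitors (EI radical
cations carry the neutral mass to four decimals).
"""

from selectiscreen.chem_io import average_mass, monoisotopic_mass, parse_formula

for text in ("C23H21NO4", "C24H23NO4", "C22H20N2O4", "C22H20N2O5"):
    f = parse_formula(text)
    print(f"{f.hill():14s} monoisotopic {monoisotopic_mass(f):9.4f} Da"
          f"   average {average_mass(f):7.2f} amu")
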