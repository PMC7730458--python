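"""Score a posed ligand with the five-term binding free energy function.

Builds the synthetic mutant receptor and its planted hinge binder, then
prints the term-by-term breakdown of ΔG_b^aq in kcal/mol.  A negative total
means the pose is predicted to be stable; e_dehydration is the penalty the
ligand pays for shedding its hydration shell (a pure ligand property).
"""

from selectiscreen.energy import binding_free_energy
from selectiscreen.fixtures import FixtureSpec, make_planted_binder, make_receptor_pair
from selectiscreen.screen import detect_hinge_hbonds

spec = FixtureSpec(seed=7)
mut, wt = make_receptor_pair(spec)
binder, center = make_planted_binder(mut, spec)

breakdown = binding_free_energy(mut, binder)
print(f"planted binder ({binder.smiles}) against the mutant pocket:")
for term, value in breakdown.as_dict().items():
    print(f"  {term:15s} {value:+8.3f} kcal/mol")

n, contacts = detect_hinge_hbonds(mut, binder, None)
print(f"hinge hydrogen bonds (< 3.5 A heavy-atom distance): {n}")
for lig_atom, rec_atom, dist in contacts:
    res = mut.atoms[rec_atom].residue
    print(f"  ligand atom {lig_atom} ... {res[0]}{res[1]} {mut.atoms[rec_atom].name}"
          f"  {dist:.2f} A")
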