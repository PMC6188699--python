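"""Theoretical average mass of a protein variant, with disulfide correction.

Builds the Asp53Ser/Asp55Ser variant of the PAF antifungal protein and
prints the reduced- and oxidized-form masses.  Comparing the computed
oxidized mass against an ESI-MS measurement tells how many disulfide
bonds formed (each bond removes two hydrogens, ~2 Da).
"""

from ionprobe import datasets, protein_average_mass

wild_type = datasets.PAF_SEQUENCE
variant = datasets.apply_mutations(wild_type, "D53S", "D55S")

reduced = protein_average_mass(variant, n_disulfides=0)
oxidized = protein_average_mass(variant, n_disulfides=3)

print(f"variant sequence ({len(variant)} aa): {variant}")
print(f"reduced form   : {reduced:.3f} kDa")
print(f"3 disulfides   : {oxidized:.3f} kDa")
print("A measured mass ~6 Da below the reduced value indicates that all")
print("three intramolecular disulfide bonds are formed.")
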