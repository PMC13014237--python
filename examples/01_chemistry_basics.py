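"""Parse SMILES into directed graphs; compare molecules by fingerprint and
scaffold.

Run:  python examples/01_chemistry_basics.py
"""

from funcscreen import (morgan_fingerprint, murcko_scaffold, parse_smiles,
                        tanimoto)

aspirin = parse_smiles("CC(=O)Oc1ccccc1C(=O)O", "aspirin")
salicylic = parse_smiles("OC(=O)c1ccccc1O", "salicylic_acid")
caffeine = parse_smiles("Cn1cnc2c1c(=O)n(C)c(=O)n2C", "caffeine")

print(f"aspirin: {aspirin.n_atoms} heavy atoms, "
      f"{aspirin.n_directed_bonds // 2} bonds (stored in both directions)")

fp_a = morgan_fingerprint(aspirin)
fp_s = morgan_fingerprint(salicylic)
fp_c = morgan_fingerprint(caffeine)
print(f"Tanimoto(aspirin, salicylic acid) = {tanimoto(fp_a, fp_s):.3f}")
print(f"Tanimoto(aspirin, caffeine)       = {tanimoto(fp_a, fp_c):.3f}")
# The first pair shares the salicylate substructure, so its 2D similarity is
# much higher; unrelated scaffolds score near zero.

for mol in (aspirin, caffeine):
    print(f"Murcko scaffold of {mol.mol_id}: "
          f"{murcko_scaffold(mol).scaffold_smiles!r}")
# Scaffolds are the ring systems + linkers; they define the equivalence
# classes the scaffold-balanced splitter keeps within one partition.
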