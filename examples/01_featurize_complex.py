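"""Featurize a single protein-ligand complex.

Builds a toy element-typed complex (a realistic stand-in for a parsed
PDB + Mol2/PDBQT pair), then computes the two structural feature blocks:
the 36 element-pair contact counts and the six Vina-style terms.
"""

import numpy as np

from sfbench import ELEM36_NAMES, VINA_NAMES, elem_pair_features, gen_toy_complex, vina_features

cx = gen_toy_complex("demo", n_protein=60, n_ligand=15, seed=3)
print(f"complex {cx.complex_id}: {len(cx.protein_atoms)} protein atoms, "
      f"{len(cx.ligand_atoms)} ligand atoms, n_rot={cx.n_rot}")

contacts = elem_pair_features(cx, cutoff=12.0)
print(f"\nelement-pair contact counts (12 Å cutoff), {contacts.sum()} total:")
for name, count in zip(ELEM36_NAMES, contacts):
    if count:
        print(f"  {name:>5}: {count}")
# Each count is the number of protein-ligand heavy-atom pairs of that
# element combination within the cutoff; dense counts like C.C dominate.

vina = vina_features(cx)
print("\nVina-style terms (8 Å cutoff):")
for name, value in zip(VINA_NAMES, vina):
    print(f"  {name:>12}: {value:.3f}")
# Gauss1/Gauss2 measure steric complementarity, Repulsion penalises
# overlap, Hydrophobic and HBonding count favourable typed contacts, and
# Nrot is the ligand's rotatable-bond (flexibility) count.
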