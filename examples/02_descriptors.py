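"""Compute the three descriptor families for one molecule.

Shows the pharmacophore typing, the CATS pair histogram's non-zero bins,
the structural-key popcount and a few physicochemical panel entries for
aspirin.
"""

import numpy as np

from herbscreen.descriptors import (
    PANEL2D_NAMES,
    assign_ppp,
    cats_bin_names,
    cats_vector,
    panel2d,
    structural_keys,
)

smiles = "CC(=O)Oc1ccccc1C(=O)O"  # aspirin
types = assign_ppp(smiles)
print("pharmacophore types per atom:", [sorted(t) for t in types])

vec = cats_vector(smiles)
names = cats_bin_names()
nonzero = [(names[i], int(v)) for i, v in enumerate(vec) if v]
print(f"CATS: {len(nonzero)} non-zero of 150 bins, e.g. {nonzero[:5]}")
print("Each bin counts atom pairs of two pharmacophore types at a given")
print("bond-path distance (0-9).")

keys = structural_keys(smiles)
print(f"structural keys: {int(keys.sum())} of 166 bits set")

panel = dict(zip(PANEL2D_NAMES, panel2d(smiles)))
print("panel2d excerpt:", {k: round(panel[k], 2)
                           for k in ("mw", "logp", "tpsa", "hbd", "hba")})
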