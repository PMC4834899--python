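"""Pedigree relationship algebra on a pedigree with a full-sib mating.

Builds the numerator relationship matrix A, the 2n x 2n gametic
relationship matrix L and the incidence M, and verifies the identity
0.5 * M L M' = A.  Individual 5 is the offspring of full sibs, so its
inbreeding coefficient is 0.25 and its two gametes covary by that amount.
"""

import numpy as np

from poegp import Pedigree, relationship_matrices

ped = Pedigree(ids=[1, 2, 3, 4, 5], sires=[0, 0, 1, 1, 3], dams=[0, 0, 2, 2, 4])
rel = relationship_matrices(ped)

print("A:")
print(rel.A)
print(f"\ndiag(A)[5] = {rel.A[4, 4]} -> inbreeding F = {rel.A[4, 4] - 1.0}")
r_pat, r_mat = rel.gamete_rows[5]
print(f"cov between the two gametes of individual 5: L[{r_pat},{r_mat}] = "
      f"{rel.L[r_pat, r_mat]}")
err = np.abs(0.5 * rel.M @ rel.L @ rel.M.T - rel.A).max()
print(f"max |0.5 M L M' - A| = {err:.2e}  (identity holds exactly)")
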