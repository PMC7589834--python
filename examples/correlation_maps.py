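"""DCCM and essential-dynamics PCA on an ensemble with planted structure.

Samples a harmonic ensemble in which residues 1-10 move together
(pairwise correlation 0.9) while residues 11-20 move independently,
then shows that the cross-correlation map and the PCA spectrum recover
exactly that design.
"""

import numpy as np

from vardyn import (
    HarmonicEnsembleSpec, build_ca_chain, compute_dccm, compute_pca,
    cumulative_variance, sample_harmonic_ensemble,
)

n = 20
cov = np.eye(n)
cov[:10, :10] = 0.9
np.fill_diagonal(cov, 1.0)

traj = sample_harmonic_ensemble(
    HarmonicEnsembleSpec(build_ca_chain(n), cov, n_frames=5000, seed=3))

dccm = compute_dccm(traj, selection="CA", superpose=False)
block = dccm.matrix[:10, :10][~np.eye(10, dtype=bool)]
cross = dccm.matrix[:10, 10:]

print(f"mean correlation inside the coupled block : {block.mean():.3f}"
      "  (planted 0.9)")
print(f"largest |correlation| across the two blocks: "
      f"{np.abs(cross).max():.3f}  (planted 0.0)")

pca = compute_pca(traj, selection="CA", superpose=False)
print(f"\nPC1 variance fraction: {pca.variance_fractions[0]:.3f}")
print(f"variance captured by the first 3 PCs: "
      f"{cumulative_variance(pca, 3):.3f}")
print("\nThe coupled block behaves as one collective mode, so a few")
print("principal components dominate; PC1 residue mobility singles out")
print("the residues carrying that mode:")
print(pca.pc1_residue_mobility.round(2).to_string())
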