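"""Mutual-information map of correlated torsional motions.

Plants two coupled residue communities (a tightly switched core plus
partially following satellites) in otherwise independent torsion data,
estimates pairwise MI with permutation bias correction and significance
masking, and clusters the residues on the corrected matrix.
"""

import numpy as np

from rexmap import mutinf

rng = np.random.default_rng(17)
n_frames, n_res = 800, 12
angles = rng.uniform(-180, 180, size=(n_frames, n_res))

# two hidden conformational switches drive residues 0-2 and 6-8 ...
sw1 = rng.integers(0, 2, size=n_frames)
sw2 = rng.integers(0, 2, size=n_frames)
for r in (0, 1, 2):
    angles[:, r] = np.where(sw1 == 0, -60.0, 60.0) + rng.normal(0, 10, n_frames)
for r in (6, 7, 8):
    angles[:, r] = np.where(sw2 == 0, 170.0, -90.0) + rng.normal(0, 10, n_frames)
# ... and are partially relayed to satellite residues
for r, sw, frac in ((3, sw1, 0.5), (4, sw1, 0.4), (9, sw2, 0.5), (10, sw2, 0.4)):
    follow = rng.random(n_frames) < frac
    angles[follow, r] = (np.where(sw[follow] == 0, -120.0, 120.0)
                         + rng.normal(0, 10, follow.sum()))

out = mutinf.significance_filter(angles, n_permutations=100, alpha=0.01,
                                 n_bins=24, seed=18)
strong = np.argwhere(np.triu(out.mask & (out.mi > 0.3), k=1))
print("strongly coupled residue pairs:", [tuple(int(i) for i in p) for p in strong])
labels = mutinf.cluster_residues(out, n_clusters=4)
print("cluster labels:", labels)
frac_sig = out.mask[~np.eye(n_res, dtype=bool)].mean()
print(f"fraction of significant off-diagonal pairs: {frac_sig:.3f}")
# The corrected MI matrix resolves the two planted communities (each core
# clusters with its satellites) and leaves the uncoupled residues apart;
# spurious background MI is removed by the permutation correction.
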