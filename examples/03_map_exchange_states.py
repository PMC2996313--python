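"""Identify the major/minor exchange states behind an Rex profile.

Runs the three search strategies on a synthetic ensemble: H-bond frame sets
(Method 1), a 2-macrostate kinetic model (Method 2), and the hybrid
macrostate search seeded by minor-signature H-bonds (Method 3).
"""

import rexmap

res = rexmap.run_exchange_pipeline(
    n_micro=200, n_macro=8, n_paths=60, path_length=2000, seed=13
)

print(f"Method 1 (H-bond search):   C_loop = {res.method1.correlation_loop:+.4f}  "
      f"minor bonds = {res.method1.minor_members}")
print(f"Method 2 (2 macrostates):   C_loop = {res.method2.correlation_loop:+.4f}")
print(f"Method 3 (hybrid, 8 macro): C_loop = {res.method3.correlation_loop:+.4f}  "
      f"minor macrostates = {res.method3.minor_members}")
print(f"planted minor macrostates: {sorted(res.model.minor_macrostates)}")
print(f"minor fraction: recovered {res.method3.minor_fraction:.3f} "
      f"vs planted {res.model.minor_mass:.3f}")
print(f"exact frame-level recovery: {res.recovered_minor_matches_truth()}")
# The hybrid search finds the planted minor blocks and a loop correlation
# near 1, while the 2-macrostate model correlates poorly: two exchange
# states are visible to the experiment, but they are unions of several
# metastable conformers, not two single basins.
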