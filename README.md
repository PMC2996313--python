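# rexmap

Map slow (microsecond–millisecond) conformational exchange with
hierarchical Markov state models.

NMR relaxation experiments report, residue by residue, the excess
transverse relaxation R<sub>ex</sub> caused by slow exchange between
conformers — but they rarely reveal *which* conformers exchange.  `rexmap`
bridges that gap for ensembles of simulated conformations: it clusters an
ensemble into rapidly interconverting **microstates** and metastable
**macrostates** (a Markov state model, MSM), then groups macrostates into a
**major** and a **minor exchange state** whose predicted relative
R<sub>ex</sub> profile best matches experiment, and finally analyzes the
kinetic network this produces (most-travelled pathways, kinetic hubs,
population comparisons, NOE consistency, and mutual-information maps of
correlated motions).

## The model

For fast two-state exchange the exchange broadening of residue *i* obeys

    Rex(i) ∝ p_A · p_B · Δω(i)² · Q / k_ex

where `p_A, p_B` are the major/minor populations, `Δω(i)` the chemical-shift
difference between the states at residue *i*, `k_ex` the exchange rate and
`Q` a pulse-train quenching factor.  `k_ex` and `Q` are residue-independent,
so the *relative* profile `Rex(i)/Rex(ref)` depends only on `Δω(i)²` — a
quantity the package estimates from any candidate partition of the ensemble
as the difference of per-state chemical-shift means.  Candidate partitions
are ranked by the Pearson correlation *C* between estimated and experimental
relative R<sub>ex</sub> over the flexible-loop residues.  Three searches are
provided:

1. **Method 1** — candidate minor states are unions of H-bond-defined frame
   sets (H-bond rearrangement tracks the slow motion);
2. **Method 2** — the two macrostates of a 2-state MSM;
3. **Method 3** — subsets of a many-macrostate MSM, restricted to
   macrostates carrying the minor-signature H-bonds found by Method 1.

The MSM itself is built with farthest-point (k-centers) clustering, a
symmetrized transition-matrix estimate, stationary/implied-timescale/
Chapman–Kolmogorov validation, spectral (Perron-cluster) lumping and a
simulated-annealing refinement that maximizes metastability
`Σ_m T(m,m)`.  The macrostate network is analyzed with free-energy edge
weights `w_ij = −ln T_ij`, betweenness centrality (Dijkstra shortest paths),
a greedy highest-betweenness spanning backbone, Kullback–Leibler comparison
of population vectors, r⁻⁶-averaged NOE violation tables, and a
MutInf-style mutual-information analysis of torsional and Cα motions with
permutation bias correction and significance masking.

A fully seeded synthetic generator (`rexmap.synthetic`) plants a known
hierarchical chain (block-structured transition matrix with exact planted
stationary populations), a known Δω profile, minor-signature H-bonds and
Gaussian emissions, so every stage of the pipeline can be tested against a
recoverable ground truth.

## Worked example

```
$ python examples/03_map_exchange_states.py
Method 1 (H-bond search):   C_loop = +0.9986  minor bonds = ('loop_hb_minor_A', 'loop_hb_minor_B')
Method 2 (2 macrostates):   C_loop = +0.8605
Method 3 (hybrid, 8 macro): C_loop = +0.9986  minor macrostates = (6, 7)
planted minor macrostates: [6, 7]
minor fraction: recovered 0.096 vs planted 0.110
exact frame-level recovery: True
```

The hybrid search (Method 3) finds exactly the two planted minor
macrostates and a loop correlation near 1, and its recovered minor-state
population (9.6%) matches the planted stationary mass (11.0%) to within
sampling error.  The
2-macrostate model correlates far worse: the exchange states seen by the
experiment are unions of several metastable conformers, not two single
free-energy basins.  The other `examples/*.py` scripts demonstrate the
generator, MSM validation, network analytics, NOE checking and the
mutual-information machinery in the same style.

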