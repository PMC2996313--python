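# Methods

## Scope and model

`rexmap` implements a pipeline for interpreting slow-exchange NMR
relaxation profiles with hierarchical Markov state models (MSMs) of a
conformational ensemble, plus a synthetic-data generator that plants a
recoverable ground truth for every stage.  The pipeline assumes:

* the ensemble's slow kinetics are Markovian at the chosen lag time on a
  discrete microstate space (validated by implied timescales and the
  Chapman–Kolmogorov test);
* exchange observed by NMR is effectively two-state at the resolution of
  the experiment, with residue-independent exchange rate `k_ex` and
  quenching factor `Q`, so only the relative profile
  `Rex(i)/Rex(ref) = Δω(i)²/Δω(ref)²` carries cross-residue information;
* `Δω(i)` is estimable as the difference of per-state chemical-shift means
  over frames assigned to each exchange state.

Candidate major/minor partitions are ranked by the Pearson correlation `C`
between estimated and experimental relative Rex over the loop residues
(default residues 11–16, reference residue 12); whole-protein correlation
and t-transform two-sided p-values (n−2 degrees of freedom) are reported
alongside.  Ties in `C` break toward the smaller minor state, then
lexicographically, so searches are deterministic.

## Synthetic generator: what it emulates

The generator produces what MD plus a shift predictor would feed the
pipeline, with known truth:

* **Kinetics.**  `n_micro` microstates (default 1,000) in `n_macro`
  near-equal blocks (default 40).  Block-level transitions follow a
  Metropolis rule on a sparse random neighbour graph (shuffled ring plus
  chords, degree ≤ 3 — a complete graph would make betweenness
  degenerate), so the planted block populations are the exact stationary
  distribution by detailed balance.  Within-block transitions are uniform
  (microstates are "rapidly interconverting" with no internal structure).
  Each block retains at least `p_stay` (default 0.95) of its row mass; the
  Metropolis acceptance makes heavier blocks stickier, which produces the
  attractor behaviour real landscapes show.  Default populations: two
  attractor blocks at 30% and 18%, a two-block minor exchange state at 11%
  (split 6.6%/4.4%), the rest floored Dirichlet.
* **Chemical shifts.**  Per-frame, per-residue Gaussians
  (`shift_sigma = 0.2 ppm`) around per-*macrostate* means.  Every block
  carries its own baseline (`block_sigma = 0.4 ppm` of conformer
  heterogeneity around a common profile): distinct conformers genuinely
  differ in their shifts.  On top of this the minor blocks carry planted
  exchange offsets whose population-weighted pool equals the designed Δω
  profile (peaks of 2.0/1.6/1.2 ppm at loop residues 12/13/15, small
  baseline elsewhere).  The two minor blocks split the peak offsets
  complementarily (70/30), so only their *union* reproduces the full
  profile; single blocks correlate visibly worse.  This design choice is
  load-bearing: with exchange-state-level emissions, every minor-enriched
  frame set yields the same Δω *shape* up to a uniform scale, and scale
  cancels under reference normalization — the search objective would be
  flat and recovery undecidable.  Conformer-level heterogeneity is also
  what makes a 2-macrostate model correlate poorly, mirroring the
  qualitative finding that two kinetic basins cannot explain the data.
* **Experimental profile.**  Derived from the *realized* pooled contrast
  between stationary-weighted minor and major emission means (what an
  ideal experiment on the emitted ensemble would measure), normalized at
  the reference residue; optional Gaussian scatter.
* **H-bonds.**  Bernoulli indicators per frame.  Signature bonds exist
  only in minor conformers (one across both minor blocks, one in the first
  block only); scaffold bonds occur with block-specific frequency drawn
  uniform(0.1, 0.9).  Block dependence matters for the same reason as the
  shift heterogeneity: a bond whose occurrence is independent of conformer
  would define frame sets that mimic the exchange contrast exactly.
* **Coordinates / restraints.**  Gaussian clouds around per-microstate
  reference geometries (for k-centers and RMSD tests); restraint upper
  bounds equal reference distances plus a slack.

What the generator does *not* emulate: force-field physics, solvent,
autocorrelated noise within a state, residue-residue shift covariance, and
experimental Rex measurement error (off by default).  Passing recovery
tests therefore demonstrates correctness of the algorithms under the
stated statistical assumptions, not robustness to all properties of real
MD/NMR data.

## MSM construction choices

* **k-centers**: farthest-point traversal, first center = frame 0, ties to
  the lowest index (deterministic); either a fixed `k` or a target
  covering radius (the 3 Å loop-RMSD usage).  Classical 2-approximation
  guarantee is tested against a brute-force optimal oracle.
* **Estimator**: sliding-window counts that never cross path boundaries;
  default symmetrized `(C + Cᵀ)/2` before row normalization (detailed
  balance); raw row-normalization available.  All-zero rows become
  self-loops.
* **Stationary distribution**: leading left eigenvector; for reducible
  chains, mass is placed on the largest closed communicating class with a
  warning.
* **PCCA**: spectral lumping from the top-`n_macro` eigenvectors (computed
  via the π-symmetrized form when the chain is reversible).  The default
  assignment is the inner-simplex/max-membership method; the classic
  recursive sign-splitting variant is available (`method="sign"`).  The
  simplex method was made the default because sign-splitting into ~40
  clusters on sampled matrices is fragile, while the simplex variant
  reaches ARI ≥ 0.9 against the planted lumping at 10⁶ sampled steps.
  States outside the stationary support (never visited) are attached to
  their most strongly connected active macrostate.
* **Annealing**: metastability `Σ_m T_macro(m,m)` maximized by
  single-microstate reassignments with Metropolis acceptance and geometric
  cooling (default 50·n_micro proposals, T from 1e-2 to 1e-7 — scale set
  by typical per-move metastability changes); moves emptying a macrostate
  are rejected; the best-seen assignment is returned, so the result never
  degrades the initialization.  Incremental flow-matrix updates make each
  proposal O(n).
* **Validation**: implied timescales `-τ/ln λ` (moduli for complex pairs,
  infinite above 1−1e-12); CK deviations `max|T_emp(kτ) − T(τ)^k|`
  restricted to rows observed at the longer lag; bootstrap over contiguous
  path segments resampled with replacement (default 10 segments).

## Exchange-state searches

Method 1 enumerates unions of H-bond frame sets exhaustively when at most
12 bonds are observed (default), otherwise exhaustively over single bonds
plus greedy agglomeration; the smaller-population side of the winning
split is the minor state.  Bonds essentially absent from the major state
(default tolerance: <1% of a bond's frames on the major side) are reported
as minor-signature bonds.  Method 3 enumerates subsets of the macrostates
containing at least one signature-bond frame, refusing above
`max_eligible` (default 20) because the enumeration is `2^eligible − 1`.
Method 2 is the `n_macro = 2` special case with no H-bond filter.  The
macrostate-count scan lumps the same microstate model at each requested
count and reports the best loop correlation per count.

## Network, NOE and MI choices

* Edge weights `w_ij = −ln T_ij` (no self-loops; no edge where `T_ij = 0`);
  betweenness uses raw fractional shortest-path membership counts with
  endpoints excluded; the graph is symmetrized by keeping the smaller of
  the two directed weights (both modes exposed).  The backbone adds edges
  in descending edge-betweenness (ties: lower weight, then lexicographic)
  until connected and spanning.  The kinetic hub is the betweenness argmax
  (ties: larger population, then lower id).
* Apo/holo character: `(rmsd_apo − rmsd_holo)/(rmsd_apo + rmsd_holo)`,
  the normalized difference satisfying the required range and endpoint
  semantics (−1 exactly apo-like, +1 exactly holo-like).
* KL divergence in nats, explicit `inf` when the support condition fails
  and no pseudocount is given.
* NOE ensemble distances average as `(Σ w_k r_k⁻⁶)^(−1/6)` (NOE
  intensities average as r⁻⁶; a linear mode is provided for comparison);
  violations are computed on the ensemble-averaged distance and binned
  (0,1], (1,2], (2,3], >3 Å by default, with an exact-zero row;
  percentages are exact to two decimals.
* Mutual information uses fixed 15° torsion bins (24 bins; deterministic
  and adequate at this scale, replacing adaptive binning), nats, joint
  histograms; per-residue multi-torsion aggregation is by summing
  per-torsion-pair MI.  Bias correction subtracts the mean MI over seeded
  frame permutations of one member (marginals preserved); entries with
  permutation `p = (1 + #{null ≥ obs})/(n_perm + 1) ≥ α` are zeroed.  Note
  `α` below `1/(n_perm+1)` is unreachable (warned).  Cartesian MI first
  superposes frames on the ensemble mean (one refinement pass) and sums MI
  over the three components.  Residue clustering is agglomerative (average
  linkage) on `max(MI) − MI`.  The periodic-image filter removes frames
  with any heavy-atom pair within the cutoff of one of the 26 neighbour
  images of an orthorhombic box.

## Numerical conventions and degenerate inputs

Stationary residual tolerance 1e-10 (polished by power iteration);
transition-matrix row sums validated to 1e-10 (generator to 1e-12);
detailed-balance check for the symmetric eigensolver at 1e-8; shortest-path
ties resolved by the solver with scores compared at 1e-9 in tests.  Empty
partitions, zero-variance correlation vectors, a vanishing Rex at the
reference residue, coincident atoms in r⁻⁶ averages, zero-mass macrostates
in lumping, disconnected graphs in backbone construction, and missing box
lengths in the image filter all raise informative errors rather than
propagating NaNs.

## Problem sizes

The default end-to-end run uses 200 paths × 5,500 steps = 1.1 M frames on
the 1,000-microstate / 40-macrostate model — the package's chosen study
scale, matching the order of magnitude a short-trajectory ensemble
protocol produces.  Unit tests use 200-microstate / 8-macrostate models
with 5×10⁴–10⁶ steps; the MI null calibration uses 50 independent
torsions, 400 frames, 100 permutations.

## Known limitations

Exact frame-level recovery of the minor state requires the lumping to
isolate the minor blocks perfectly; this holds robustly at the default
sampling but degrades below ~10⁵ aggregate steps.  The loop correlation is
computed over six residues, so it is a weak discriminator between
candidates that reproduce the Δω shape; the generator's conformer
heterogeneity is what gives the true partition a decisive margin, and
ensembles lacking such heterogeneity would leave the search on a plateau.
Betweenness assumes comparable residency times across macrostates (the
stated premise of the free-energy edge weights).  The MI module implements
fixed-bin estimation with a permutation null only — no higher-order or
adaptive corrections.
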