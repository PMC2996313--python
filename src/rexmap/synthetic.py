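"""Synthetic conformational-ensemble generator with planted ground truth.

Everything downstream (microstate clustering, kinetic lumping, exchange-state
search, network analytics) is tested against data produced here, where the
"right answer" is known by construction:

* a block-structured microstate Markov chain whose blocks are the planted
  macrostates, with a designated minor subset of blocks carrying ~11% of the
  stationary mass (the NMR-invisible minor species);
* per-frame chemical-shift emissions whose macrostate-dependent means encode
  a planted per-residue |delta-omega| profile between the pooled minor and
  major exchange states;
* per-frame hydrogen-bond indicator emissions, with designated bonds present
  only in the minor state (the H-bond signature the state search exploits);
* Gaussian coordinate clouds around per-microstate reference geometries.

All randomness flows through explicit integer seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "GroundTruthModel",
    "EmissionSpec",
    "StatePathSet",
    "HBondObservations",
    "ChemicalShiftTable",
    "RestraintSet",
    "make_ground_truth_msm",
    "default_delta_omega",
    "default_emission_spec",
    "experimental_rex_profile",
    "sample_state_paths",
    "emit_observables",
    "make_restraints",
]

#: 1-based residue ids of the flexible binding loop (Loop 1) in the reference
#: numbering used throughout: residues 11-16, with residue 12 the reference
#: site showing the largest experimental exchange contribution.
LOOP_RESIDUES = (11, 12, 13, 14, 15, 16)
REFERENCE_RESIDUE = 12
N_RESIDUES = 33


# ---------------------------------------------------------------------------
# ground-truth model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroundTruthModel:
    """Planted hierarchical Markov model.

    Attributes
    ----------
    T_true : (n_micro, n_micro) row-stochastic transition matrix.
    lumping_true : (n_micro,) int array mapping microstate -> macrostate id
        in ``range(n_macro)``.
    minor_macrostates : frozenset of macrostate ids forming the planted minor
        exchange state.
    p_stay : probability mass each microstate keeps inside its own macrostate
        block per step.
    delta_omega_true : (n_residues,) planted pooled |shift difference| (ppm)
        between the minor and major exchange states.
    residues : 1-based residue ids aligned with ``delta_omega_true``.
    """

    n_micro: int
    n_macro: int
    T_true: np.ndarray
    lumping_true: np.ndarray
    minor_macrostates: frozenset
    p_stay: float
    delta_omega_true: np.ndarray
    residues: tuple
    seed: int
    target_populations: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        rows = self.T_true.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-12):
            raise ValueError("T_true rows must sum to 1 within 1e-12")
        if (self.T_true < 0).any():
            raise ValueError("T_true entries must be non-negative")
        if set(np.unique(self.lumping_true)) != set(range(self.n_macro)):
            raise ValueError("lumping_true must be surjective onto macrostates")

    @property
    def stationary(self) -> np.ndarray:
        """Exact stationary distribution of ``T_true`` (left Perron vector)."""
        from .msm import stationary as _stat

        return _stat(self.T_true)

    @property
    def macro_populations(self) -> np.ndarray:
        """Stationary mass per planted macrostate."""
        pi = self.stationary
        return np.bincount(self.lumping_true, weights=pi, minlength=self.n_macro)

    @property
    def minor_mass(self) -> float:
        """Stationary mass of the planted minor exchange state."""
        return float(self.macro_populations[sorted(self.minor_macrostates)].sum())

    def exchange_state_of(self, micro_labels: np.ndarray) -> np.ndarray:
        """Boolean minor-state membership for an array of microstate labels."""
        minor = np.isin(self.lumping_true, sorted(self.minor_macrostates))
        return minor[np.asarray(micro_labels)]


def _block_sizes(n_micro: int, n_macro: int) -> np.ndarray:
    sizes = np.full(n_macro, n_micro // n_macro, dtype=int)
    sizes[: n_micro % n_macro] += 1
    return sizes


def _neighbor_graph(n_macro: int, rng: np.random.Generator) -> list[set]:
    """Sparse symmetric neighbour sets: a shuffled ring plus chords, degree <= 3."""
    order = rng.permutation(n_macro)
    nbrs = [set() for _ in range(n_macro)]
    if n_macro == 1:
        return nbrs
    if n_macro == 2:
        nbrs[0].add(1)
        nbrs[1].add(0)
        return nbrs
    for i in range(n_macro):
        a, b = order[i], order[(i + 1) % n_macro]
        nbrs[a].add(b)
        nbrs[b].add(a)
    # chords make betweenness non-degenerate without saturating the graph
    for _ in range(max(1, n_macro // 4)):
        a, b = rng.integers(0, n_macro, size=2)
        if a != b and len(nbrs[a]) < 3 and len(nbrs[b]) < 3:
            nbrs[a].add(b)
            nbrs[b].add(a)
    return nbrs


def _macro_transition_matrix(
    target: np.ndarray, p_stay: float, nbrs: list[set]
) -> np.ndarray:
    """Block-level chain with *exact* planted stationary distribution.

    Metropolis construction on the neighbour graph: for neighbours A != B,
    T_AB = (1 - p_stay)/d_max * min(1, pi_B/pi_A), remainder on the
    diagonal.  Detailed balance pi_A T_AB = pi_B T_BA holds edge by edge, so
    ``target`` is the exact stationary distribution.  The smallest block in
    each neighbourhood keeps exactly ``p_stay`` within-block mass; heavier
    blocks keep more (they are stickier — attractor behaviour).
    """
    n = len(target)
    if n == 1:
        return np.array([[1.0]])
    d_max = max(len(s) for s in nbrs)
    T = np.zeros((n, n))
    eps = 1.0 - p_stay
    for a in range(n):
        for b in sorted(nbrs[a]):
            T[a, b] = eps / d_max * min(1.0, target[b] / target[a])
        T[a, a] = 1.0 - T[a].sum()
    return T


def make_ground_truth_msm(
    n_micro: int = 1000,
    n_macro: int = 40,
    p_stay: float = 0.95,
    minor_macrostates: Sequence[int] | None = None,
    minor_mass: float = 0.11,
    delta_omega_profile: np.ndarray | None = None,
    residues: Sequence[int] | None = None,
    seed: int = 0,
) -> GroundTruthModel:
    """Build a planted hierarchical microstate chain.

    Microstates are grouped into ``n_macro`` near-equal blocks.  Each block
    keeps at least ``p_stay`` of its row mass inside itself (spread
    uniformly over the block; the smallest block of each neighbourhood keeps
    exactly ``p_stay``, heavier blocks are stickier) and sends the rest to a
    sparse set of 1-3 neighbouring blocks via a Metropolis rule, so the
    planted macrostate populations are the *exact* stationary distribution:
    heterogeneous major-block masses (two dominant attractor blocks) and a
    minor exchange state of two blocks holding ``minor_mass`` of the total.
    """
    if n_macro > n_micro:
        raise ValueError("n_macro must not exceed n_micro")
    if not (0.0 < p_stay <= 1.0):
        raise ValueError("p_stay must lie in (0, 1]")
    rng = np.random.default_rng(seed)

    sizes = _block_sizes(n_micro, n_macro)
    lumping = np.repeat(np.arange(n_macro), sizes)

    if minor_macrostates is None:
        if n_macro >= 3:
            minor_macrostates = frozenset(
                rng.choice(n_macro, size=2, replace=False).tolist()
            )
        else:
            minor_macrostates = frozenset({n_macro - 1})
    else:
        minor_macrostates = frozenset(int(m) for m in minor_macrostates)
    if not minor_macrostates or len(minor_macrostates) >= n_macro:
        raise ValueError("minor_macrostates must be a nonempty proper subset")

    # target block populations: two dominant attractor blocks among the
    # majors (as in real metastable landscapes), the remaining majors from a
    # floored Dirichlet, and the planted minor mass split unevenly across
    # the minor blocks.
    minor = sorted(minor_macrostates)
    major = [m for m in range(n_macro) if m not in minor_macrostates]
    target = np.empty(n_macro)
    min_w = np.linspace(1.25, 0.75, len(minor))
    target[minor] = minor_mass * min_w / min_w.sum()
    attractor_mass = (0.30, 0.18)
    if len(major) > 3:
        attract = list(rng.choice(major, size=2, replace=False))
        rest = [m for m in major if m not in attract]
        target[attract] = attractor_mass
        rest_w = np.maximum(rng.dirichlet(np.ones(len(rest))), 0.5 / len(rest))
        target[rest] = (1.0 - minor_mass - sum(attractor_mass)) * rest_w / rest_w.sum()
    else:
        maj_w = np.maximum(rng.dirichlet(np.ones(len(major))), 0.1 / len(major))
        target[major] = (1.0 - minor_mass) * maj_w / maj_w.sum()
    target /= target.sum()

    nbrs = _neighbor_graph(n_macro, rng)
    T_macro = _macro_transition_matrix(target, p_stay, nbrs)

    # expand blocks: uniform within-block mixing, uniform spread over the
    # destination block's microstates.
    T = np.zeros((n_micro, n_micro))
    starts = np.concatenate([[0], np.cumsum(sizes)])
    for a in range(n_macro):
        ia = slice(starts[a], starts[a + 1])
        for b in range(n_macro):
            if T_macro[a, b] == 0.0:
                continue
            ib = slice(starts[b], starts[b + 1])
            T[ia, ib] = T_macro[a, b] / sizes[b]

    if residues is None:
        residues = tuple(range(1, N_RESIDUES + 1))
    if delta_omega_profile is None:
        delta_omega_profile = default_delta_omega(len(residues), seed=seed)
    delta_omega_profile = np.asarray(delta_omega_profile, dtype=float)
    if delta_omega_profile.shape != (len(residues),):
        raise ValueError("delta_omega_profile must have one entry per residue")

    return GroundTruthModel(
        n_micro=n_micro,
        n_macro=n_macro,
        T_true=T,
        lumping_true=lumping,
        minor_macrostates=minor_macrostates,
        p_stay=p_stay,
        delta_omega_true=delta_omega_profile,
        residues=tuple(int(r) for r in residues),
        seed=seed,
        target_populations=target,
    )


def default_delta_omega(n_residues: int = N_RESIDUES, seed: int = 0) -> np.ndarray:
    """Planted |delta-omega| profile (ppm): large at three loop residues.

    Mirrors the experimental picture in which three loop residues carry
    large exchange contributions (the reference site largest) on top of a
    small baseline elsewhere.
    """
    rng = np.random.default_rng(seed + 101)
    dw = rng.uniform(0.15, 0.45, size=n_residues)
    peaks = {12: 2.0, 13: 1.6, 15: 1.2}  # residue id -> ppm
    for r, val in peaks.items():
        if r <= n_residues:
            dw[r - 1] = val
    return dw


# ---------------------------------------------------------------------------
# emissions
# ---------------------------------------------------------------------------

@dataclass
class EmissionSpec:
    """Observable-emission parameters.

    ``shift_means`` has shape (n_macro, n_residues): state-dependent Gaussian
    means (ppm).  Major blocks share the baseline row; minor blocks carry
    complementary offsets whose population-weighted pool equals the planted
    delta-omega profile (each minor conformer contributes a different part of
    the shift signature, as distinct loop geometries would).

    ``hbond_probs`` has shape (n_bonds, n_macro): Bernoulli presence
    probability of each bond in each macrostate (signature bonds are present
    only in minor blocks; scaffold bonds vary from conformer to conformer).
    ``coord_centers`` (n_micro, n_atoms, 3) are per-microstate reference
    geometries; None disables coordinate output.
    """

    shift_means: np.ndarray
    shift_sigma: float
    hbond_names: tuple
    hbond_probs: np.ndarray
    coord_centers: np.ndarray | None = None
    coord_sigma: float = 0.0
    box_length: float | None = None

    def __post_init__(self):
        if self.shift_sigma < 0 or self.coord_sigma < 0:
            raise ValueError("emission sigmas must be non-negative")
        if ((self.hbond_probs < 0) | (self.hbond_probs > 1)).any():
            raise ValueError("hbond_probs must lie in [0, 1]")


def default_emission_spec(
    model: GroundTruthModel,
    shift_sigma: float = 0.2,
    base_shift: float = 118.0,
    block_sigma: float = 0.4,
    coord_centers: np.ndarray | None = None,
    coord_sigma: float = 0.25,
    box_length: float | None = None,
    seed: int = 0,
) -> EmissionSpec:
    """Emission parameters realizing the planted exchange signature.

    Every macrostate gets its own baseline shift vector (``block_sigma`` of
    per-residue conformer heterogeneity around a common profile — distinct
    conformers genuinely differ in their shifts, which is what makes a
    2-macrostate cut along the wrong kinetic axis correlate poorly).  On top
    of that, the minor blocks carry the planted exchange offsets: the pooled
    minor-minus-major difference equals ``model.delta_omega_true`` (in
    expectation at stationarity), but each minor block carries a
    complementary piece of the loop signature, so the *union* of minor
    blocks is the unique best-correlating minor state — single blocks
    reproduce only part of the profile.
    """
    rng = np.random.default_rng(seed + 202)
    n_res = len(model.residues)
    minor = sorted(model.minor_macrostates)
    pops = model.macro_populations
    w = pops[minor] / pops[minor].sum()

    baseline = base_shift + rng.normal(0.0, 3.0, size=n_res)
    means = baseline + rng.normal(0.0, block_sigma, size=(model.n_macro, n_res))

    dw = model.delta_omega_true
    peak_idx = np.argsort(dw)[-3:]  # the three planted peak residues
    ref_peak = peak_idx[np.argmax(dw[peak_idx])]
    other_peaks = [i for i in peak_idx if i != ref_peak]
    split = np.zeros((len(minor), n_res))
    split[:, :] = dw  # baseline residues: same offset in every minor block
    if len(minor) >= 2:
        # complementary peak allocation (alpha vs 1-alpha between the first
        # minor block and the rest), normalized so the population-weighted
        # pool equals dw: single blocks reproduce only part of the profile,
        # while the pooled profile is insensitive to modest occupancy noise.
        alpha = 0.7
        w_rest = w[1:].sum()
        for i, a in [(ref_peak, alpha)] + [(i, 1 - alpha) for i in other_peaks]:
            k_norm = dw[i] / (a * w[0] + (1 - a) * w_rest)
            split[0, i] = a * k_norm
            split[1:, i] = (1 - a) * k_norm
    for k, m in enumerate(minor):
        means[m] = means[m] + split[k]

    hbond_names = ("loop_hb_minor_A", "loop_hb_minor_B", "bg_hb_1", "bg_hb_2", "bg_hb_3")
    # (n_bonds, n_macro): the signature bonds exist only in minor
    # conformers (the first in every minor block, the second in the first
    # minor block's loop geometry alone); scaffold bonds occur with
    # block-specific frequency (bond geometry differs between conformers),
    # which keeps their frame sets from mimicking the exchange contrast.
    hbond_probs = np.zeros((5, model.n_macro))
    hbond_probs[0, minor] = 1.0
    hbond_probs[1, minor[0]] = 1.0
    hbond_probs[2:] = rng.uniform(0.1, 0.9, size=(3, model.n_macro))
    return EmissionSpec(
        shift_means=means,
        shift_sigma=shift_sigma,
        hbond_names=hbond_names,
        hbond_probs=hbond_probs,
        coord_centers=coord_centers,
        coord_sigma=coord_sigma,
        box_length=box_length,
    )


def experimental_rex_profile(model: GroundTruthModel,
                             spec: EmissionSpec | None = None,
                             noise_sigma: float = 0.0,
                             seed: int = 0):
    """Reference-normalized relative exchange profile implied by the truth.

    Under a global two-state process the relative exchange contribution of
    residue i is delta-omega(i)^2 normalized to the reference residue
    (population and rate factors cancel).  When an :class:`EmissionSpec` is
    given, delta-omega is the *realized* pooled contrast between the
    stationary-weighted minor and major emission means (the quantity an
    experiment on the emitted ensemble would report); otherwise the designed
    ``delta_omega_true`` is used directly.  Optional Gaussian noise emulates
    experimental scatter.
    """
    from .exchange import ExperimentalRexProfile

    if spec is None:
        dw = model.delta_omega_true
    else:
        pops = model.macro_populations
        minor = sorted(model.minor_macrostates)
        major = [m for m in range(model.n_macro) if m not in model.minor_macrostates]
        w_min = pops[minor] / pops[minor].sum()
        w_maj = pops[major] / pops[major].sum()
        dw = np.abs(w_min @ spec.shift_means[minor] - w_maj @ spec.shift_means[major])
    ref_ix = model.residues.index(REFERENCE_RESIDUE)
    ratios = dw**2 / dw[ref_ix] ** 2
    if noise_sigma > 0:
        rng = np.random.default_rng(seed + 303)
        ratios = np.clip(ratios + rng.normal(0, noise_sigma, ratios.shape), 0, None)
        ratios[ref_ix] = 1.0
    return ExperimentalRexProfile(
        residues=model.residues,
        ratios=ratios,
        reference_residue=REFERENCE_RESIDUE,
        loop_residues=tuple(r for r in LOOP_RESIDUES if r in model.residues),
    )


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

@dataclass
class StatePathSet:
    """A set of integer microstate paths (labels in ``range(n_micro)``)."""

    paths: list
    lag_unit: float = 1.0

    def __post_init__(self):
        if not self.paths:
            raise ValueError("paths must be nonempty")
        self.paths = [np.asarray(p, dtype=np.int64) for p in self.paths]

    @property
    def n_steps(self) -> int:
        return int(sum(len(p) for p in self.paths))

    @property
    def concatenated(self) -> np.ndarray:
        return np.concatenate(self.paths)


def sample_state_paths(
    model: GroundTruthModel,
    n_paths: int = 100,
    path_length: int = 3000,
    seed: int = 0,
    start_states: np.ndarray | None = None,
) -> StatePathSet:
    """Sample realizations of the planted chain (vectorized across paths)."""
    if path_length < 2:
        raise ValueError("path_length must be >= 2")
    rng = np.random.default_rng(seed)
    cum = np.cumsum(model.T_true, axis=1)
    cum[:, -1] = 1.0
    if start_states is None:
        pi = model.stationary
        states = rng.choice(model.n_micro, size=n_paths, p=pi)
    else:
        states = np.asarray(start_states, dtype=np.int64).copy()
        if states.shape != (n_paths,):
            raise ValueError("start_states must have length n_paths")
    out = np.empty((n_paths, path_length), dtype=np.int64)
    out[:, 0] = states
    for t in range(1, path_length):
        u = rng.random(n_paths)
        # row-wise inverse-CDF draw
        states = np.array(
            [np.searchsorted(cum[s], x, side="right") for s, x in zip(states, u)],
            dtype=np.int64,
        )
        np.minimum(states, model.n_micro - 1, out=states)
        out[:, t] = states
    return StatePathSet(paths=list(out))


# ---------------------------------------------------------------------------
# observables
# ---------------------------------------------------------------------------

@dataclass
class ChemicalShiftTable:
    """Per-frame, per-residue chemical shifts (ppm), wide layout."""

    shifts: np.ndarray  # (n_frames, n_residues)
    residues: tuple

    def __post_init__(self):
        if not np.isfinite(self.shifts).all():
            raise ValueError("shift table contains non-finite values")
        if self.shifts.shape[1] != len(self.residues):
            raise ValueError("column count must match residue list")

    @property
    def n_frames(self) -> int:
        return self.shifts.shape[0]

    def column(self, residue: int) -> np.ndarray:
        return self.shifts[:, self.residues.index(residue)]


@dataclass
class HBondObservations:
    """Per-frame hydrogen-bond presence indicators."""

    present: np.ndarray  # (n_frames, n_bonds) bool
    bond_names: tuple

    def frame_set(self, bond: str) -> np.ndarray:
        """Frame indices in which ``bond`` is present."""
        j = self.bond_names.index(bond)
        return np.flatnonzero(self.present[:, j])

    @property
    def n_frames(self) -> int:
        return self.present.shape[0]


def emit_observables(
    paths: StatePathSet,
    model: GroundTruthModel,
    spec: EmissionSpec,
    seed: int = 0,
):
    """Emit per-frame observables for every step of every path.

    Returns ``(frames_or_None, ChemicalShiftTable, HBondObservations)``; the
    first element is a :class:`rexmap.featurize.FrameEnsemble` when
    ``spec.coord_centers`` is set, else None.  Frames are ordered
    path-by-path (concatenated), matching ``paths.concatenated``.
    """
    if spec.shift_means.shape != (model.n_macro, len(model.residues)):
        raise ValueError("shift_means must be (n_macro, n_residues)")
    if spec.hbond_probs.shape[1] != model.n_macro:
        raise ValueError("hbond_probs must cover every macrostate")
    labels = paths.concatenated
    macro = model.lumping_true[labels]
    is_minor = model.exchange_state_of(labels)
    n = labels.size
    rng = np.random.default_rng(seed)

    shifts = spec.shift_means[macro] + rng.normal(
        0.0, spec.shift_sigma, size=(n, len(model.residues))
    )
    table = ChemicalShiftTable(shifts=shifts, residues=model.residues)

    probs = spec.hbond_probs[:, macro].T  # (n, n_bonds)
    present = rng.random(probs.shape) < probs
    hbonds = HBondObservations(present=present, bond_names=tuple(spec.hbond_names))

    frames = None
    if spec.coord_centers is not None:
        if spec.coord_centers.shape[0] != model.n_micro:
            raise ValueError("coord_centers must cover every microstate")
        from .featurize import FrameEnsemble

        coords = spec.coord_centers[labels] + rng.normal(
            0.0, spec.coord_sigma, size=(n,) + spec.coord_centers.shape[1:]
        )
        frames = FrameEnsemble(
            coords=coords,
            atom_labels=tuple(
                (i + 1, "CA") for i in range(spec.coord_centers.shape[1])
            ),
            box_length=spec.box_length,
        )
    return frames, table, hbonds


# ---------------------------------------------------------------------------
# restraints
# ---------------------------------------------------------------------------

@dataclass
class RestraintSet:
    """Upper-bound distance restraints between atom indices."""

    pairs: np.ndarray      # (n, 2) int atom indices
    upper: np.ndarray      # (n,) Angstrom
    lower: np.ndarray | None = None

    def __post_init__(self):
        self.pairs = np.asarray(self.pairs, dtype=int)
        self.upper = np.asarray(self.upper, dtype=float)
        if (self.upper <= 0).any():
            raise ValueError("restraint bounds must be positive")

    def __len__(self) -> int:
        return len(self.upper)


def make_restraints(
    reference_coords: np.ndarray,
    n_restraints: int,
    slack: float = 0.5,
    seed: int = 0,
) -> RestraintSet:
    """Restraints whose upper bound = true pair distance + slack."""
    ref = np.asarray(reference_coords, dtype=float)
    n_atoms = ref.shape[0]
    all_pairs = [(i, j) for i in range(n_atoms) for j in range(i + 1, n_atoms)]
    if n_restraints > len(all_pairs):
        raise ValueError("n_restraints exceeds number of atom pairs")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(all_pairs), size=n_restraints, replace=False)
    pairs = np.array([all_pairs[c] for c in sorted(chosen)])
    dists = np.linalg.norm(ref[pairs[:, 0]] - ref[pairs[:, 1]], axis=1)
    return RestraintSet(pairs=pairs, upper=dists + slack)
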