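"""Exchange-state identification from chemical shifts and NMR Rex profiles.

Under fast two-state exchange the exchange broadening of residue i scales as

    Rex(i)  ~  p_major * p_minor * delta_omega(i)^2

with the two-state rate constant and the CPMG quenching fraction entering
only as residue-independent multiplicative constants.  Dividing by the value
at a reference residue therefore cancels every unknowable constant, so
candidate major/minor partitions of the simulation ensemble can be ranked by
the Pearson correlation between their reference-normalized estimated Rex and
the experimental relative Rex profile.

Three search strategies are implemented:

* Method 1 — candidate minor states are H-bond frame sets (and unions of
  them); the union maximizing the loop correlation wins.
* Method 2 — the two macrostates of a 2-macrostate kinetic model define the
  partition directly.
* Method 3 (hybrid) — a many-macrostate model is searched over subsets of
  the macrostates eligible by H-bond content; combinatorial, so the
  eligible-set size is capped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .synthetic import ChemicalShiftTable, HBondObservations

__all__ = [
    "ExperimentalRexProfile",
    "RexProfile",
    "ExchangePartition",
    "delta_omega",
    "rex_estimate",
    "normalize_reference",
    "correlation_score",
    "partition_profile",
    "search_hbond_partition",
    "search_macrostate_partition",
    "scan_macrostate_counts",
]


@dataclass
class ExperimentalRexProfile:
    """Per-residue relative Rex, normalized to a reference residue (value 1)."""

    residues: tuple
    ratios: np.ndarray
    reference_residue: int
    loop_residues: tuple

    def __post_init__(self):
        self.ratios = np.asarray(self.ratios, dtype=float)
        ref = self.ratios[self.residues.index(self.reference_residue)]
        if not np.isclose(ref, 1.0):
            raise ValueError("reference residue must carry ratio 1")

    def values_for(self, residues) -> np.ndarray:
        return np.array([self.ratios[self.residues.index(r)] for r in residues])


@dataclass
class RexProfile:
    """Estimated per-residue exchange profile for one candidate partition."""

    residues: tuple
    delta_omega: np.ndarray     # ppm
    rex: np.ndarray             # arbitrary units, p_major*p_minor*dw^2
    p_major: float
    p_minor: float
    reference_residue: int = None
    ratios: np.ndarray = None   # rex / rex(reference)

    def values_for(self, residues) -> np.ndarray:
        return np.array([self.ratios[self.residues.index(r)] for r in residues])


@dataclass
class ExchangePartition:
    """A major/minor split of the analyzed frames."""

    kind: str                       # "hbond-frame-set" | "macrostate-set"
    minor_members: tuple            # H-bond names or macrostate ids
    major_members: tuple
    minor_frames: np.ndarray
    n_frames: int
    correlation_loop: float
    p_value_loop: float
    correlation_all: float
    p_value_all: float
    profile: RexProfile
    n_candidates: int = None    # candidates scored during the search
    minor_unique_bonds: tuple = None  # bonds (almost) absent from the major state

    @property
    def minor_count(self) -> int:
        return len(self.minor_frames)

    @property
    def major_count(self) -> int:
        return self.n_frames - self.minor_count

    @property
    def minor_fraction(self) -> float:
        return self.minor_count / self.n_frames

    @property
    def major_fraction(self) -> float:
        return 1.0 - self.minor_fraction


# ---------------------------------------------------------------------------
# estimator pieces
# ---------------------------------------------------------------------------

def delta_omega(shifts: ChemicalShiftTable, minor_frames, major_frames) -> np.ndarray:
    """|mean shift over minor frames - mean shift over major frames| per residue."""
    minor_frames = np.asarray(minor_frames)
    major_frames = np.asarray(major_frames)
    if minor_frames.size == 0 or major_frames.size == 0:
        raise ValueError("both partition frame sets must be nonempty")
    return np.abs(
        shifts.shifts[minor_frames].mean(axis=0)
        - shifts.shifts[major_frames].mean(axis=0)
    )


def rex_estimate(dw: np.ndarray, p_major: float, p_minor: float,
                 residues=None) -> RexProfile:
    """Relative exchange-broadening estimate p_major * p_minor * dw^2."""
    if not (0 < p_major < 1 and 0 < p_minor < 1):
        raise ValueError("populations must lie in (0, 1)")
    if not np.isclose(p_major + p_minor, 1.0):
        raise ValueError("populations must sum to 1")
    dw = np.asarray(dw, dtype=float)
    if residues is None:
        residues = tuple(range(1, len(dw) + 1))
    return RexProfile(
        residues=tuple(residues),
        delta_omega=dw,
        rex=p_major * p_minor * dw**2,
        p_major=p_major,
        p_minor=p_minor,
    )


def normalize_reference(profile: RexProfile, reference_residue: int) -> RexProfile:
    """Divide the Rex estimate by its value at the reference residue."""
    ref = profile.rex[profile.residues.index(reference_residue)]
    if ref <= 0:
        raise ZeroDivisionError(
            f"Rex estimate vanishes at reference residue {reference_residue}; "
            "ratios are undefined for this partition"
        )
    profile.reference_residue = reference_residue
    profile.ratios = profile.rex / ref
    return profile


def correlation_score(estimated: RexProfile, experimental: ExperimentalRexProfile,
                      residues=None):
    """Pearson correlation (and two-sided p) over a residue subset."""
    if residues is None:
        residues = experimental.loop_residues
    if len(residues) < 3:
        raise ValueError("need at least 3 residues for a correlation")
    x = estimated.values_for(residues)
    y = experimental.values_for(residues)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def partition_profile(shifts: ChemicalShiftTable, minor_frames: np.ndarray,
                      experimental: ExperimentalRexProfile) -> RexProfile:
    """Full estimated profile (dw -> Rex -> ratios) for one candidate split."""
    n = shifts.n_frames
    mask = np.zeros(n, dtype=bool)
    mask[minor_frames] = True
    major_frames = np.flatnonzero(~mask)
    dw = delta_omega(shifts, np.flatnonzero(mask), major_frames)
    p_minor = mask.mean()
    prof = rex_estimate(dw, 1.0 - p_minor, p_minor, residues=shifts.residues)
    return normalize_reference(prof, experimental.reference_residue)


def _score_candidate(shifts, minor_frames, experimental):
    """(C_loop, p_loop, C_all, p_all, profile) or None when undefined."""
    n = shifts.n_frames
    if len(minor_frames) == 0 or len(minor_frames) == n:
        return None
    try:
        prof = partition_profile(shifts, minor_frames, experimental)
        c_loop, p_loop = correlation_score(prof, experimental,
                                           experimental.loop_residues)
        c_all, p_all = correlation_score(prof, experimental,
                                         experimental.residues)
    except (ValueError, ZeroDivisionError):
        return None
    return c_loop, p_loop, c_all, p_all, prof


# ---------------------------------------------------------------------------
# Method 1: H-bond frame-set search
# ---------------------------------------------------------------------------

def search_hbond_partition(
    hbonds: HBondObservations,
    shifts: ChemicalShiftTable,
    experimental: ExperimentalRexProfile,
    strategy: str = "auto",
    exhaustive_max_bonds: int = 12,
    unique_major_tol: float = 0.01,
) -> ExchangePartition:
    """Find the H-bond-defined minor state maximizing the loop correlation.

    Candidate minor states are unions of per-bond frame sets.  With at most
    ``exhaustive_max_bonds`` observed bonds (or ``strategy="exhaustive"``)
    every nonempty union is scored; otherwise single bonds are scored
    exhaustively and extended by greedy agglomeration.  The smaller-
    population side of the winning split is labelled minor.  Ties in C break
    toward the smaller minor state.
    """
    names = [b for b in hbonds.bond_names if hbonds.frame_set(b).size > 0]
    if not names:
        raise ValueError("no H-bond was ever observed; no partition exists")
    frame_sets = {b: hbonds.frame_set(b) for b in names}
    n = shifts.n_frames

    def union(bonds):
        mask = np.zeros(n, dtype=bool)
        for b in bonds:
            mask[frame_sets[b]] = True
        return np.flatnonzero(mask)

    candidates = []  # (C_loop, -minor_count, bonds tuple, scored)
    if strategy == "exhaustive" or (strategy == "auto" and len(names) <= exhaustive_max_bonds):
        subsets = [
            tuple(c) for r in range(1, len(names) + 1)
            for c in combinations(names, r)
        ]
    else:
        subsets = [(b,) for b in names]

    scored_cache = {}

    def score(bonds):
        key = tuple(sorted(bonds))
        if key not in scored_cache:
            frames = union(bonds)
            # minor = smaller-population side
            if len(frames) > n - len(frames):
                frames = np.setdiff1d(np.arange(n), frames)
            scored_cache[key] = (frames, _score_candidate(shifts, frames, experimental))
        return scored_cache[key]

    best = None
    for bonds in subsets:
        frames, sc = score(bonds)
        if sc is None:
            continue
        item = (sc[0], -len(frames), tuple(sorted(bonds)), frames, sc)
        if best is None or item[:3] > best[:3]:
            best = item
    if best is None:
        raise ValueError("no candidate H-bond union yields a defined correlation")

    if strategy != "exhaustive" and len(names) > exhaustive_max_bonds:
        improved = True
        while improved:
            improved = False
            for b in names:
                if b in best[2]:
                    continue
                bonds = best[2] + (b,)
                frames, sc = score(bonds)
                if sc is None:
                    continue
                item = (sc[0], -len(frames), tuple(sorted(bonds)), frames, sc)
                if item[:3] > best[:3]:
                    best = item
                    improved = True

    c_loop, p_loop, c_all, p_all, prof = best[4]
    minor_frames = best[3]
    in_minor = np.zeros(n, dtype=bool)
    in_minor[minor_frames] = True
    # bonds characteristic of the minor state: essentially never seen in
    # major-state frames (these drive the hybrid macrostate search)
    unique = tuple(
        b for b in names
        if (~in_minor[frame_sets[b]]).mean() < unique_major_tol
    )
    return ExchangePartition(
        kind="hbond-frame-set",
        minor_members=best[2],
        major_members=tuple(b for b in names if b not in best[2]),
        minor_frames=minor_frames,
        n_frames=n,
        correlation_loop=c_loop,
        p_value_loop=p_loop,
        correlation_all=c_all,
        p_value_all=p_all,
        profile=prof,
        minor_unique_bonds=unique,
    )


# ---------------------------------------------------------------------------
# Methods 2/3: macrostate-set search
# ---------------------------------------------------------------------------

def search_macrostate_partition(
    frame_macrostates: np.ndarray,
    shifts: ChemicalShiftTable,
    experimental: ExperimentalRexProfile,
    required_hbond_frames=None,
    max_eligible: int = 20,
) -> ExchangePartition:
    """Search subsets of macrostates for the best-correlating minor state.

    ``required_hbond_frames`` is a list of frame-index arrays, one per
    signature H-bond (Method 1 output); only macrostates containing at least
    one such frame are eligible to join the minor state, which keeps the
    2^eligible enumeration tractable.  With ``required_hbond_frames=None``
    every macrostate is eligible (pure Method 2 when there are 2).
    """
    frame_macrostates = np.asarray(frame_macrostates)
    n = shifts.n_frames
    if frame_macrostates.shape != (n,):
        raise ValueError("need one macrostate label per shift-table frame")
    macrostates = np.unique(frame_macrostates)

    if required_hbond_frames is not None:
        req = [np.asarray(f) for f in required_hbond_frames]
        if not req:
            raise ValueError("required H-bond list must be nonempty")
        marked = np.zeros(n, dtype=bool)
        for f in req:
            marked[f] = True
        eligible = np.unique(frame_macrostates[marked])
    else:
        eligible = macrostates
    if eligible.size == 0:
        raise ValueError("no macrostate contains a required H-bond frame")
    if eligible.size > max_eligible:
        raise ValueError(
            f"{eligible.size} eligible macrostates exceed max_eligible="
            f"{max_eligible}: enumerating 2^{eligible.size}-1 candidate minor "
            "states is combinatorially infeasible; tighten the H-bond filter"
        )

    best = None
    n_candidates = 0
    for r in range(1, eligible.size + 1):
        for combo in combinations(eligible.tolist(), r):
            if len(combo) == len(macrostates):
                continue  # minor state must be a proper subset
            n_candidates += 1
            frames = np.flatnonzero(np.isin(frame_macrostates, combo))
            sc = _score_candidate(shifts, frames, experimental)
            if sc is None:
                continue
            item = (sc[0], -len(frames), tuple(combo), frames, sc)
            if best is None or item[:3] > best[:3]:
                best = item
    if best is None:
        raise ValueError("no macrostate subset yields a defined correlation")

    c_loop, p_loop, c_all, p_all, prof = best[4]
    minor_set = best[2]
    return ExchangePartition(
        kind="macrostate-set",
        minor_members=minor_set,
        major_members=tuple(int(m) for m in macrostates if m not in minor_set),
        minor_frames=best[3],
        n_frames=n,
        correlation_loop=c_loop,
        p_value_loop=p_loop,
        correlation_all=c_all,
        p_value_all=p_all,
        profile=prof,
        n_candidates=n_candidates,
    )


def scan_macrostate_counts(
    T_micro,
    micro_labels: np.ndarray,
    shifts: ChemicalShiftTable,
    experimental: ExperimentalRexProfile,
    counts=(2, 5, 10, 20, 40),
    required_hbond_frames=None,
    pi: np.ndarray = None,
    max_eligible: int = 20,
    anneal: bool = True,
    seed: int = 0,
):
    """Best correlation as a function of the number of macrostates.

    For each requested count the microstate model is lumped (PCCA, then
    optional annealing refinement) and the exchange-state search is run;
    rows report (n_macro, best loop C, loop p-value, minor fraction).
    Search failures propagate as NaN rows rather than aborting the scan.
    """
    import pandas as pd

    from .msm import anneal_lumping, pcca, stationary as _stat

    if pi is None:
        pi = _stat(T_micro)
    rows = []
    for n_macro in counts:
        if n_macro < 2:
            raise ValueError("macrostate counts must be >= 2")
        lump = pcca(T_micro, n_macro, pi=pi)
        if anneal and n_macro < len(pi):
            lump = anneal_lumping(T_micro, lump, pi=pi, seed=seed)
        frame_macro = lump.frame_macrostates(micro_labels)
        req = required_hbond_frames if n_macro > 2 else None
        try:
            part = search_macrostate_partition(
                frame_macro, shifts, experimental,
                required_hbond_frames=req, max_eligible=max_eligible,
            )
            rows.append(
                dict(n_macro=n_macro, best_C=part.correlation_loop,
                     p_value=part.p_value_loop,
                     minor_fraction=part.minor_fraction)
            )
        except ValueError as err:
            warnings.warn(f"n_macro={n_macro}: {err}")
            rows.append(dict(n_macro=n_macro, best_C=np.nan, p_value=np.nan,
                             minor_fraction=np.nan))
    return pd.DataFrame(rows)
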