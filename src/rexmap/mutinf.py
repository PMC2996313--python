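"""Correlated motions via mutual information between residues.

Torsion-space variant: per-residue torsion angles are histogrammed on fixed
periodic bins and pairwise mutual information (nats) is computed from joint
and marginal histograms.  Finite-sample bias is removed by subtracting the
mean MI over frame-permuted replicas (which preserve both marginals while
destroying the coupling), and entries that are not significant against the
permutation null are masked to zero.  The corrected matrix is clustered
hierarchically to reveal groups of co-moving residues.

Cartesian variant: the same machinery on Calpha coordinates after removing
rigid-body motion by superposition onto the mean structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform

from .featurize import kabsch_superpose

__all__ = [
    "MIMatrix",
    "torsion_mi",
    "mi_matrix",
    "significance_filter",
    "cluster_residues",
    "cartesian_mi",
]


@dataclass
class MIMatrix:
    """Corrected, significance-masked mutual-information matrix (nats)."""

    mi: np.ndarray             # (n, n); off-diagonal corrected+masked
    raw: np.ndarray            # uncorrected MI
    mask: np.ndarray           # bool; True = significant
    p_values: np.ndarray
    n_permutations: int
    alpha: float
    seed: int

    @property
    def n(self) -> int:
        return self.mi.shape[0]


def _bin_codes(angles: np.ndarray, n_bins: int) -> np.ndarray:
    """Fixed periodic binning of angles in degrees onto [0, n_bins)."""
    a = np.mod(np.asarray(angles, dtype=float) + 180.0, 360.0)
    codes = np.floor(a / (360.0 / n_bins)).astype(np.int64)
    return np.clip(codes, 0, n_bins - 1)


def _mi_from_codes(ci: np.ndarray, cj: np.ndarray, n_bins: int) -> float:
    joint = np.bincount(ci * n_bins + cj, minlength=n_bins * n_bins).astype(float)
    n = ci.size
    joint /= n
    pi = joint.reshape(n_bins, n_bins).sum(axis=1)
    pj = joint.reshape(n_bins, n_bins).sum(axis=0)
    nz = joint > 0
    J = joint.reshape(n_bins, n_bins)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = J / (pi[:, None] * pj[None, :])
    vals = J[nz.reshape(n_bins, n_bins)] * np.log(ratio[nz.reshape(n_bins, n_bins)])
    return float(vals.sum())


def torsion_mi(angles_i: np.ndarray, angles_j: np.ndarray, n_bins: int = 24) -> float:
    """Mutual information between two torsion series (degrees, periodic).

    Uses fixed bins of width 360/n_bins; MI(X, X) equals the binned marginal
    entropy H(X).  Warns when the sample is too small relative to the joint
    histogram (bias-dominated regime).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    ai = np.asarray(angles_i, dtype=float)
    aj = np.asarray(angles_j, dtype=float)
    if ai.shape != aj.shape:
        raise ValueError("angle series must have equal frame counts")
    if ai.size < n_bins**2:
        warnings.warn(
            f"{ai.size} frames < n_bins^2 = {n_bins**2}: raw MI is "
            "bias-dominated; rely on the permutation correction"
        )
    return _mi_from_codes(_bin_codes(ai, n_bins), _bin_codes(aj, n_bins), n_bins)


def mi_matrix(angles: np.ndarray, n_bins: int = 24) -> np.ndarray:
    """Raw pairwise MI matrix over residues (columns of ``angles``)."""
    angles = np.asarray(angles, dtype=float)
    n_res = angles.shape[1]
    codes = [_bin_codes(angles[:, r], n_bins) for r in range(n_res)]
    out = np.zeros((n_res, n_res))
    for i in range(n_res):
        for j in range(i, n_res):
            out[i, j] = out[j, i] = _mi_from_codes(codes[i], codes[j], n_bins)
    return out


def significance_filter(
    angles: np.ndarray,
    n_permutations: int = 100,
    alpha: float = 0.01,
    n_bins: int = 24,
    seed: int = 0,
    raw: np.ndarray = None,
) -> MIMatrix:
    """Bias-correct and significance-mask the pairwise MI matrix.

    For every pair, frames of the second residue are permuted (the same
    ``n_permutations`` seeded permutations for all pairs), preserving
    marginals; corrected MI = raw - mean(permuted MI), and pairs whose raw
    MI is not in the top ``alpha`` tail of the permutation distribution
    (p = (1 + #{perm >= raw}) / (n_permutations + 1)) are zeroed.
    The diagonal keeps the raw self-information, unmasked.
    """
    if n_permutations < 20:
        raise ValueError("need at least 20 permutations")
    if alpha < 1.0 / (n_permutations + 1):
        warnings.warn(
            f"alpha={alpha} is below the permutation-test resolution "
            f"1/(n_permutations+1)={1/(n_permutations+1):.4f}: nothing can "
            "pass; increase n_permutations"
        )
    angles = np.asarray(angles, dtype=float)
    n_frames, n_res = angles.shape
    if raw is None:
        raw = mi_matrix(angles, n_bins)
    rng = np.random.default_rng(seed)
    perms = [rng.permutation(n_frames) for _ in range(n_permutations)]
    codes = [_bin_codes(angles[:, r], n_bins) for r in range(n_res)]
    perm_codes = [[c[p] for p in perms] for c in codes]

    null_mean = np.zeros((n_res, n_res))
    p_values = np.zeros((n_res, n_res))
    for i in range(n_res):
        for j in range(i + 1, n_res):
            null = np.array(
                [_mi_from_codes(codes[i], pc, n_bins) for pc in perm_codes[j]]
            )
            null_mean[i, j] = null_mean[j, i] = null.mean()
            p = (1 + (null >= raw[i, j]).sum()) / (n_permutations + 1)
            p_values[i, j] = p_values[j, i] = p
    mask = p_values < alpha
    np.fill_diagonal(mask, True)
    np.fill_diagonal(p_values, 0.0)
    corrected = raw - null_mean
    corrected[~mask] = 0.0
    np.fill_diagonal(corrected, np.diag(raw))
    return MIMatrix(
        mi=corrected, raw=raw, mask=mask, p_values=p_values,
        n_permutations=n_permutations, alpha=alpha, seed=seed,
    )


def cluster_residues(mi, n_clusters: int = 4, method: str = "average") -> np.ndarray:
    """Agglomerative clustering of residues on distance = max(MI) - MI.

    Deterministic given the linkage method; returns 0-based cluster labels.
    """
    M = mi.mi if isinstance(mi, MIMatrix) else np.asarray(mi, dtype=float)
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if n_clusters >= M.shape[0]:
        return np.arange(M.shape[0])
    D = M.max() - M
    np.fill_diagonal(D, 0.0)
    D = 0.5 * (D + D.T)  # guard float asymmetry
    Z = scipy_linkage(squareform(D, checks=False), method=method)
    labels = fcluster(Z, t=n_clusters, criterion="maxclust") - 1
    return labels


def cartesian_mi(
    ca_coords: np.ndarray,
    n_bins: int = 24,
    n_permutations: int = 100,
    alpha: float = 0.01,
    seed: int = 0,
) -> MIMatrix:
    """MI between Calpha atoms after removing rigid-body motion.

    Frames are superposed onto the ensemble-mean structure (one refinement
    pass), each coordinate component is binned on a fixed linear grid, and
    per-atom-pair MI is the sum over the three components, with the same
    permutation correction and masking as the torsion variant.
    """
    X = np.asarray(ca_coords, dtype=float)
    if X.ndim != 3 or X.shape[2] != 3:
        raise ValueError("ca_coords must be (n_frames, n_atoms, 3)")
    n_frames, n_atoms, _ = X.shape
    # superpose to frame 0, take the mean, superpose to the mean
    ref = X[0]
    for _ in range(2):
        aligned = np.empty_like(X)
        for f in range(n_frames):
            R, t = kabsch_superpose(X[f], ref)
            aligned[f] = X[f] @ R.T + t
        ref = aligned.mean(axis=0)
    X = aligned

    rng = np.random.default_rng(seed)
    perms = [rng.permutation(n_frames) for _ in range(n_permutations)]

    def component_codes(v):
        lo, hi = v.min(), v.max()
        if hi - lo < 1e-12:
            return np.zeros(v.shape, dtype=np.int64)
        c = np.floor((v - lo) / (hi - lo) * n_bins).astype(np.int64)
        return np.clip(c, 0, n_bins - 1)

    codes = [
        [component_codes(X[:, a, d]) for d in range(3)] for a in range(n_atoms)
    ]

    def pair_mi(ci, cj):
        return sum(_mi_from_codes(ci[d], cj[d], n_bins) for d in range(3))

    raw = np.zeros((n_atoms, n_atoms))
    for i in range(n_atoms):
        for j in range(i, n_atoms):
            raw[i, j] = raw[j, i] = pair_mi(codes[i], codes[j])

    null_mean = np.zeros((n_atoms, n_atoms))
    p_values = np.zeros((n_atoms, n_atoms))
    for i in range(n_atoms):
        for j in range(i + 1, n_atoms):
            null = np.array(
                [sum(_mi_from_codes(codes[i][d], codes[j][d][p], n_bins)
                     for d in range(3)) for p in perms]
            )
            null_mean[i, j] = null_mean[j, i] = null.mean()
            p = (1 + (null >= raw[i, j]).sum()) / (n_permutations + 1)
            p_values[i, j] = p_values[j, i] = p
    mask = p_values < alpha
    np.fill_diagonal(mask, True)
    np.fill_diagonal(p_values, 0.0)
    corrected = raw - null_mean
    corrected[~mask] = 0.0
    np.fill_diagonal(corrected, np.diag(raw))
    return MIMatrix(
        mi=corrected, raw=raw, mask=mask, p_values=p_values,
        n_permutations=n_permutations, alpha=alpha, seed=seed,
    )
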