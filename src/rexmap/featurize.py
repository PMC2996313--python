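"""Frame featurization: superposition RMSD, H-bond fingerprints, image filter.

The clustering coordinate used throughout is a loop RMSD computed after
least-squares superposition on a rigid scaffold selection (the beta-sheet
analogue), so loop plasticity is measured in a common frame of reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FrameEnsemble",
    "HBondFingerprint",
    "kabsch_superpose",
    "loop_rmsd",
    "pairwise_loop_rmsd",
    "detect_hbonds",
    "image_distance_filter",
]


@dataclass
class FrameEnsemble:
    """An ordered set of frames sharing one topology.

    coords : (n_frames, n_atoms, 3) Angstrom
    atom_labels : tuple of (residue_id, atom_name)
    box_length : scalar or per-axis (3,) box edge lengths, or None
    traj_ids : optional per-frame trajectory-of-origin id
    """

    coords: np.ndarray
    atom_labels: tuple
    box_length: float | np.ndarray | None = None
    traj_ids: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must be (n_frames, n_atoms, 3)")
        if len(self.atom_labels) != self.coords.shape[1]:
            raise ValueError("atom_labels must match atom count")
        if not np.isfinite(self.coords).all():
            raise ValueError("coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def select(self, residues=None, atom_names=None) -> np.ndarray:
        """Atom indices matching the residue/atom-name filters."""
        idx = []
        for i, (rid, name) in enumerate(self.atom_labels):
            if residues is not None and rid not in residues:
                continue
            if atom_names is not None and name not in atom_names:
                continue
            idx.append(i)
        return np.asarray(idx, dtype=int)


@dataclass
class HBondFingerprint:
    """Per-frame sets of present H-bonds, each a (donor, acceptor) id pair."""

    bonds_per_frame: list  # list of frozensets of (donor_idx, acceptor_idx)

    def __len__(self) -> int:
        return len(self.bonds_per_frame)


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray):
    """Optimal rotation/translation of ``mobile`` onto ``target``.

    Returns ``(R, t)`` with the superposed coordinates ``mobile @ R.T + t``.
    Proper rotation enforced (no reflection).
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    H = (mobile - mc).T @ (target - tc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = tc - R @ mc
    return R, t


def loop_rmsd(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    align_selection: np.ndarray,
    rmsd_selection: np.ndarray,
) -> float:
    """RMSD over ``rmsd_selection`` after superposing on ``align_selection``.

    ``frame_b`` is superposed onto ``frame_a`` by least squares over the
    alignment atoms; the deviation is then measured over the loop atoms.
    Symmetric in its frame arguments (optimal superposition is).
    """
    frame_a = np.asarray(frame_a, dtype=float)
    frame_b = np.asarray(frame_b, dtype=float)
    if frame_a.shape != frame_b.shape:
        raise ValueError("frames must share one topology")
    align_selection = np.asarray(align_selection, dtype=int)
    rmsd_selection = np.asarray(rmsd_selection, dtype=int)
    if align_selection.size < 3:
        raise ValueError("align_selection needs at least 3 atoms")
    if rmsd_selection.size == 0:
        raise ValueError("rmsd_selection must be nonempty")
    R, t = kabsch_superpose(frame_b[align_selection], frame_a[align_selection])
    moved = frame_b[rmsd_selection] @ R.T + t
    diff = moved - frame_a[rmsd_selection]
    return float(np.sqrt((diff**2).sum() / rmsd_selection.size))


def pairwise_loop_rmsd(
    ensemble: FrameEnsemble,
    frame_indices_a: np.ndarray,
    frame_indices_b: np.ndarray,
    align_selection: np.ndarray,
    rmsd_selection: np.ndarray,
) -> np.ndarray:
    """Dense RMSD matrix between two frame index sets (loop after alignment)."""
    out = np.empty((len(frame_indices_a), len(frame_indices_b)))
    for i, fa in enumerate(frame_indices_a):
        a = ensemble.coords[fa]
        for j, fb in enumerate(frame_indices_b):
            out[i, j] = loop_rmsd(a, ensemble.coords[fb], align_selection, rmsd_selection)
    return out


def detect_hbonds(
    frame: np.ndarray,
    donors,
    acceptors,
    d_max: float = 3.5,
    angle_min: float = 120.0,
) -> frozenset:
    """Geometric H-bond detection for a single frame.

    donors : sequence of (donor_heavy_idx, hydrogen_idx)
    acceptors : sequence of acceptor heavy-atom indices
    A bond (D, A) is present iff the D-A heavy-atom distance <= ``d_max``
    (Angstrom) and the D-H...A angle >= ``angle_min`` (degrees).
    """
    frame = np.asarray(frame, dtype=float)
    present = set()
    for d_idx, h_idx in donors:
        if h_idx is None:
            raise ValueError(f"donor {d_idx} has no attached hydrogen")
        D = frame[d_idx]
        H = frame[h_idx]
        for a_idx in acceptors:
            if a_idx == d_idx:
                continue
            A = frame[a_idx]
            if np.linalg.norm(D - A) > d_max:
                continue
            v1 = D - H
            v2 = A - H
            n1 = np.linalg.norm(v1)
            n2 = np.linalg.norm(v2)
            if n1 == 0 or n2 == 0:
                continue
            cosang = np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0)
            if np.degrees(np.arccos(cosang)) >= angle_min:
                present.add((d_idx, a_idx))
    return frozenset(present)


def hbond_fingerprints(ensemble: FrameEnsemble, donors, acceptors,
                       d_max: float = 3.5, angle_min: float = 120.0) -> HBondFingerprint:
    """Per-frame geometric H-bond fingerprints for a whole ensemble."""
    return HBondFingerprint(
        bonds_per_frame=[
            detect_hbonds(ensemble.coords[i], donors, acceptors, d_max, angle_min)
            for i in range(ensemble.n_frames)
        ]
    )


_IMAGE_SHIFTS = np.array(
    [(a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)
     if (a, b, c) != (0, 0, 0)],
    dtype=float,
)


def image_distance_filter(ensemble: FrameEnsemble, cutoff: float = 5.0) -> FrameEnsemble:
    """Drop frames whose atoms come within ``cutoff`` of a periodic image.

    For every atom pair (including an atom with its own replicas) the
    distance to each of the 26 neighbouring periodic images of an
    orthorhombic box is evaluated; a frame is removed iff any such
    atom-to-image distance is below the cutoff.  Contacts *within* the
    central copy do not count — only image contacts do.  Order of the
    surviving frames is preserved.
    """
    if ensemble.box_length is None:
        raise ValueError("image filter requires box_length")
    box = np.asarray(ensemble.box_length, dtype=float)
    if box.ndim == 0:
        box = np.full(3, float(box))
    if cutoff <= 0:
        return ensemble

    keep = []
    for f in range(ensemble.n_frames):
        X = ensemble.coords[f]
        diff = X[:, None, :] - X[None, :, :]  # (n, n, 3)
        bad = False
        for s in _IMAGE_SHIFTS:
            d = np.linalg.norm(diff - s * box, axis=-1)
            if (d < cutoff).any():
                bad = True
                break
        if not bad:
            keep.append(f)
    return FrameEnsemble(
        coords=ensemble.coords[keep],
        atom_labels=ensemble.atom_labels,
        box_length=ensemble.box_length,
        traj_ids=None if ensemble.traj_ids is None else ensemble.traj_ids[keep],
    )
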