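"""Plain-text interchange: TSV tables, MTX matrices, JSON sidecars, PDB.

All tabular formats are tab-separated with a header row.  Shift tables and
H-bond observations use a long layout (one value per row) so they diff and
stream well; matrices go to dense TSV or sparse Matrix Market text.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread, mmwrite

from .exchange import ExperimentalRexProfile
from .synthetic import ChemicalShiftTable, GroundTruthModel, HBondObservations

__all__ = [
    "write_shift_table", "read_shift_table",
    "write_hbond_observations", "read_hbond_observations",
    "write_matrix_tsv", "read_matrix_tsv",
    "write_matrix_mtx", "read_matrix_mtx",
    "write_ground_truth", "read_ground_truth_summary",
    "write_experimental_profile", "read_experimental_profile",
    "write_assignments",
    "write_pdb_ensemble", "read_pdb_ensemble",
]


def write_shift_table(table: ChemicalShiftTable, path) -> None:
    n, m = table.shifts.shape
    df = pd.DataFrame(
        {
            "frame": np.repeat(np.arange(n), m),
            "residue": np.tile(table.residues, n),
            "shift_ppm": table.shifts.ravel(),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_shift_table(path) -> ChemicalShiftTable:
    df = pd.read_csv(path, sep="\t")
    wide = df.pivot(index="frame", columns="residue", values="shift_ppm").sort_index()
    residues = tuple(int(r) for r in wide.columns)
    return ChemicalShiftTable(shifts=wide.to_numpy(float), residues=residues)


def write_hbond_observations(obs: HBondObservations, path) -> None:
    """Long TSV of present bonds only: columns frame, bond."""
    frames, bonds = np.nonzero(obs.present)
    df = pd.DataFrame(
        {"frame": frames, "bond": [obs.bond_names[j] for j in bonds]}
    )
    # header row encodes totals so absent bonds/frames round-trip
    with open(path, "w") as fh:
        fh.write(f"# n_frames={obs.n_frames}\tbonds={','.join(obs.bond_names)}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_hbond_observations(path) -> HBondObservations:
    with open(path) as fh:
        header = fh.readline().strip()
        df = pd.read_csv(fh, sep="\t")
    meta = dict(item.split("=", 1) for item in header.lstrip("# ").split("\t"))
    names = tuple(meta["bonds"].split(","))
    present = np.zeros((int(meta["n_frames"]), len(names)), dtype=bool)
    col = {b: j for j, b in enumerate(names)}
    present[df["frame"].to_numpy(int), [col[b] for b in df["bond"]]] = True
    return HBondObservations(present=present, bond_names=names)


def write_matrix_tsv(M: np.ndarray, path) -> None:
    pd.DataFrame(np.asarray(M)).to_csv(path, sep="\t", index=False, header=False)


def read_matrix_tsv(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t", header=None).to_numpy(float)


def write_matrix_mtx(M, path) -> None:
    mmwrite(str(path), sparse.coo_matrix(np.asarray(M)))


def read_matrix_mtx(path) -> np.ndarray:
    return np.asarray(mmread(str(path)).todense())


def write_ground_truth(model: GroundTruthModel, path) -> None:
    """JSON sidecar with everything except the (large) transition matrix."""
    payload = {
        "n_micro": model.n_micro,
        "n_macro": model.n_macro,
        "p_stay": model.p_stay,
        "seed": model.seed,
        "lumping_true": model.lumping_true.tolist(),
        "minor_macrostates": sorted(model.minor_macrostates),
        "minor_mass": model.minor_mass,
        "macro_populations": model.macro_populations.tolist(),
        "residues": list(model.residues),
        "delta_omega_true": model.delta_omega_true.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_ground_truth_summary(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_experimental_profile(profile: ExperimentalRexProfile, path) -> None:
    df = pd.DataFrame({"residue": profile.residues, "rex_ratio": profile.ratios})
    with open(path, "w") as fh:
        fh.write(
            f"# reference={profile.reference_residue}\t"
            f"loop={','.join(str(r) for r in profile.loop_residues)}\n"
        )
        df.to_csv(fh, sep="\t", index=False)


def read_experimental_profile(path) -> ExperimentalRexProfile:
    with open(path) as fh:
        header = fh.readline().strip()
        df = pd.read_csv(fh, sep="\t")
    meta = dict(item.split("=", 1) for item in header.lstrip("# ").split("\t"))
    return ExperimentalRexProfile(
        residues=tuple(df["residue"].astype(int)),
        ratios=df["rex_ratio"].to_numpy(float),
        reference_residue=int(meta["reference"]),
        loop_residues=tuple(int(r) for r in meta["loop"].split(",")),
    )


def write_assignments(micro_labels, macro_labels, path) -> None:
    pd.DataFrame(
        {"frame": np.arange(len(micro_labels)), "microstate": micro_labels,
         "macrostate": macro_labels}
    ).to_csv(path, sep="\t", index=False)


def write_pdb_ensemble(ensemble, path) -> None:
    """Write a FrameEnsemble as a multi-model PDB (CA pseudo-topology)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n_frames, n_atoms = ensemble.n_frames, ensemble.n_atoms
    atoms = struc.AtomArrayStack(n_frames, n_atoms)
    atoms.coord = ensemble.coords.astype(np.float32)
    atoms.res_id = np.array([rid for rid, _ in ensemble.atom_labels])
    atoms.atom_name = np.array([name for _, name in ensemble.atom_labels])
    atoms.res_name = np.array(["ALA"] * n_atoms)
    atoms.chain_id = np.array(["A"] * n_atoms)
    atoms.element = np.array([name[0] for _, name in ensemble.atom_labels])
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(path))


def read_pdb_ensemble(path):
    from biotite.structure.io.pdb import PDBFile

    from .featurize import FrameEnsemble

    atoms = PDBFile.read(str(path)).get_structure()
    return FrameEnsemble(
        coords=np.asarray(atoms.coord, dtype=float),
        atom_labels=tuple(
            (int(r), str(n)) for r, n in zip(atoms.res_id, atoms.atom_name)
        ),
    )
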