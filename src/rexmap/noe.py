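"""NOE distance-restraint checking against a population-weighted ensemble.

NOE cross-peak intensities average as r^-6 over the conformational ensemble,
so the effective distance compared against an upper bound is

    d_eff = ( sum_k w_k r_k^-6 )^(-1/6)

over representative structures k with populations w_k.  Violations
(max(0, d_eff - upper)) are binned into a small table of counts and exact
percentages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import RestraintSet

__all__ = [
    "RestraintSet",
    "ViolationTable",
    "load_restraints",
    "write_restraints",
    "ensemble_distance",
    "violation_table",
]

#: default violation bin edges (Angstrom) -> rows: none, (0,1], (1,2], (2,3], >3
DEFAULT_BIN_EDGES = (1.0, 2.0, 3.0)


def load_restraints(path) -> RestraintSet:
    """Read a restraint TSV with columns atom1, atom2, upper_A [, lower_A].

    Atom columns are 0-based integer atom indices into the shared topology.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("atom1", "atom2", "upper_A"):
        if col not in df.columns:
            raise ValueError(f"restraint file lacks required column '{col}'")
    if (df["upper_A"] <= 0).any():
        bad = int(df.index[df["upper_A"] <= 0][0]) + 2  # +header +1-based
        raise ValueError(f"non-positive upper bound at line {bad}")
    lower = df["lower_A"].to_numpy(float) if "lower_A" in df.columns else None
    return RestraintSet(
        pairs=df[["atom1", "atom2"]].to_numpy(int),
        upper=df["upper_A"].to_numpy(float),
        lower=lower,
    )


def write_restraints(restraints: RestraintSet, path) -> None:
    df = pd.DataFrame(
        {"atom1": restraints.pairs[:, 0], "atom2": restraints.pairs[:, 1],
         "upper_A": restraints.upper}
    )
    if restraints.lower is not None:
        df["lower_A"] = restraints.lower
    df.to_csv(path, sep="\t", index=False)


def ensemble_distance(structures: np.ndarray, weights: np.ndarray, pair,
                      mode: str = "r6") -> float:
    """Population-weighted effective distance for one atom pair.

    ``mode="r6"`` (default) is the NOE-consistent inverse-sixth-power mean;
    ``mode="linear"`` is the plain weighted mean distance.
    """
    structures = np.asarray(structures, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if (weights < 0).any() or not np.isclose(weights.sum(), 1.0):
        raise ValueError("weights must be non-negative and sum to 1")
    i, j = pair
    r = np.linalg.norm(structures[:, i] - structures[:, j], axis=1)
    if (r == 0).any():
        raise ValueError("coincident atoms give an undefined r^-6 average")
    if mode == "r6":
        return float((weights @ r**-6.0) ** (-1.0 / 6.0))
    if mode == "linear":
        return float(weights @ r)
    raise ValueError(f"unknown averaging mode {mode!r}")


@dataclass
class ViolationTable:
    """Binned NOE violation summary with exact percentages."""

    bin_edges: tuple
    labels: tuple
    counts: np.ndarray
    violations: np.ndarray   # per-restraint violation magnitude (Angstrom)
    distances: np.ndarray    # per-restraint effective distance

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def percentages(self) -> np.ndarray:
        return 100.0 * self.counts / self.total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"range": self.labels, "count": self.counts,
             "percent": np.round(self.percentages, 2)}
        )


def violation_table(
    restraints: RestraintSet,
    structures: np.ndarray,
    weights: np.ndarray,
    bin_edges=DEFAULT_BIN_EDGES,
    mode: str = "r6",
) -> ViolationTable:
    """Bin per-restraint ensemble violations.

    Violation = max(0, d_eff - upper).  Bins are half-open (lo, hi] above
    zero, with an exact-zero "no violation" row and an open top row.
    """
    edges = tuple(float(e) for e in bin_edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly ascending")
    deff = np.array(
        [ensemble_distance(structures, weights, p, mode) for p in restraints.pairs]
    )
    viol = np.maximum(0.0, deff - restraints.upper)

    bounds = (0.0,) + edges + (np.inf,)
    labels = ["No violations"] + [
        f"({lo:g}, {hi:g}] A" if np.isfinite(hi) else f"> {lo:g} A"
        for lo, hi in zip(bounds[:-1], bounds[1:])
    ]
    counts = np.zeros(len(labels), dtype=int)
    counts[0] = int((viol == 0).sum())
    for k, (lo, hi) in enumerate(zip(bounds[:-1], bounds[1:]), start=1):
        counts[k] = int(((viol > lo) & (viol <= hi)).sum())
    return ViolationTable(
        bin_edges=edges,
        labels=tuple(labels),
        counts=counts,
        violations=viol,
        distances=deff,
    )
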