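"""End-to-end exchange-mapping pipeline on synthetic ground-truth data.

Glues the stages together the way an analysis of a real ensemble would run:
generate (or load) microstate paths and per-frame observables, estimate and
validate the microstate transition matrix, lump into macrostates, locate the
signature H-bonds (Method 1), and search macrostate subsets for the
exchange-state partition best correlated with the experimental relative Rex
profile (Method 3), with the 2-macrostate model (Method 2) as the baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import exchange, msm, synthetic

__all__ = ["PipelineResult", "run_exchange_pipeline"]


@dataclass
class PipelineResult:
    model: synthetic.GroundTruthModel
    paths: synthetic.StatePathSet
    shifts: synthetic.ChemicalShiftTable
    hbonds: synthetic.HBondObservations
    experimental: exchange.ExperimentalRexProfile
    T_micro: msm.TransitionMatrix
    pi_micro: np.ndarray
    lumping: msm.MacrostateAssignment
    method1: exchange.ExchangePartition
    method2: exchange.ExchangePartition
    method3: exchange.ExchangePartition

    @property
    def planted_minor_frames(self) -> np.ndarray:
        return np.flatnonzero(self.model.exchange_state_of(self.paths.concatenated))

    def recovered_minor_matches_truth(self) -> bool:
        return np.array_equal(
            np.sort(self.method3.minor_frames), self.planted_minor_frames
        )


def run_exchange_pipeline(
    n_micro: int = 1000,
    n_macro: int = 40,
    p_stay: float = 0.95,
    n_paths: int = 200,
    path_length: int = 5500,
    lag: int = 1,
    seed: int = 0,
    anneal: bool = True,
    model: synthetic.GroundTruthModel = None,
) -> PipelineResult:
    """Run generate -> estimate -> lump -> Methods 1/2/3 and collect results.

    Randomness is split deterministically off ``seed`` for the model, the
    paths and the emissions, so two runs with different seeds share nothing
    but the protocol.
    """
    if model is None:
        model = synthetic.make_ground_truth_msm(
            n_micro=n_micro, n_macro=n_macro, p_stay=p_stay, seed=seed
        )
    paths = synthetic.sample_state_paths(
        model, n_paths=n_paths, path_length=path_length, seed=seed + 1
    )
    spec = synthetic.default_emission_spec(model, seed=seed)
    _, shifts, hbonds = synthetic.emit_observables(paths, model, spec, seed=seed + 2)
    experimental = synthetic.experimental_rex_profile(model, spec)

    counts = msm.count_transitions(paths.paths, lag=lag, n_states=model.n_micro)
    T_micro = msm.estimate_T(counts, symmetrize=True, lag=lag)
    pi_micro = msm.stationary(T_micro)

    lumping = msm.pcca(T_micro, model.n_macro, pi=pi_micro)
    if anneal:
        lumping = msm.anneal_lumping(T_micro, lumping, pi=pi_micro, seed=seed + 3)
    frame_macro = lumping.frame_macrostates(paths.concatenated)

    method1 = exchange.search_hbond_partition(hbonds, shifts, experimental)
    signature = method1.minor_unique_bonds or method1.minor_members
    required = [hbonds.frame_set(b) for b in signature]

    lump2 = msm.pcca(T_micro, 2, pi=pi_micro)
    if anneal:
        lump2 = msm.anneal_lumping(T_micro, lump2, pi=pi_micro, seed=seed + 4)
    method2 = exchange.search_macrostate_partition(
        lump2.frame_macrostates(paths.concatenated), shifts, experimental
    )

    method3 = exchange.search_macrostate_partition(
        frame_macro, shifts, experimental, required_hbond_frames=required
    )
    return PipelineResult(
        model=model, paths=paths, shifts=shifts, hbonds=hbonds,
        experimental=experimental, T_micro=T_micro, pi_micro=pi_micro,
        lumping=lumping, method1=method1, method2=method2, method3=method3,
    )
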