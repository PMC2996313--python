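"""MSM construction: clustering, estimation, validation, lumping."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from rexmap import msm, synthetic


class TestKcenters:
    def test_k_equals_n_gives_zero_radius(self, rng):
        X = rng.normal(size=(15, 2))
        out = msm.kcenters(X, k=15)
        assert out.radius == 0.0
        assert len(np.unique(out.labels)) == 15

    def test_two_separated_clouds_recovered(self, rng):
        a = rng.normal(size=(10, 3)) * 0.1
        b = rng.normal(size=(10, 3)) * 0.1 + 100.0
        X = np.vstack([a, b])
        out = msm.kcenters(X, k=2)
        assert len(set(out.labels[:10])) == 1
        assert len(set(out.labels[10:])) == 1
        assert out.labels[0] != out.labels[10]

    def test_radius_within_2x_of_optimal(self, rng):
        """Classical 2-approximation bound vs a brute-force optimal oracle."""
        X = rng.normal(size=(10, 2)) * 3
        D = np.linalg.norm(X[:, None] - X[None, :], axis=2)
        for k in (2, 3):
            best = min(
                D[list(centers)].min(axis=0).max()
                for centers in itertools.combinations(range(10), k)
            )
            out = msm.kcenters(X, k=k)
            assert out.radius <= 2 * best + 1e-12

    def test_target_radius_mode(self, rng):
        X = rng.normal(size=(60, 2)) * 5
        out = msm.kcenters(X, target_radius=2.0)
        assert out.radius <= 2.0

    def test_members_within_reported_radius(self, rng):
        X = rng.normal(size=(40, 3))
        out = msm.kcenters(X, k=5)
        centers = X[out.centers]
        d = np.linalg.norm(X - centers[out.labels], axis=1)
        assert (d <= out.radius + 1e-12).all()

    def test_invalid_k(self, rng):
        with pytest.raises(ValueError):
            msm.kcenters(rng.normal(size=(5, 2)), k=0)


class TestCounting:
    def test_single_path_lag1(self):
        C = msm.count_transitions([[1, 1, 2]], lag=1)
        assert C[1, 1] == 1 and C[1, 2] == 1 and C.sum() == 2

    def test_single_path_lag2(self):
        C = msm.count_transitions([[1, 1, 2]], lag=2)
        assert C[1, 2] == 1 and C.sum() == 1

    def test_total_counts_arithmetic(self, rng):
        paths = [rng.integers(0, 4, size=n) for n in (10, 3, 7, 2)]
        for lag in (1, 2, 4):
            with pytest.warns(UserWarning) if lag >= 2 else _nullcontext():
                C = msm.count_transitions(paths, lag=lag)
            assert C.sum() == sum(max(len(p) - lag, 0) for p in paths)

    def test_counting_never_crosses_path_boundaries(self):
        C = msm.count_transitions([[0, 1], [1, 0]], lag=1)
        assert C[0, 1] == 1 and C[1, 0] == 1 and C.sum() == 2


class _nullcontext:
    def __enter__(self):
        return self

    def __exit__(self, *a):
        return False


class TestEstimateT:
    def test_row_normalization(self):
        out = msm.estimate_T(np.array([[9.0, 1], [1, 9]]), symmetrize=False)
        assert np.allclose(out.T, [[0.9, 0.1], [0.1, 0.9]])

    def test_symmetrized_satisfies_detailed_balance(self, rng):
        C = rng.integers(1, 50, size=(6, 6)).astype(float)
        out = msm.estimate_T(C, symmetrize=True)
        pi = msm.stationary(out)
        flow = pi[:, None] * out.T
        assert np.abs(flow - flow.T).max() < 1e-10

    def test_zero_row_becomes_self_loop(self):
        C = np.zeros((3, 3))
        C[0, 1] = C[1, 0] = 5
        out = msm.estimate_T(C, symmetrize=False)
        assert out.T[2, 2] == 1.0


class TestStationary:
    def test_symmetric_T_uniform(self):
        T = np.array([[0.5, 0.3, 0.2], [0.3, 0.5, 0.2], [0.2, 0.2, 0.6]])
        # symmetric matrix => uniform stationary
        pi = msm.stationary(T)
        assert np.allclose(pi, 1 / 3, atol=1e-10)

    def test_two_state_balance(self):
        pi = msm.stationary(np.array([[0.9, 0.1], [0.5, 0.5]]))
        assert np.allclose(pi, [5 / 6, 1 / 6], atol=1e-10)

    def test_residual_contract(self, small_model):
        pi = msm.stationary(small_model.T_true)
        assert np.abs(pi @ small_model.T_true - pi).max() < 1e-10

    def test_reducible_chain_warns_and_uses_largest_closed_class(self):
        T = np.eye(3)
        T[0] = [0.5, 0.5, 0]
        T[1] = [0.5, 0.5, 0]
        with pytest.warns(UserWarning, match="reducible"):
            pi = msm.stationary(T)
        assert pi[2] == 0.0 and np.isclose(pi[:2].sum(), 1.0)


class TestImpliedTimescales:
    def test_two_state_closed_form(self):
        T = np.array([[0.95, 0.05], [0.05, 0.95]])
        t = msm.implied_timescales(T, lag=1, n_timescales=1)
        assert t[0] == pytest.approx(-1 / np.log(0.9), abs=1e-10)

    def test_block_diagonal_flagged_infinite(self):
        T = np.eye(4)
        T[:2, :2] = [[0.9, 0.1], [0.1, 0.9]]
        T[2:, 2:] = [[0.8, 0.2], [0.2, 0.8]]
        t = msm.implied_timescales(T, lag=1, n_timescales=2)
        assert np.isinf(t[0])

    def test_spectral_mapping_of_matrix_power(self, small_model):
        T = small_model.T_true
        t1 = msm.implied_timescales(T, lag=1, n_timescales=4)
        t2 = msm.implied_timescales(np.linalg.matrix_power(T, 2), lag=2,
                                    n_timescales=4)
        assert np.allclose(t1, t2, rtol=1e-8)

    def test_bootstrap_shape_and_determinism(self, small_paths):
        a = msm.implied_timescales_bootstrap(small_paths.paths, lag=1,
                                             n_timescales=3, n_boot=5, seed=4)
        b = msm.implied_timescales_bootstrap(small_paths.paths, lag=1,
                                             n_timescales=3, n_boot=5, seed=4)
        assert a.shape == (5, 3)
        assert np.array_equal(a, b, equal_nan=True)


class TestCKTest:
    def test_k1_deviation_zero(self, small_paths):
        rep = msm.ck_test(small_paths.paths, lag=1, lag_multiples=(1,))
        assert rep.deviations[1] == pytest.approx(0.0, abs=1e-12)

    def test_markov_chain_passes_within_multinomial_error(self):
        m = synthetic.make_ground_truth_msm(n_micro=10, n_macro=2, p_stay=0.8, seed=9)
        paths = synthetic.sample_state_paths(m, 20, 5000, seed=10)
        rep = msm.ck_test(paths.paths, lag=1, lag_multiples=(2, 3))
        # rows hold >= 100k/10 counts; 4 standard errors on a probability
        bound = 4 * np.sqrt(0.25 / (100000 / 10 / 2))
        assert rep.max_deviation() < bound

    def test_hidden_rule_stream_fails_at_k2(self):
        # deterministic period-4 label stream: 0,0,1,1,0,0,1,1,...
        # 1-step estimate says T(0->0)=T(0->1)=1/2; the true 2-step law is
        # deterministic alternation, so CK must fail at k=2.
        path = np.tile([0, 0, 1, 1], 3000)
        rep = msm.ck_test([path], lag=1, lag_multiples=(2,))
        assert rep.deviations[2] > 0.2


class TestLumping:
    def two_block_chain(self, eps=0.01):
        m = synthetic.make_ground_truth_msm(n_micro=20, n_macro=2,
                                            p_stay=1 - eps, seed=3)
        return m

    def test_pcca_recovers_well_separated_blocks(self):
        m = self.two_block_chain()
        for method in ("simplex", "sign"):
            lump = msm.pcca(m.T_true, 2, method=method)
            assert adjusted_rand_score(m.lumping_true, lump.lumping) == 1.0

    def test_pcca_identity_when_n_macro_equals_n(self):
        m = self.two_block_chain()
        lump = msm.pcca(m.T_true, 20)
        assert lump.n_macro == 20
        assert len(np.unique(lump.lumping)) == 20

    def test_pcca_recovery_on_sampled_default_model(self):
        """1000 microstates / 40 blocks, one million sampled steps."""
        m = synthetic.make_ground_truth_msm(n_micro=1000, n_macro=40,
                                            p_stay=0.95, seed=21)
        paths = synthetic.sample_state_paths(m, 100, 10000, seed=22)
        C = msm.count_transitions(paths.paths, lag=1, n_states=1000)
        T = msm.estimate_T(C, symmetrize=True)
        pi = msm.stationary(T)
        lump = msm.pcca(T, 40, pi=pi)
        assert adjusted_rand_score(m.lumping_true, lump.lumping) >= 0.9

    def test_metastability_of_planted_beats_random_lumpings(self, small_model,
                                                            rng):
        m = small_model
        pi = m.stationary
        planted = msm.metastability(m.T_true, pi, m.lumping_true)
        sizes = np.bincount(m.lumping_true)
        for _ in range(100):
            perm = rng.permutation(m.n_micro)
            random_lump = np.empty(m.n_micro, dtype=int)
            random_lump[perm] = np.repeat(np.arange(m.n_macro), sizes)
            assert msm.metastability(m.T_true, pi, random_lump) <= planted

    def test_anneal_never_degrades_and_reaches_exhaustive_optimum(self):
        m = synthetic.make_ground_truth_msm(n_micro=6, n_macro=2, p_stay=0.9,
                                            seed=5)
        pi = m.stationary
        # exhaustive oracle over all 2-partitions of 6 microstates
        best = -np.inf
        for assign in itertools.product((0, 1), repeat=6):
            arr = np.array(assign)
            if len(set(assign)) < 2:
                continue
            best = max(best, msm.metastability(m.T_true, pi, arr))
        bad_init = msm.MacrostateAssignment(
            lumping=np.array([0, 1, 0, 1, 0, 1]), n_macro=2,
            metastability=msm.metastability(m.T_true, pi,
                                            np.array([0, 1, 0, 1, 0, 1])),
        )
        out = msm.anneal_lumping(m.T_true, bad_init, pi=pi, seed=6)
        assert out.metastability >= bad_init.metastability
        assert out.metastability == pytest.approx(best, abs=1e-10)

    def test_anneal_deterministic_given_seed(self, small_model):
        m = small_model
        pi = m.stationary
        init = msm.pcca(m.T_true, m.n_macro, pi=pi)
        a = msm.anneal_lumping(m.T_true, init, pi=pi, seed=7)
        b = msm.anneal_lumping(m.T_true, init, pi=pi, seed=7)
        assert np.array_equal(a.lumping, b.lumping)

    def test_lump_T_identity_and_collapse(self, small_model):
        m = small_model
        pi = m.stationary
        ident = msm.lump_T(m.T_true, pi, np.arange(m.n_micro))
        assert np.allclose(ident.T, m.T_true, atol=1e-12)
        one = msm.lump_T(m.T_true, pi, np.zeros(m.n_micro, dtype=int))
        assert one.T.shape == (1, 1) and one.T[0, 0] == pytest.approx(1.0)

    def test_lump_T_matches_hand_expanded_sum(self):
        T = np.array(
            [[0.7, 0.2, 0.05, 0.05],
             [0.1, 0.8, 0.05, 0.05],
             [0.05, 0.05, 0.6, 0.3],
             [0.05, 0.05, 0.4, 0.5]]
        )
        pi = msm.stationary(T)
        lump = np.array([0, 0, 1, 1])
        out = msm.lump_T(T, pi, lump)
        # direct-summation oracle
        expect = np.zeros((2, 2))
        for A in (0, 1):
            for B in (0, 1):
                num = sum(pi[i] * T[i, j]
                          for i in range(4) if lump[i] == A
                          for j in range(4) if lump[j] == B)
                expect[A, B] = num / pi[lump == A].sum()
        assert np.allclose(out.T, expect, atol=1e-12)

    def test_end_to_end_macrostate_population_recovery(self):
        """Estimated macrostate populations near planted at 1e6 steps."""
        m = synthetic.make_ground_truth_msm(n_micro=200, n_macro=8,
                                            p_stay=0.95, seed=31)
        paths = synthetic.sample_state_paths(m, 100, 10000, seed=32)
        C = msm.count_transitions(paths.paths, lag=1, n_states=200)
        T = msm.estimate_T(C, symmetrize=True)
        pi = msm.stationary(T)
        lump = msm.anneal_lumping(T, msm.pcca(T, 8, pi=pi), pi=pi, seed=33)
        est = np.bincount(lump.lumping, weights=pi, minlength=8)
        true = m.macro_populations
        # total-variation distance under best label matching via sorting
        tv = 0.5 * np.abs(np.sort(est) - np.sort(true)).sum()
        assert tv < 0.03
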