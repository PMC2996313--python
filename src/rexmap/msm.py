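"""Hierarchical Markov state model construction and validation.

Pipeline: geometric k-centers microstates -> lag-time transition counts ->
(optionally symmetrized) transition matrix -> stationary distribution,
implied timescales and Chapman-Kolmogorov validation -> spectral (PCCA)
lumping into metastable macrostates -> simulated-annealing refinement of the
lumping by direct metastability maximization.

Conventions: microstate and macrostate ids are 0-based; lag times are in
path steps; stationary distributions are left Perron eigenvectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csgraph, csr_matrix
from scipy.sparse.linalg import eigs as sparse_eigs

__all__ = [
    "MicrostateAssignment",
    "TransitionMatrix",
    "MacrostateAssignment",
    "CKReport",
    "kcenters",
    "count_transitions",
    "estimate_T",
    "stationary",
    "implied_timescales",
    "implied_timescales_bootstrap",
    "ck_test",
    "pcca",
    "metastability",
    "anneal_lumping",
    "lump_T",
]


# ---------------------------------------------------------------------------
# microstate clustering
# ---------------------------------------------------------------------------

@dataclass
class MicrostateAssignment:
    labels: np.ndarray          # (n_frames,) microstate per frame
    centers: np.ndarray         # (k,) frame index of each cluster center
    radius: float               # max member-to-center distance
    distances: np.ndarray = field(repr=False, default=None)  # (n_frames,)

    @property
    def k(self) -> int:
        return len(self.centers)


def kcenters(X, k: int = None, metric=None, seed: int = 0,
             target_radius: float = None) -> MicrostateAssignment:
    """Approximate (farthest-point) k-centers clustering.

    Greedy 2-approximation: seed with frame 0, then repeatedly promote the
    frame farthest from its current center.  Produces clusters of roughly
    equal radius.  Either ``k`` or ``target_radius`` must be given; with
    ``target_radius`` centers are added until the covering radius drops to
    the target (the "3 Angstrom spread" usage).

    Parameters
    ----------
    X : (n, d) feature array, or any sequence indexable by frame when a
        custom ``metric`` is supplied.
    metric : callable(X, center_index) -> (n,) distances; Euclidean default.
    seed : kept for interface stability; the first center is deterministic
        (frame 0) and ties break toward the lowest frame index.
    """
    n = len(X)
    if k is None and target_radius is None:
        raise ValueError("provide k or target_radius")
    if k is not None and not (1 <= k <= n):
        raise ValueError("k must be in [1, n_frames]")
    if metric is None:
        Xa = np.asarray(X, dtype=float)

        def metric(_, c):
            return np.linalg.norm(Xa - Xa[c], axis=1)

    centers = [0]
    dist = metric(X, 0)
    labels = np.zeros(n, dtype=int)
    while True:
        radius = float(dist.max()) if n else 0.0
        if k is not None and len(centers) >= k:
            break
        if target_radius is not None and radius <= target_radius:
            break
        if len(centers) >= n:
            break
        nxt = int(np.argmax(dist))  # argmax returns the lowest index on ties
        centers.append(nxt)
        d_new = metric(X, nxt)
        closer = d_new < dist
        labels[closer] = len(centers) - 1
        dist = np.minimum(dist, d_new)
    return MicrostateAssignment(
        labels=labels,
        centers=np.asarray(centers, dtype=int),
        radius=float(dist.max()) if n else 0.0,
        distances=dist,
    )


# ---------------------------------------------------------------------------
# transition matrix estimation
# ---------------------------------------------------------------------------

@dataclass
class TransitionMatrix:
    T: np.ndarray
    lag: int = 1
    symmetrized: bool = False
    counts: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        if not np.allclose(self.T.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("transition matrix rows must sum to 1 within 1e-10")
        if (self.T < 0).any():
            raise ValueError("transition probabilities must be non-negative")

    @property
    def n(self) -> int:
        return self.T.shape[0]


def count_transitions(paths, lag: int = 1, n_states: int = None) -> np.ndarray:
    """Sliding-window transition counts at the given lag.

    Counting never crosses path boundaries; a path shorter than ``lag + 1``
    contributes nothing (warned).
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    arrs = [np.asarray(p, dtype=np.int64) for p in paths]
    if n_states is None:
        n_states = int(max(p.max() for p in arrs if p.size)) + 1
    C = np.zeros(n_states * n_states, dtype=float)
    for p in arrs:
        if len(p) <= lag:
            warnings.warn(f"path of length {len(p)} contributes no counts at lag {lag}")
            continue
        idx = p[:-lag] * n_states + p[lag:]
        C += np.bincount(idx, minlength=n_states * n_states)
    return C.reshape(n_states, n_states)


def estimate_T(counts: np.ndarray, symmetrize: bool = True, lag: int = 1) -> TransitionMatrix:
    """Row-normalized transition matrix from a count matrix.

    With ``symmetrize`` the counts are replaced by (C + C^T)/2 first, which
    enforces detailed balance of the estimate.  All-zero rows become
    self-loop (identity) rows.
    """
    C = np.asarray(counts, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("counts must be square")
    if symmetrize:
        C = 0.5 * (C + C.T)
    rows = C.sum(axis=1)
    T = np.empty_like(C)
    zero = rows == 0
    T[~zero] = C[~zero] / rows[~zero, None]
    T[zero] = 0.0
    zi = np.flatnonzero(zero)
    T[zi, zi] = 1.0
    return TransitionMatrix(T=T, lag=lag, symmetrized=symmetrize, counts=np.asarray(counts, float))


def _as_matrix(T) -> np.ndarray:
    return T.T if isinstance(T, TransitionMatrix) else np.asarray(T, dtype=float)


def stationary(T) -> np.ndarray:
    """Stationary distribution: leading left eigenvector, pi T = pi.

    For a reducible chain the stationary distribution is supported on the
    largest closed communicating class; a warning reports the component
    structure and mass is placed on that class only.
    """
    M = _as_matrix(T)
    n = M.shape[0]
    n_comp, comp = csgraph.connected_components(csr_matrix(M > 0), connection="strong")
    support = np.arange(n)
    if n_comp > 1:
        # keep only closed classes (no outgoing probability), take the largest
        closed = []
        for c in range(n_comp):
            members = comp == c
            if M[np.ix_(members, ~members)].sum() <= 1e-15:
                closed.append(c)
        sizes = [np.sum(comp == c) for c in closed]
        best = closed[int(np.argmax(sizes))]
        support = np.flatnonzero(comp == best)
        warnings.warn(
            f"reducible chain: {n_comp} strong components; stationary mass "
            f"placed on the largest closed class ({len(support)} states)"
        )
    Ms = M[np.ix_(support, support)]
    m = len(support)
    if m == 1:
        v = np.array([1.0])
    elif m <= 200:
        w, V = np.linalg.eig(Ms.T)
        v = np.real(V[:, np.argmax(np.real(w))])
    else:
        w, V = sparse_eigs(csr_matrix(Ms.T), k=1, which="LR",
                           v0=np.full(m, 1.0 / m))
        v = np.real(V[:, 0])
    v = np.abs(v)
    v /= v.sum()
    # polish to the 1e-10 residual contract
    for _ in range(1000):
        v_new = v @ Ms
        v_new /= v_new.sum()
        if np.abs(v_new - v).max() < 1e-14:
            v = v_new
            break
        v = v_new
    pi = np.zeros(n)
    pi[support] = v
    return pi


def implied_timescales(T, lag: int = None, n_timescales: int = 5) -> np.ndarray:
    """Relaxation timescales t_i = -lag / ln(lambda_i).

    Eigenvalues are sorted by modulus (descending); the Perron eigenvalue is
    skipped.  Further eigenvalues at or above 1 (disconnected chains) give
    infinite timescales.  Complex pairs are reported via their modulus, with
    a warning.
    """
    if isinstance(T, TransitionMatrix) and lag is None:
        lag = T.lag
    if lag is None:
        lag = 1
    M = _as_matrix(T)
    ev = np.linalg.eigvals(M)
    order = np.argsort(-np.abs(ev))
    ev = ev[order][1 : n_timescales + 1]
    if np.abs(ev.imag).max(initial=0.0) > 1e-10:
        warnings.warn("complex eigenvalues encountered; using moduli")
    lam = np.abs(ev)
    out = np.empty(len(lam))
    for i, l in enumerate(lam):
        if l >= 1.0 - 1e-12:
            out[i] = np.inf
        elif l <= 0.0:
            out[i] = 0.0
        else:
            out[i] = -lag / np.log(l)
    return out


def implied_timescales_bootstrap(paths, lag: int, n_timescales: int = 5,
                                 n_boot: int = 10, n_segments: int = 10,
                                 symmetrize: bool = True, seed: int = 0) -> np.ndarray:
    """Bootstrap implied timescales by resampling contiguous path segments.

    Paths are chopped into ``n_segments`` contiguous pieces which are
    resampled with replacement; returns an (n_boot, n_timescales) array of
    timescale replicas from which percentile error bars can be read.
    """
    arrs = [np.asarray(p) for p in paths]
    pieces = []
    for p in arrs:
        splits = np.array_split(p, max(1, min(n_segments // max(1, len(arrs)), len(p) // (lag + 1))) or 1)
        pieces.extend(s for s in splits if len(s) > lag)
    if len(pieces) < n_segments:
        # fall back to treating whole paths as segments
        pieces = [p for p in arrs if len(p) > lag]
    n_states = int(max(p.max() for p in arrs)) + 1
    rng = np.random.default_rng(seed)
    out = np.empty((n_boot, n_timescales))
    for b in range(n_boot):
        take = rng.integers(0, len(pieces), size=len(pieces))
        C = count_transitions([pieces[i] for i in take], lag, n_states=n_states)
        out[b] = implied_timescales(estimate_T(C, symmetrize=symmetrize, lag=lag),
                                    n_timescales=n_timescales)
    return out


@dataclass
class CKReport:
    """Chapman-Kolmogorov deviations: max |T_emp(k tau) - T(tau)^k| per k."""

    lag: int
    deviations: dict  # lag multiple -> max abs deviation

    def max_deviation(self) -> float:
        return max(self.deviations.values())


def ck_test(paths, lag: int = 1, lag_multiples=(1, 2, 4, 8),
            symmetrize: bool = True) -> CKReport:
    """Chapman-Kolmogorov validation of Markovianity.

    Estimates T at the base lag from ``paths``, then for each multiple k
    compares the k-step matrix power against a direct estimate at lag k*tau.
    Only rows observed at the longer lag are compared (unvisited states are
    uninformative there).
    """
    arrs = [np.asarray(p) for p in paths]
    n_states = int(max(p.max() for p in arrs)) + 1
    T1 = estimate_T(count_transitions(arrs, lag, n_states), symmetrize, lag)
    devs = {}
    for k in lag_multiples:
        Ck = count_transitions(arrs, k * lag, n_states)
        observed = Ck.sum(axis=1) > 0
        Tk = estimate_T(Ck, symmetrize, k * lag)
        Tpow = np.linalg.matrix_power(T1.T, k)
        devs[k] = float(np.abs(Tk.T - Tpow)[observed].max())
    return CKReport(lag=lag, deviations=devs)


# ---------------------------------------------------------------------------
# kinetic lumping
# ---------------------------------------------------------------------------

@dataclass
class MacrostateAssignment:
    lumping: np.ndarray     # (n_micro,) macrostate per microstate
    n_macro: int
    metastability: float

    def __post_init__(self):
        present = set(np.unique(self.lumping))
        if present != set(range(self.n_macro)):
            raise ValueError("lumping must be surjective onto range(n_macro)")

    def frame_macrostates(self, micro_labels: np.ndarray) -> np.ndarray:
        return self.lumping[np.asarray(micro_labels)]


def lump_T(T, pi: np.ndarray, lumping: np.ndarray, lag: int = None) -> TransitionMatrix:
    """Stationary-weighted coarse-graining of a microstate matrix.

    T_macro(A, B) = sum_{i in A, j in B} pi_i T_ij / sum_{i in A} pi_i.
    """
    M = _as_matrix(T)
    lumping = np.asarray(lumping, dtype=int)
    n_macro = int(lumping.max()) + 1
    mass = np.bincount(lumping, weights=pi, minlength=n_macro)
    if (mass <= 0).any():
        raise ValueError("every macrostate needs positive stationary mass")
    F = np.zeros((n_macro, n_macro))
    flow = pi[:, None] * M
    np.add.at(F, (lumping[:, None], lumping[None, :]), flow)
    Tm = F / mass[:, None]
    Tm /= Tm.sum(axis=1, keepdims=True)  # absorb float round-off
    if lag is None:
        lag = T.lag if isinstance(T, TransitionMatrix) else 1
    return TransitionMatrix(T=Tm, lag=lag, symmetrized=getattr(T, "symmetrized", False))


def metastability(T, pi: np.ndarray, lumping: np.ndarray) -> float:
    """Sum of macrostate self-transition probabilities (trace of the lumped T)."""
    return float(np.trace(lump_T(T, pi, lumping).T))


def _spectral_vectors(M: np.ndarray, pi: np.ndarray, m: int) -> np.ndarray:
    """Top-m right eigenvectors, using the pi-symmetrized form when reversible."""
    flow = pi[:, None] * M
    if np.abs(flow - flow.T).max() < 1e-8 and (pi > 0).all():
        s = np.sqrt(pi)
        S = (M * s[:, None]) / s[None, :]
        S = 0.5 * (S + S.T)
        w, V = np.linalg.eigh(S)
        order = np.argsort(-w)[:m]
        return V[:, order] / s[:, None]
    w, V = np.linalg.eig(M)
    order = np.argsort(-np.real(w))[:m]
    if np.abs(np.imag(w[order])).max() > 1e-8:
        warnings.warn("non-real dominant eigenvalues; using real parts")
    return np.real(V[:, order])


def _relabel(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters 0..m-1 in order of first appearance (deterministic)."""
    out = np.empty_like(labels)
    mapping = {}
    for i, l in enumerate(labels):
        if l not in mapping:
            mapping[l] = len(mapping)
        out[i] = mapping[l]
    return out


def _pcca_simplex(V: np.ndarray, m: int) -> np.ndarray:
    """Inner-simplex vertex search + max-membership assignment (PCCA+ style)."""
    n = V.shape[0]
    W = V.copy()
    W[:, 0] = 1.0
    verts = [int(np.argmax(np.linalg.norm(W - W.mean(axis=0), axis=1)))]
    B = W - W[verts[0]]
    for _ in range(1, m):
        # project out directions already spanned, take the farthest state
        Q, _ = np.linalg.qr(B[verts].T) if len(verts) > 1 else (np.zeros((m, 0)), None)
        resid = B - B @ Q @ Q.T if Q.shape[1] else B
        verts.append(int(np.argmax(np.linalg.norm(resid, axis=1))))
    A = W[verts]  # (m, m)
    try:
        chi = W @ np.linalg.inv(A)
    except np.linalg.LinAlgError:
        chi = W @ np.linalg.pinv(A)
    labels = np.argmax(chi, axis=1)
    for k, v in enumerate(verts):  # vertices anchor their own cluster
        labels[v] = k
    # guard: absorb any empty cluster by splitting the largest along chi
    for k in range(m):
        if not (labels == k).any():
            labels[int(np.argmax(chi[:, k]))] = k
    return _relabel(labels)


def _pcca_sign(V: np.ndarray, m: int) -> np.ndarray:
    """Classic recursive sign-structure splitting on successive eigenvectors."""
    n = V.shape[0]
    labels = np.zeros(n, dtype=int)
    n_clusters = 1
    for k in range(1, m):
        v = V[:, k]
        # split the cluster with the widest spread along eigenvector k
        spreads = [
            (v[labels == c].max() - v[labels == c].min(), c)
            for c in range(n_clusters)
        ]
        spreads.sort(reverse=True)
        done = False
        for _, c in spreads:
            sel = labels == c
            pos = v > 0
            if (sel & pos).any() and (sel & ~pos).any():
                labels[sel & pos] = n_clusters
                done = True
                break
        if not done:  # deterministic fallback: median split of widest cluster
            _, c = spreads[0]
            sel = labels == c
            med = np.median(v[sel])
            hi = sel & (v > med)
            if hi.any() and (sel & ~hi).any():
                labels[hi] = n_clusters
            else:
                idx = np.flatnonzero(sel)
                labels[idx[np.argmax(v[sel])]] = n_clusters
        n_clusters += 1
    return _relabel(labels)


def pcca(T, n_macro: int, pi: np.ndarray = None, method: str = "simplex") -> MacrostateAssignment:
    """Perron-cluster spectral lumping of microstates into macrostates.

    Groups microstates by the structure of the ``n_macro`` dominant
    eigenvectors of the transition matrix.  ``method="simplex"`` (default)
    assigns by maximum membership after an inner-simplex vertex search;
    ``method="sign"`` is the classic recursive sign-splitting variant.
    """
    M = _as_matrix(T)
    n = M.shape[0]
    if not (1 <= n_macro <= n):
        raise ValueError("n_macro must be in [1, n_states]")
    if pi is None:
        pi = stationary(M)
    active = pi > 0
    if n_macro == n:
        lumping = np.arange(n)
    elif n_macro == 1:
        lumping = np.zeros(n, dtype=int)
    elif active.all():
        V = _spectral_vectors(M, pi, n_macro)
        lumping = _pcca_simplex(V, n_macro) if method == "simplex" else _pcca_sign(V, n_macro)
    else:
        # states outside the stationary support (never sampled) carry no
        # kinetic information: lump the active subchain and attach each
        # inactive state to its most strongly connected active macrostate
        # (falling back to the first macrostate when fully isolated).
        idx = np.flatnonzero(active)
        Ms = M[np.ix_(idx, idx)]
        Ms = Ms / Ms.sum(axis=1, keepdims=True)
        ps = pi[idx] / pi[idx].sum()
        V = _spectral_vectors(Ms, ps, n_macro)
        sub = _pcca_simplex(V, n_macro) if method == "simplex" else _pcca_sign(V, n_macro)
        lumping = np.zeros(n, dtype=int)
        lumping[idx] = sub
        for i in np.flatnonzero(~active):
            link = M[i, idx] + M[idx, i]
            link[idx == i] = 0.0
            lumping[i] = sub[int(np.argmax(link))] if link.max() > 0 else 0
        warnings.warn(
            f"{(~active).sum()} states outside the stationary support were "
            "attached to their nearest active macrostate"
        )
    return MacrostateAssignment(
        lumping=lumping,
        n_macro=n_macro,
        metastability=metastability(M, pi, lumping),
    )


def anneal_lumping(
    T,
    init: MacrostateAssignment,
    pi: np.ndarray = None,
    n_moves: int = None,
    temp_initial: float = 1e-2,
    temp_final: float = 1e-7,
    seed: int = 0,
) -> MacrostateAssignment:
    """Refine a lumping by simulated annealing on metastability.

    Proposes single-microstate reassignments under Metropolis acceptance
    with geometric cooling; moves that would empty a macrostate are
    rejected.  Returns the best assignment ever visited, so the result's
    metastability is never below the initial one.
    """
    M = _as_matrix(T)
    n = M.shape[0]
    m = init.n_macro
    if pi is None:
        pi = stationary(M)
    if n_moves is None:
        n_moves = 50 * n
    rng = np.random.default_rng(seed)

    labels = init.lumping.copy()
    flow = pi[:, None] * M
    F = np.zeros((m, m))
    np.add.at(F, (labels[:, None], labels[None, :]), flow)
    mass = np.bincount(labels, weights=pi, minlength=m)
    sizes = np.bincount(labels, minlength=m)
    obj = float((np.diag(F) / mass).sum())

    best_obj = obj
    best_labels = labels.copy()
    if n_moves > 0 and m > 1:
        cool = (temp_final / temp_initial) ** (1.0 / n_moves)
        temp = temp_initial
        micros = rng.integers(0, n, size=n_moves)
        targets = rng.integers(0, m - 1, size=n_moves)
        accept_u = rng.random(n_moves)
        for step in range(n_moves):
            i = micros[step]
            a = labels[i]
            b = targets[step]
            if b >= a:
                b += 1
            temp *= cool
            if sizes[a] == 1 or mass[a] - pi[i] <= 0:
                continue
            s = flow[i, i]
            fo = np.bincount(labels, weights=flow[i], minlength=m)
            fi = np.bincount(labels, weights=flow[:, i], minlength=m)
            fo[a] -= s
            fi[a] -= s
            Faa = F[a, a] - fo[a] - fi[a] - s
            Fbb = F[b, b] + fo[b] + fi[b] + s
            delta = (
                Faa / (mass[a] - pi[i]) - F[a, a] / mass[a]
                + Fbb / (mass[b] + pi[i]) - F[b, b] / mass[b]
            )
            if delta <= 0 and accept_u[step] >= np.exp(delta / max(temp, 1e-300)):
                continue
            F[a, :] -= fo
            F[b, :] += fo
            F[:, a] -= fi
            F[:, b] += fi
            F[a, a] -= s
            F[b, b] += s
            mass[a] -= pi[i]
            mass[b] += pi[i]
            sizes[a] -= 1
            sizes[b] += 1
            labels[i] = b
            obj += delta
            if obj > best_obj:
                best_obj = obj
                best_labels = labels.copy()
    return MacrostateAssignment(
        lumping=_relabel(best_labels),
        n_macro=m,
        metastability=metastability(M, pi, _relabel(best_labels)),
    )
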