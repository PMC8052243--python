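"""Hidden Markov models over microstate observations.

The M-macrostate HMM treats the PCCA metastable states as hidden states
emitting k-means microstates.  Estimation is Baum-Welch (EM with the scaled
forward-backward recursions) on lag-subsampled label sequences: every
lag-th frame is kept and all offsets are pooled as independent chains, so
the hidden transition matrix A is the macrostate transition probability at
the model lag.  Stationary populations are the left Perron eigenvector of
A; transition rates default to the first-order estimate K_ij = A_ij / tau
(valid when A_ij << 1) with a generator-matrix (matrix logarithm) estimate
available behind ``method="logm"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import logm
from scipy.optimize import linear_sum_assignment
from scipy.sparse.csgraph import connected_components

from .msm import MetastableSets, TransitionModel

try:
    from numba import njit as _njit
    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def deco(f):
            return f
        return deco

__all__ = [
    "MacrostateModel",
    "fit_hmm",
    "macrostate_populations",
    "transition_rates",
    "posterior_decode",
    "match_states_to_basins",
]


@dataclass
class MacrostateModel:
    """Baum-Welch estimate of the macrostate HMM at a lag.

    ``transition_matrix`` (A, M x M) and ``emission_matrix`` (B, M x n) are
    row-stochastic; ``initial`` is the estimated chain-start distribution.
    """

    lag_ns: float
    transition_matrix: np.ndarray
    emission_matrix: np.ndarray
    initial: np.ndarray
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int

    @property
    def n_macrostates(self) -> int:
        return self.transition_matrix.shape[0]

    @property
    def n_microstates(self) -> int:
        return self.emission_matrix.shape[1]


def _chains_from_labels(labels_per_replica, lag: int):
    """Lag-subsample each replica at every offset; pool as independent chains."""
    chains = []
    for lab in labels_per_replica:
        lab = np.asarray(lab, dtype=int)
        for off in range(lag):
            c = lab[off::lag]
            if len(c) >= 2:
                chains.append(c)
    if not chains:
        raise ValueError("no chain of length >= 2 after lag subsampling")
    return chains


def _group_by_length(chains):
    groups = {}
    for c in chains:
        groups.setdefault(len(c), []).append(c)
    return {L: np.vstack(cs) for L, cs in groups.items()}


def _em_pass(obs: np.ndarray, A: np.ndarray, Bm: np.ndarray, init: np.ndarray):
    """One scaled forward-backward pass over a batch of equal-length chains.

    Returns (loglik, xi_sum, emission_counts, gamma0_sum) sufficient
    statistics summed over the batch.
    """
    n_chains, T = obs.shape
    M = A.shape[0]
    pe = Bm.T[obs]                     # (n_chains, T, M)

    alpha = np.empty((n_chains, T, M))
    c = np.empty((n_chains, T))
    a = init[np.newaxis, :] * pe[:, 0, :]
    c[:, 0] = a.sum(axis=1)
    alpha[:, 0, :] = a / c[:, 0, np.newaxis]
    for t in range(1, T):
        a = (alpha[:, t - 1, :] @ A) * pe[:, t, :]
        c[:, t] = a.sum(axis=1)
        alpha[:, t, :] = a / c[:, t, np.newaxis]
    loglik = float(np.log(c).sum())

    xi_sum = np.zeros((M, M))
    emit = np.zeros((Bm.shape[1], M))
    beta = np.ones((n_chains, M))
    gamma = alpha[:, T - 1, :] * beta
    np.add.at(emit, obs[:, T - 1], gamma)
    for t in range(T - 2, -1, -1):
        tmp = pe[:, t + 1, :] * beta / c[:, t + 1, np.newaxis]
        xi_sum += (alpha[:, t, :].T @ tmp) * A
        beta = tmp @ A.T
        gamma = alpha[:, t, :] * beta
        np.add.at(emit, obs[:, t], gamma)
    gamma0 = (alpha[:, 0, :] * beta).sum(axis=0)
    return loglik, xi_sum, emit.T, gamma0


@_njit(cache=True)
def _em_pass_compiled(obs, A, Bm, init):  # pragma: no cover - numba kernel
    """Per-chain scaled forward-backward; numerically identical statistics
    to :func:`_em_pass` (cross-checked in the test suite)."""
    n_chains, T = obs.shape
    M = A.shape[0]
    n_sym = Bm.shape[1]
    ll = 0.0
    xi = np.zeros((M, M))
    emit = np.zeros((M, n_sym))
    g0 = np.zeros(M)
    alpha = np.empty((T, M))
    c = np.empty(T)
    beta = np.empty(M)
    tmp = np.empty(M)
    for b in range(n_chains):
        s = 0.0
        for i in range(M):
            alpha[0, i] = init[i] * Bm[i, obs[b, 0]]
            s += alpha[0, i]
        c[0] = s
        for i in range(M):
            alpha[0, i] /= s
        for t in range(1, T):
            o = obs[b, t]
            s = 0.0
            for j in range(M):
                acc = 0.0
                for i in range(M):
                    acc += alpha[t - 1, i] * A[i, j]
                alpha[t, j] = acc * Bm[j, o]
                s += alpha[t, j]
            c[t] = s
            for j in range(M):
                alpha[t, j] /= s
        for t in range(T):
            ll += np.log(c[t])
        for i in range(M):
            beta[i] = 1.0
            emit[i, obs[b, T - 1]] += alpha[T - 1, i]
        for t in range(T - 2, -1, -1):
            o = obs[b, t + 1]
            for j in range(M):
                tmp[j] = Bm[j, o] * beta[j] / c[t + 1]
            for i in range(M):
                acc = 0.0
                for j in range(M):
                    xi[i, j] += alpha[t, i] * A[i, j] * tmp[j]
                    acc += A[i, j] * tmp[j]
                beta[i] = acc
            o = obs[b, t]
            for i in range(M):
                emit[i, o] += alpha[t, i] * beta[i]
        for i in range(M):
            g0[i] += alpha[0, i] * beta[i]
    return ll, xi, emit, g0


def _run_em_pass(obs, A, Bm, init, use_compiled=True):
    if _HAVE_NUMBA and use_compiled:
        ll, xi, emit, g0 = _em_pass_compiled(
            np.ascontiguousarray(obs, dtype=np.int64), A, Bm, init)
        return ll, xi, emit, g0
    return _em_pass(obs, A, Bm, init)


def _init_from_metastable(labels_per_replica, lag, sets: MetastableSets,
                          n_symbols, pseudocount):
    """Initial (A, B, init) from crisp PCCA macrostate labels."""
    M = sets.n_macrostates
    A = np.zeros((M, M))
    B = np.full((M, n_symbols), pseudocount)
    init = np.zeros(M)
    for lab in labels_per_replica:
        macro = sets.crisp[np.asarray(lab, dtype=int)]
        np.add.at(A, (macro[:-lag], macro[lag:]), 1)
        np.add.at(B.T, np.asarray(lab, dtype=int), np.eye(M)[macro])
        init[macro[0]] += 1
    A += pseudocount
    A /= A.sum(axis=1, keepdims=True)
    B /= B.sum(axis=1, keepdims=True)
    init = (init + 1e-12) / (init + 1e-12).sum()
    return A, B, init


def fit_hmm(labels_per_replica, n_macrostates: int, lag_frames: int,
            lag_ns: float | None = None, init: MetastableSets | None = None,
            tol: float = 1e-6, max_iter: int = 500,
            pseudocount: float = 1e-8, seed: int | None = None,
            rel_a_tol: float = 1e-3, b_warmup: int = 10) -> MacrostateModel:
    """Baum-Welch estimation of the macrostate HMM.

    The first ``b_warmup`` iterations update only the emission matrix with
    A frozen (a generalized-EM schedule, still monotone in likelihood):
    the crisp warm start inflates the rare-transition entries of A through
    misclassified frames, and sharpening B first removes the shallow
    saddle that EM otherwise has to drift through.  ``tol`` is the
    per-frame log-likelihood improvement below which the joint phase is
    considered converged; because rare-transition entries can still move
    while the likelihood gain per frame is tiny, convergence additionally
    requires the transition matrix to be stationary
    (max |dA_ij| / A_ij < ``rel_a_tol`` over the last M-step).  ``init``
    supplies the PCCA warm start; without it, emissions are randomized
    from ``seed``.  Non-convergence warns and still returns the model with
    diagnostics.
    """
    labels_per_replica = [np.asarray(l, dtype=int) for l in labels_per_replica]
    n_symbols = max(int(l.max()) for l in labels_per_replica) + 1
    M = int(n_macrostates)
    if M < 1:
        raise ValueError("need at least one macrostate")
    if M > n_symbols:
        raise ValueError("more macrostates than observed microstates")

    chains = _chains_from_labels(labels_per_replica, int(lag_frames))
    groups = _group_by_length(chains)
    n_obs = sum(len(c) for c in chains)
    if lag_ns is None:
        lag_ns = float(lag_frames)

    if init is not None:
        A, B, pi0 = _init_from_metastable(labels_per_replica, int(lag_frames),
                                          init, n_symbols, pseudocount)
    else:
        rng = np.random.default_rng(seed)
        A = np.full((M, M), 0.1 / max(M - 1, 1)) + np.eye(M) * (0.9 - 0.1 / max(M - 1, 1))
        A /= A.sum(axis=1, keepdims=True)
        B = rng.random((M, n_symbols)) + 0.1
        B /= B.sum(axis=1, keepdims=True)
        pi0 = np.full(M, 1.0 / M)

    trace = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        ll = 0.0
        xi_sum = np.zeros((M, M))
        emit = np.zeros((M, n_symbols))
        gamma0 = np.zeros(M)
        for obs in groups.values():
            ll_g, xi_g, emit_g, g0 = _run_em_pass(obs, A, B, pi0)
            ll += ll_g
            xi_sum += xi_g
            emit += emit_g
            gamma0 += g0
        trace.append(ll)
        B = emit + pseudocount
        B /= B.sum(axis=1, keepdims=True)
        if n_iter <= b_warmup:
            continue           # emission-only phase: A and pi0 stay fixed
        A_new = xi_sum + pseudocount
        A_new /= A_new.sum(axis=1, keepdims=True)
        dA = np.max(np.abs(A_new - A) / np.maximum(A, 1e-5))
        A = A_new
        pi0 = gamma0 / gamma0.sum()
        if (n_iter > b_warmup + 1
                and (trace[-1] - trace[-2]) / n_obs < tol
                and dA < rel_a_tol):
            converged = True
            break
    if not converged:
        warnings.warn(
            f"Baum-Welch did not converge in {n_iter} iterations "
            f"(last per-frame improvement "
            f"{(trace[-1] - trace[-2]) / n_obs:.2e})", RuntimeWarning)
    return MacrostateModel(lag_ns=float(lag_ns), transition_matrix=A,
                           emission_matrix=B, initial=pi0,
                           loglik_trace=np.asarray(trace),
                           converged=converged, n_iter=n_iter)


def macrostate_populations(model: MacrostateModel, tol: float = 1e-12
                           ) -> np.ndarray:
    """Stationary macrostate populations: left Perron eigenvector of A."""
    A = model.transition_matrix
    n_comp, comp = connected_components((A > tol).astype(int), directed=True,
                                        connection="strong")
    if n_comp > 1:
        groups = [list(np.flatnonzero(comp == k)) for k in range(n_comp)]
        raise ValueError(f"hidden transition matrix is reducible: {groups}")
    evals, evecs = np.linalg.eig(A.T)
    k = int(np.argmax(evals.real))
    pi = np.abs(evecs[:, k].real)
    return pi / pi.sum()


def transition_rates(model: MacrostateModel, method: str = "ratio"
                     ) -> np.ndarray:
    """Macrostate rate matrix K (us^-1) from the HMM transition matrix.

    ``method="ratio"`` uses the first-order estimate K_ij = A_ij / tau for
    i != j (diagonal = minus row sum), accurate when transition
    probabilities per lag are small.  ``method="logm"`` returns the full
    generator estimate logm(A) / tau, falling back to the ratio estimate
    with a warning when the matrix logarithm is not a valid generator.
    """
    A = model.transition_matrix
    tau_us = model.lag_ns * 1e-3
    if method == "ratio":
        K = A / tau_us
        np.fill_diagonal(K, 0.0)
        np.fill_diagonal(K, -K.sum(axis=1))
        return K
    if method != "logm":
        raise ValueError("method must be 'ratio' or 'logm'")
    L = logm(A)
    scale = max(1.0, float(np.max(np.abs(L))))
    if np.max(np.abs(np.imag(L))) > 1e-8 * scale:
        warnings.warn("matrix logarithm is not real; falling back to the "
                      "ratio estimate", RuntimeWarning)
        return transition_rates(model, method="ratio")
    K = np.real(L) / tau_us
    off = K - np.diag(np.diag(K))
    if np.min(off) < -1e-6 * scale / tau_us:
        warnings.warn("matrix logarithm has negative off-diagonal rates; "
                      "falling back to the ratio estimate", RuntimeWarning)
        return transition_rates(model, method="ratio")
    K = np.clip(off, 0.0, None)
    np.fill_diagonal(K, -K.sum(axis=1))
    return K


def posterior_decode(model: MacrostateModel, labels_per_replica,
                     lag_frames: int, viterbi: bool = False):
    """Per-frame macrostate assignment from the fitted HMM.

    Each lag-subsampled chain is decoded independently and the results are
    re-interleaved to frame order.  By default returns the posterior
    probabilities (forward-backward smoothing, one (n_frames, M) array per
    replica); with ``viterbi=True`` returns the most probable state paths
    instead.
    """
    A = model.transition_matrix
    B = model.emission_matrix
    init = model.initial
    M = A.shape[0]
    out = []
    for lab in labels_per_replica:
        lab = np.asarray(lab, dtype=int)
        n = len(lab)
        result = np.empty(n, dtype=int) if viterbi else np.empty((n, M))
        for off in range(lag_frames):
            obs = lab[off::lag_frames]
            if len(obs) == 0:
                continue
            if viterbi:
                result[off::lag_frames] = _viterbi_chain(obs, A, B, init)
            else:
                result[off::lag_frames] = _smoothed_chain(obs, A, B, init)
        out.append(result)
    return out


def _smoothed_chain(obs, A, Bm, init):
    """Forward-backward posterior state probabilities for one chain."""
    T = len(obs)
    M = A.shape[0]
    pe = Bm.T[obs]
    alpha = np.empty((T, M))
    c = np.empty(T)
    a = init * pe[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * pe[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    gamma = np.empty((T, M))
    beta = np.ones(M)
    gamma[T - 1] = alpha[T - 1]
    for t in range(T - 2, -1, -1):
        beta = ((pe[t + 1] * beta) / c[t + 1]) @ A.T
        g = alpha[t] * beta
        gamma[t] = g / g.sum()
    return gamma


def _viterbi_chain(obs, A, Bm, init):
    tiny = 1e-300
    logA = np.log(A + tiny)
    logB = np.log(Bm + tiny)
    T = len(obs)
    M = A.shape[0]
    delta = np.log(init + tiny) + logB[:, obs[0]]
    back = np.zeros((T, M), dtype=int)
    for t in range(1, T):
        scores = delta[:, np.newaxis] + logA
        back[t] = np.argmax(scores, axis=0)
        delta = scores[back[t], np.arange(M)] + logB[:, obs[t]]
    path = np.empty(T, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    return path


def match_states_to_basins(model: MacrostateModel,
                           microstate_centers: np.ndarray,
                           basin_centers: np.ndarray) -> np.ndarray:
    """Map recovered macrostates to reference basins by emission location.

    Each hidden state's mean emission position is the B-weighted average of
    its microstate centers (circular mean for theta_r); states are matched
    to basin centers by minimum-cost assignment with a periodic theta_r
    metric.  Returns ``mapping`` with ``mapping[hidden_state] = basin``.
    """
    B = model.emission_matrix
    centers = np.asarray(microstate_centers, dtype=float)
    theta_t = B @ centers[:, 0]
    rad = np.radians(centers[:, 1])
    theta_r = np.degrees(np.arctan2(B @ np.sin(rad), B @ np.cos(rad)))
    est = np.column_stack([theta_t, theta_r])

    ref = np.asarray(basin_centers, dtype=float)
    dt = est[:, 0][:, np.newaxis] - ref[:, 0][np.newaxis, :]
    dr = est[:, 1][:, np.newaxis] - ref[:, 1][np.newaxis, :]
    dr = (dr + 180.0) % 360.0 - 180.0
    cost = dt ** 2 + dr ** 2
    rows, cols = linear_sum_assignment(cost)
    mapping = np.empty(len(rows), dtype=int)
    mapping[rows] = cols
    return mapping
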