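"""Markov state models over (theta_t, theta_r) microstates.

Workflow: k-means discretization of the two-angle space (400 microstates by
default), sliding-window transition counts at a lag time, ergodic trimming
to the largest strongly connected set, reversible maximum-likelihood
transition-matrix estimation, implied timescales t_i = -tau / ln lambda_i,
and PCCA+ coarse-graining into metastable macrostates.

The rotation angle is periodic, so clustering operates on the embedding
(theta_t, s cos theta_r, s sin theta_r) with s = 180/pi, which maps small
periodic distances in theta_r to comparable Euclidean distances in degrees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans

__all__ = [
    "MicrostateAssignment",
    "TransitionModel",
    "TimescaleSpectrum",
    "MetastableSets",
    "kmeans_discretize",
    "count_matrix",
    "estimate_transition_matrix",
    "implied_timescales",
    "timescales_at_lag",
    "pcca",
    "select_n_macrostates",
]

#: Degrees-equivalent scale of the periodic embedding.
PERIODIC_SCALE = 180.0 / np.pi


def _embed(angles: np.ndarray) -> np.ndarray:
    """Map (theta_t, theta_r) in degrees to the periodic-safe 3D embedding."""
    theta_t = angles[:, 0]
    theta_r = np.radians(angles[:, 1])
    return np.column_stack([theta_t,
                            PERIODIC_SCALE * np.cos(theta_r),
                            PERIODIC_SCALE * np.sin(theta_r)])


@dataclass
class MicrostateAssignment:
    """k-means microstate definition and per-replica frame labels."""

    centers: np.ndarray          # (k, 2) in (theta_t, theta_r) degrees
    centers_embedded: np.ndarray  # (k, 3) in embedding space
    labels: list                 # one int array per replica
    n_clusters: int
    seed: int | None = None

    def all_labels(self) -> np.ndarray:
        return np.concatenate(self.labels)


def kmeans_discretize(trajectories, n_clusters: int = 400,
                      seed: int | None = None,
                      max_fit_samples: int = 200_000) -> MicrostateAssignment:
    """Cluster the angle space into microstates with k-means.

    k-means (k-means++ initialization, fixed seed) is fit on at most
    ``max_fit_samples`` randomly chosen frames — a standard cost-control for
    multi-million-frame trajectories — and all frames are then assigned to
    the nearest center.  Empty clusters are dropped with relabeling.
    """
    trajectories = list(trajectories)
    X_parts = [_embed(t.angles()) for t in trajectories]
    X = np.vstack(X_parts)
    if len(X) < n_clusters:
        raise ValueError(
            f"need at least {n_clusters} frames, got {len(X)}")

    rng = np.random.default_rng(seed)
    if len(X) > max_fit_samples:
        fit_idx = rng.choice(len(X), size=max_fit_samples, replace=False)
        X_fit = X[fit_idx]
    else:
        X_fit = X
    km = KMeans(n_clusters=n_clusters, init="k-means++", n_init=1,
                random_state=int(rng.integers(2**31 - 1)))
    km.fit(X_fit)

    centers = km.cluster_centers_
    labels = [_assign_chunked(part, centers) for part in X_parts]

    # drop empty clusters and relabel contiguously
    used = np.unique(np.concatenate(labels))
    remap = -np.ones(n_clusters, dtype=int)
    remap[used] = np.arange(len(used))
    labels = [remap[lab] for lab in labels]
    centers = centers[used]
    theta_r = np.degrees(np.arctan2(centers[:, 2], centers[:, 1]))
    centers_angles = np.column_stack([centers[:, 0], theta_r])
    return MicrostateAssignment(centers=centers_angles,
                                centers_embedded=centers,
                                labels=labels, n_clusters=len(used),
                                seed=seed)


def _assign_chunked(X, centers, chunk=200_000):
    out = np.empty(len(X), dtype=int)
    sq = (centers ** 2).sum(axis=1)
    for start in range(0, len(X), chunk):
        block = X[start:start + chunk]
        d = sq[np.newaxis, :] - 2.0 * block @ centers.T
        out[start:start + chunk] = np.argmin(d, axis=1)
    return out


# ---------------------------------------------------------------------------
# counting and estimation
# ---------------------------------------------------------------------------

def count_matrix(labels_per_replica, lag: int, n_states: int | None = None
                 ) -> np.ndarray:
    """Sliding-window transition counts at an integer lag (frames).

    C_ij counts pairs (s_t = i, s_{t+lag} = j) within each replica; counts
    never cross replica boundaries.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1 frame")
    seqs = [np.asarray(lab, dtype=int) for lab in labels_per_replica]
    if any(len(s) <= lag for s in seqs):
        raise ValueError("lag must be shorter than every replica")
    if n_states is None:
        n_states = max(int(s.max()) for s in seqs) + 1
    C = np.zeros((n_states, n_states), dtype=np.int64)
    for s in seqs:
        np.add.at(C, (s[:-lag], s[lag:]), 1)
    return C


@dataclass
class TransitionModel:
    """Estimated transition matrix restricted to the ergodic active set."""

    lag_ns: float
    counts: np.ndarray           # counts on the active set
    transition_matrix: np.ndarray
    active_set: np.ndarray       # original state indices
    stationary: np.ndarray
    reversible: bool = True

    @property
    def n_states(self) -> int:
        return len(self.active_set)


def _largest_strong_component(C: np.ndarray) -> np.ndarray:
    n_comp, comp = connected_components((C > 0).astype(int), directed=True,
                                        connection="strong")
    sizes = np.bincount(comp)
    # tie-break toward the component with the most counts
    if (sizes == sizes.max()).sum() > 1:
        weights = np.zeros(n_comp)
        for k in range(n_comp):
            idx = np.flatnonzero(comp == k)
            weights[k] = C[np.ix_(idx, idx)].sum()
        best = int(np.argmax(np.where(sizes == sizes.max(), weights, -1)))
    else:
        best = int(np.argmax(sizes))
    return np.flatnonzero(comp == best)


def estimate_transition_matrix(counts: np.ndarray, reversible: bool = True,
                               lag_ns: float = 0.0, tol: float = 1e-10,
                               max_iter: int = 1_000_000) -> TransitionModel:
    """Maximum-likelihood transition matrix from a count matrix.

    The estimate is restricted to the largest strongly connected component
    of the count graph.  The reversible estimator solves the
    detailed-balance-constrained likelihood by the standard self-consistent
    fixed-point iteration on the unnormalized symmetric flux matrix
    x_ij = (c_ij + c_ji) / (c_i / x_i + c_j / x_j), converged when the
    transition matrix changes by less than ``tol`` elementwise.  The
    non-reversible estimate is plain row normalization.
    """
    C = np.asarray(counts, dtype=float)
    active = _largest_strong_component(C)
    if len(active) == 0:
        raise ValueError("empty active set")
    C = C[np.ix_(active, active)]

    if not reversible:
        rows = C.sum(axis=1)
        T = C / rows[:, np.newaxis]
        evals, evecs = np.linalg.eig(T.T)
        k = int(np.argmax(evals.real))
        pi = np.abs(evecs[:, k].real)
        pi /= pi.sum()
    else:
        c_sym = C + C.T
        c_row = C.sum(axis=1)
        x = c_sym.copy()
        T_prev = x / x.sum(axis=1, keepdims=True)
        for _ in range(max_iter):
            x_row = x.sum(axis=1)
            q = c_row / x_row
            denom = q[:, np.newaxis] + q[np.newaxis, :]
            with np.errstate(invalid="ignore", divide="ignore"):
                x = np.where(c_sym > 0, c_sym / denom, 0.0)
            T = x / x.sum(axis=1, keepdims=True)
            if np.max(np.abs(T - T_prev)) < tol:
                break
            T_prev = T
        else:
            warnings.warn("reversible MLE did not reach tolerance", RuntimeWarning)
        x_row = x.sum(axis=1)
        pi = x_row / x_row.sum()

    return TransitionModel(lag_ns=lag_ns, counts=C.astype(np.int64),
                           transition_matrix=T, active_set=active,
                           stationary=pi, reversible=reversible)


# ---------------------------------------------------------------------------
# spectral analysis
# ---------------------------------------------------------------------------

@dataclass
class TimescaleSpectrum:
    """Implied timescales t_i = -tau / ln lambda_i over a ladder of lags."""

    lags_ns: np.ndarray
    eigenvalues: list            # one descending |lambda| array per lag
    timescales: list             # matching arrays in ns (inf marker allowed)

    def at_lag(self, lag_ns: float) -> np.ndarray:
        k = int(np.argmin(np.abs(self.lags_ns - lag_ns)))
        return self.timescales[k]


def _sorted_eigenvalues(model: TransitionModel, k: int | None = None,
                        imag_tol: float = 1e-8) -> np.ndarray:
    T = model.transition_matrix
    if model.reversible:
        # symmetrize with the stationary distribution for a stable real spectrum
        pi = model.stationary
        sqrt_pi = np.sqrt(pi)
        S = sqrt_pi[:, np.newaxis] * T / sqrt_pi[np.newaxis, :]
        S = 0.5 * (S + S.T)
        evals = np.linalg.eigvalsh(S)
    else:
        evals = np.linalg.eigvals(T)
        if np.max(np.abs(evals.imag)) > imag_tol * max(1.0, np.max(np.abs(evals))):
            evals = np.abs(evals)
        else:
            evals = evals.real
    order = np.argsort(np.abs(evals))[::-1]
    evals = evals[order]
    return evals if k is None else evals[:k]


def timescales_at_lag(model: TransitionModel, n_timescales: int | None = None,
                      imag_tol: float = 1e-8) -> np.ndarray:
    """Implied timescales (ns) of one model, excluding the stationary process.

    Non-positive or unit-modulus eigenvalues map to 0 and inf respectively.
    On reversible models, eigenvalues with imaginary parts beyond
    ``imag_tol`` would indicate a symmetrization defect and raise.
    """
    if model.n_states < 2:
        raise ValueError("need at least 2 states in the active set")
    if model.reversible:
        # eigvalsh of the pi-symmetrized matrix is real by construction;
        # verify the model is actually reversible before trusting it
        pi = model.stationary
        flux = pi[:, np.newaxis] * model.transition_matrix
        if np.max(np.abs(flux - flux.T)) > 1e-6:
            raise ValueError("model flagged reversible violates detailed balance")
    evals = _sorted_eigenvalues(model, imag_tol=imag_tol)[1:]
    if n_timescales is not None:
        evals = evals[:n_timescales]
    tau = model.lag_ns
    ts = np.full(len(evals), np.inf)
    mod = np.abs(evals)
    with np.errstate(divide="ignore"):
        valid = (mod > 0) & (mod < 1)
        ts[valid] = -tau / np.log(mod[valid])
        ts[mod <= 0] = 0.0
    return ts


def implied_timescales(labels_per_replica, lags_frames, stride_ns: float,
                       n_states: int | None = None, reversible: bool = True,
                       n_timescales: int = 10) -> TimescaleSpectrum:
    """Implied-timescale spectrum over a ladder of lags."""
    lags_ns, evs, tss = [], [], []
    for lag in lags_frames:
        C = count_matrix(labels_per_replica, lag, n_states=n_states)
        model = estimate_transition_matrix(C, reversible=reversible,
                                           lag_ns=lag * stride_ns)
        ts = timescales_at_lag(model, n_timescales=n_timescales)
        lags_ns.append(lag * stride_ns)
        evs.append(_sorted_eigenvalues(model, k=n_timescales + 1))
        tss.append(ts)
    return TimescaleSpectrum(lags_ns=np.asarray(lags_ns),
                             eigenvalues=evs, timescales=tss)


# ---------------------------------------------------------------------------
# PCCA+
# ---------------------------------------------------------------------------

@dataclass
class MetastableSets:
    """Fuzzy PCCA+ memberships and crisp macrostate labels."""

    memberships: np.ndarray      # (n, M), rows sum to 1
    crisp: np.ndarray            # argmax labels, (n,)
    n_macrostates: int

    def macrostate_of(self, microstate_labels: np.ndarray) -> np.ndarray:
        return self.crisp[microstate_labels]


def pcca(model: TransitionModel, n_macrostates: int) -> MetastableSets:
    """PCCA+ metastable memberships from the dominant eigenvectors.

    Uses the inner-simplex vertex construction of Deuflhard & Weber: the
    first M pi-orthonormal right eigenvectors span a simplex whose vertices
    are identified by successive orthogonal deflation; memberships are the
    barycentric coordinates, clipped of numerically tiny negatives and
    renormalized.
    """
    M = int(n_macrostates)
    n = model.n_states
    if M > n:
        raise ValueError("more macrostates than active microstates")
    if not model.reversible:
        raise ValueError("PCCA+ requires a reversible model")
    if M == 1:
        return MetastableSets(memberships=np.ones((n, 1)),
                              crisp=np.zeros(n, dtype=int), n_macrostates=1)

    pi = model.stationary
    sqrt_pi = np.sqrt(pi)
    S = sqrt_pi[:, np.newaxis] * model.transition_matrix / sqrt_pi[np.newaxis, :]
    S = 0.5 * (S + S.T)
    evals, evecs = np.linalg.eigh(S)
    order = np.argsort(evals)[::-1]
    psi = evecs[:, order[:M]] / sqrt_pi[:, np.newaxis]
    # normalize sign/scale so psi[:, 0] is the constant vector
    psi = psi / psi[0, 0]
    psi[:, 0] = 1.0

    # inner-simplex vertex search
    vertices = np.zeros(M, dtype=int)
    ortho = psi.copy()
    vertices[0] = int(np.argmax(np.linalg.norm(ortho, axis=1)))
    v0 = ortho[vertices[0]].copy()
    ortho -= v0[np.newaxis, :]
    for k in range(1, M):
        norms = np.linalg.norm(ortho, axis=1)
        vertices[k] = int(np.argmax(norms))
        vk = ortho[vertices[k]] / norms[vertices[k]]
        ortho -= np.outer(ortho @ vk, vk)

    A = np.linalg.inv(psi[vertices])
    chi = psi @ A
    chi = np.clip(chi, 0.0, None)
    row = chi.sum(axis=1)
    if np.any(row <= 0):
        raise RuntimeError("PCCA+ produced an empty membership row")
    chi /= row[:, np.newaxis]
    crisp = np.argmax(chi, axis=1)
    if len(np.unique(crisp)) < M:
        raise RuntimeError("PCCA+ produced an empty macrostate under crisp "
                           "assignment; reduce the number of macrostates")
    return MetastableSets(memberships=chi, crisp=crisp, n_macrostates=M)


def select_n_macrostates(timescales, lag_ns: float) -> int:
    """Number of metastable states from the largest timescale gap.

    The stationary process counts as the first (infinite) timescale; with
    the finite spectrum sorted descending, the largest ratio t_k / t_{k+1}
    after k resolved timescales (t_k above the lag) yields M = k + 1
    macrostates.  Ties break toward smaller M; if no finite timescale
    exceeds the lag, M = 1 with a warning.
    """
    ts = np.asarray(timescales, dtype=float)
    ts = ts[np.isfinite(ts) & (ts > 0)]
    ts = np.sort(ts)[::-1]
    n_resolved = int((ts > lag_ns).sum())
    if n_resolved == 0:
        warnings.warn("no implied timescale above the lag; M = 1", RuntimeWarning)
        return 1
    # gap candidates: after the (k+1)-th resolved timescale, the denominator
    # may be the first unresolved one
    max_k = min(n_resolved, len(ts) - 1)
    if max_k == 0:
        return 2
    ratios = ts[:max_k] / ts[1:max_k + 1]
    k = int(np.argmax(ratios))  # first occurrence wins -> smaller M on ties
    return k + 2
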