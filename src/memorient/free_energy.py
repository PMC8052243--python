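"""Free-energy estimators for orientational and desorption coordinates.

Four estimators are provided:

* a 2D Boltzmann histogram over (theta_t, theta_r),
  F = -k_B T ln(H / H_max), with empty bins flagged rather than imputed;
* WHAM for harmonic umbrella windows (binned self-consistent iteration)
  with three-block convergence assessment;
* well-tempered metadynamics bookkeeping: Gaussian deposition with the
  height rule W(k tau) = W0 exp(-V(s, k tau) / (k_B DeltaT)), bias factor
  gamma = (T + DeltaT)/T, and the asymptotic surface estimate
  F(s) = -(gamma / (gamma - 1)) V_G(s);
* the parallel-tempering metadynamics exchange rule
  Delta = Delta_PT + beta_i [V_G^i(s_i) - V_G^i(s_j)]
               + beta_j [V_G^j(s_j) - V_G^j(s_i)],
  with acceptance min(1, e^Delta), which preserves detailed balance of the
  extended (replica x bias) ensemble.

Energies are in kJ/mol, distances in nm, temperatures in K.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import KB, DEFAULT_TEMPERATURE

__all__ = [
    "FreeEnergySurface",
    "UmbrellaWindowSet",
    "BiasPotentialState",
    "ReplicaState",
    "boltzmann_fes_2d",
    "wham",
    "block_convergence",
    "wt_metad_update",
    "wt_metad_fes",
    "ptmetad_acceptance",
]


@dataclass
class FreeEnergySurface:
    """Binned free energy with empty bins flagged as NaN."""

    edges: list                  # one bin-edge array per CV
    F: np.ndarray                # kJ/mol, NaN on empty bins, min over occupied = 0
    counts: np.ndarray
    temperature: float

    @property
    def bin_centers(self) -> list:
        return [0.5 * (e[1:] + e[:-1]) for e in self.edges]

    def occupied_min(self) -> float:
        return float(np.nanmin(self.F))


def boltzmann_fes_2d(trajectories, bins=(70, 70),
                     temperature: float = DEFAULT_TEMPERATURE,
                     ranges=((0.0, 180.0), (-180.0, 180.0))
                     ) -> FreeEnergySurface:
    """Boltzmann-histogram free-energy surface over (theta_t, theta_r).

    F(bin) = -k_B T ln(H / H_max); the minimum over occupied bins is zero
    by construction and empty bins carry NaN.
    """
    trajectories = list(trajectories)
    if not trajectories or all(len(t) == 0 for t in trajectories):
        raise ValueError("need at least one frame")
    angles = np.vstack([t.angles() for t in trajectories])
    H, ex, ey = np.histogram2d(angles[:, 0], angles[:, 1], bins=bins,
                               range=ranges)
    kT = KB * temperature
    with np.errstate(divide="ignore"):
        F = -kT * np.log(H / H.max())
    F[H == 0] = np.nan
    return FreeEnergySurface(edges=[ex, ey], F=F, counts=H,
                             temperature=temperature)


# ---------------------------------------------------------------------------
# umbrella sampling / WHAM
# ---------------------------------------------------------------------------

@dataclass
class UmbrellaWindowSet:
    """Biased samples from harmonic umbrella windows along one coordinate."""

    centers: np.ndarray          # nm
    k_spring: float              # kJ mol^-1 nm^-2
    temperature: float
    samples: list                # one sample array per window

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=float)
        if self.k_spring <= 0:
            raise ValueError("spring constant must be positive")
        if len(self.samples) != len(self.centers):
            raise ValueError("one sample array per window required")
        self.samples = [np.asarray(s, dtype=float) for s in self.samples]
        if any(len(s) < 1 for s in self.samples):
            raise ValueError("every window needs at least one sample")


def wham(windows: UmbrellaWindowSet, n_bins: int | None = None,
         tol: float = 1e-11, max_iter: int = 1_000_000):
    """Weighted-histogram PMF from umbrella windows.

    Standard binned WHAM self-consistency: with histogram counts n_ib and
    per-window free-energy offsets f_i,

        P_b propto (sum_i n_ib) / (sum_i N_i exp[(f_i - U_i(b)) / kT]),
        f_i = -kT ln sum_b P_b exp(-U_i(b) / kT),

    iterated until max |Delta f_i| < tol.  Convergence of the fixed point
    is geometric with a rate close to one for many-window sets, so the
    per-iteration change understates the distance to the solution; the
    default tolerance is therefore far below the kJ/mol scale of interest.
    The default bin width is one fifth of the window spacing.  Returns (bin_centers, pmf, offsets); the
    PMF is shifted so its minimum is zero.  Raises when adjacent windows do
    not overlap (naming the gap).
    """
    kT = KB * windows.temperature
    order = np.argsort(windows.centers)
    centers = windows.centers[order]
    samples = [windows.samples[i] for i in order]

    lo = min(s.min() for s in samples)
    hi = max(s.max() for s in samples)
    if n_bins is None:
        spacing = np.min(np.diff(centers)) if len(centers) > 1 else (hi - lo)
        n_bins = max(int(np.ceil((hi - lo) / (spacing / 5.0))), 10)
    edges = np.linspace(lo, hi, n_bins + 1)
    mids = 0.5 * (edges[1:] + edges[:-1])

    hist = np.array([np.histogram(s, bins=edges)[0] for s in samples],
                    dtype=float)                       # (W, B)
    # overlap check between adjacent windows
    for i in range(len(centers) - 1):
        if not np.any((hist[i] > 0) & (hist[i + 1] > 0)):
            raise ValueError(
                f"umbrella windows at {centers[i]:.4g} and "
                f"{centers[i + 1]:.4g} do not overlap")

    N = hist.sum(axis=1)                               # samples per window
    bias = 0.5 * windows.k_spring * (mids[np.newaxis, :]
                                     - centers[:, np.newaxis]) ** 2  # (W, B)
    boltz = np.exp(-bias / kT)
    total = hist.sum(axis=0)                           # (B,)
    f = np.zeros(len(centers))
    for _ in range(max_iter):
        denom = (N * np.exp(f / kT)) @ boltz           # (B,)
        with np.errstate(divide="ignore", invalid="ignore"):
            P = np.where(denom > 0, total / denom, 0.0)
        Z = P.sum()
        P = P / Z
        f_new = -kT * np.log(boltz @ P)
        f_new -= f_new[0]
        if np.max(np.abs(f_new - f)) < tol:
            f = f_new
            break
        f = f_new
    else:
        warnings.warn("WHAM did not reach tolerance", RuntimeWarning)

    with np.errstate(divide="ignore"):
        pmf = -kT * np.log(P)
    pmf[total == 0] = np.nan
    pmf -= np.nanmin(pmf)
    return mids, pmf, f


def block_convergence(windows: UmbrellaWindowSet, n_blocks: int = 3,
                      n_bins: int | None = None, tol: float = 1e-11):
    """Per-block WHAM PMFs and their pointwise spread.

    Each window's samples are split into ``n_blocks`` contiguous blocks
    (trajectory thirds by default); WHAM runs per block and the reported
    spread is the pointwise max-minus-min over blocks, restricted to bins
    occupied in every block.  Returns (bin_centers, block_pmfs, spread).
    """
    if any(len(s) < n_blocks for s in windows.samples):
        raise ValueError(f"every window needs at least {n_blocks} samples")
    lo = min(s.min() for s in windows.samples)
    hi = max(s.max() for s in windows.samples)
    if n_bins is None:
        c = np.sort(windows.centers)
        spacing = np.min(np.diff(c)) if len(c) > 1 else (hi - lo)
        n_bins = max(int(np.ceil((hi - lo) / (spacing / 5.0))), 10)

    block_pmfs = []
    mids_ref = None
    for b in range(n_blocks):
        block_samples = [np.array_split(s, n_blocks)[b] for s in windows.samples]
        sub = UmbrellaWindowSet(centers=windows.centers,
                                k_spring=windows.k_spring,
                                temperature=windows.temperature,
                                samples=block_samples)
        # common grid across blocks: fix the bin count, clamp to full range
        mids, pmf, _ = wham(sub, n_bins=n_bins, tol=tol)
        if mids_ref is None:
            mids_ref = mids
            block_pmfs.append(pmf)
        else:
            block_pmfs.append(np.interp(mids_ref, mids, pmf,
                                        left=np.nan, right=np.nan))
    stack = np.vstack(block_pmfs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        spread = np.nanmax(stack, axis=0) - np.nanmin(stack, axis=0)
    spread[np.any(np.isnan(stack), axis=0)] = np.nan
    return mids_ref, stack, spread


# ---------------------------------------------------------------------------
# well-tempered metadynamics
# ---------------------------------------------------------------------------

@dataclass
class BiasPotentialState:
    """Accumulated well-tempered metadynamics bias along one or more CVs.

    ``sigma`` holds one Gaussian width per CV; ``periodic`` marks CVs with
    a periodic distance (period per CV, or None).  The bias factor is
    gamma = (T + DeltaT) / T.
    """

    sigma: np.ndarray
    height0: float               # W0, kJ/mol
    delta_T: float               # K
    temperature: float = DEFAULT_TEMPERATURE
    deposition_stride: int = 500
    periodic: list | None = None
    centers: list = field(default_factory=list)
    heights: list = field(default_factory=list)

    def __post_init__(self):
        self.sigma = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        if np.any(self.sigma <= 0):
            raise ValueError("Gaussian widths must be positive")
        if self.height0 <= 0:
            raise ValueError("initial Gaussian height must be positive")
        if self.periodic is None:
            self.periodic = [None] * len(self.sigma)

    @property
    def n_cvs(self) -> int:
        return len(self.sigma)

    @property
    def gamma(self) -> float:
        return (self.temperature + self.delta_T) / self.temperature

    def _displacements(self, points: np.ndarray) -> np.ndarray:
        """(n_points, n_gaussians, n_cvs) CV displacements, periodic-aware."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        cen = np.asarray(self.centers, dtype=float).reshape(-1, self.n_cvs)
        d = pts[:, np.newaxis, :] - cen[np.newaxis, :, :]
        for k, period in enumerate(self.periodic):
            if period is not None:
                d[:, :, k] -= period * np.round(d[:, :, k] / period)
        return d

    def bias_value(self, points) -> np.ndarray:
        """Current bias V_G at one or more CV points (kJ/mol)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if pts.shape[-1] != self.n_cvs:
            pts = pts.reshape(-1, self.n_cvs)
        if not self.centers:
            out = np.zeros(len(pts))
        else:
            d = self._displacements(pts)
            expo = -0.5 * np.sum((d / self.sigma[np.newaxis, np.newaxis, :]) ** 2,
                                 axis=2)
            out = np.exp(expo) @ np.asarray(self.heights)
        return out if out.size > 1 else float(out[0])


def wt_metad_update(state: BiasPotentialState, cv_value) -> BiasPotentialState:
    """Deposit one Gaussian with the well-tempered height rule.

    The new height is W0 exp(-V(s) / (k_B DeltaT)) with V the bias already
    accumulated at the deposition point; the first deposition has height W0.
    """
    if state.delta_T <= 0:
        raise ValueError("DeltaT must be positive for well-tempered deposition")
    cv = np.atleast_1d(np.asarray(cv_value, dtype=float))
    if len(cv) != state.n_cvs:
        raise ValueError("CV dimensionality mismatch")
    v_here = state.bias_value(cv)
    v_here = float(np.atleast_1d(v_here)[0])
    height = state.height0 * math.exp(-v_here / (KB * state.delta_T))
    state.centers.append(cv.copy())
    state.heights.append(height)
    return state


def wt_metad_fes(state: BiasPotentialState, grid) -> FreeEnergySurface:
    """Free-energy estimate from the accumulated well-tempered bias.

    Uses the asymptotic relation F(s) = -(gamma / (gamma - 1)) V_G(s),
    min-shifted to zero on the grid.  Requires gamma > 1; with no Gaussians
    deposited yet the surface is flat zero.
    """
    if state.gamma <= 1.0:
        raise ValueError("bias factor gamma must exceed 1")
    grid = np.asarray(grid, dtype=float)
    pts = grid.reshape(-1, 1) if grid.ndim == 1 else grid
    if not state.centers:
        V = np.zeros(len(pts))
    else:
        V = np.atleast_1d(state.bias_value(pts))
    F = -(state.gamma / (state.gamma - 1.0)) * V
    F -= F.min()
    if grid.ndim == 1:
        edges = np.concatenate([[grid[0] - 0.5 * (grid[1] - grid[0])],
                                0.5 * (grid[1:] + grid[:-1]),
                                [grid[-1] + 0.5 * (grid[-1] - grid[-2])]])
        return FreeEnergySurface(edges=[edges], F=F,
                                 counts=np.full(len(F), np.nan),
                                 temperature=state.temperature)
    return FreeEnergySurface(edges=[], F=F, counts=np.full(len(F), np.nan),
                             temperature=state.temperature)


# ---------------------------------------------------------------------------
# parallel-tempering metadynamics exchange
# ---------------------------------------------------------------------------

@dataclass
class ReplicaState:
    """State of one PT-MetaD replica: temperature, energy, CVs and bias."""

    temperature: float
    energy: float                # potential energy U(R), kJ/mol
    cv: np.ndarray               # CV values s(R)
    bias: BiasPotentialState | None = None

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("replica temperature must be positive")
        self.cv = np.atleast_1d(np.asarray(self.cv, dtype=float))

    def bias_at(self, cv) -> float:
        if self.bias is None:
            return 0.0
        return float(np.atleast_1d(self.bias.bias_value(
            np.atleast_1d(cv)))[0])


def ptmetad_acceptance(rep_i: ReplicaState, rep_j: ReplicaState):
    """Exchange exponent and acceptance probability for a PT-MetaD swap.

    Delta = (beta_i - beta_j)(U_i - U_j)
            + beta_i [V_G^i(s_i) - V_G^i(s_j)]
            + beta_j [V_G^j(s_j) - V_G^j(s_i)]

    with beta = 1/(k_B T); the swap is accepted with min(1, e^Delta).  With
    zero bias this reduces to the standard parallel-tempering rule, and the
    sign convention satisfies detailed balance of the two-replica extended
    ensemble (each replica Boltzmann-weighted with its own bias).
    """
    if len(rep_i.cv) != len(rep_j.cv):
        raise ValueError("replicas expose CVs of different dimensionality")
    beta_i = 1.0 / (KB * rep_i.temperature)
    beta_j = 1.0 / (KB * rep_j.temperature)
    delta_pt = (beta_i - beta_j) * (rep_i.energy - rep_j.energy)
    delta = (delta_pt
             + beta_i * (rep_i.bias_at(rep_i.cv) - rep_i.bias_at(rep_j.cv))
             + beta_j * (rep_j.bias_at(rep_j.cv) - rep_j.bias_at(rep_i.cv)))
    return delta, min(1.0, math.exp(min(delta, 700.0)))
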