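"""Synthetic trajectory generators emulating CG membrane-protein data.

The generators provide every input the analysis pipeline consumes, with the
statistical structure the estimators assume:

* a continuous-time Markov jump process over a small number of orientational
  macrostates (exposed / occluded / transition states), sampled exactly via
  exponential waiting times and embedded-chain jumps, then frame-sampled at
  the trajectory stride;
* Gaussian angle emissions around basin centers in (theta_t, theta_r) space,
  with theta_r wrapped to (-180, 180] and theta_t reflected into [0, 180];
* rigid bead fixtures posed at exact tilt/rotation/height for geometry
  oracles;
* exact inverse-CDF sampling of biased umbrella-window densities;
* an overdamped Langevin integrator on analytic potentials to exercise the
  metadynamics operators;
* planar lipid point fields (mixed or two-phase) for RDF and partitioning.

Kinetics are expressed in "effective" microseconds throughout: rates carry
the units the source trajectories report and no coarse-grained time-scaling
factor is applied.

Preset kinetic schemes
----------------------
Rate matrices for the preset systems are built from target stationary
populations and symmetric exchange coefficients ``c_ij`` via detailed
balance, ``k_ij = c_ij / pi_i``, with any directly known rates overriding
the constructed edges.  The anionic-membrane GTP scheme keeps the direct
exposed<->occluded exchange (0.0027 / 0.00096 us^-1) roughly two orders of
magnitude slower than the pathway through the membrane-detached transition
state, and the exchange coefficients are sized so every intermediate relaxes
on the 1-2 us scale — slow enough to stay resolved above the 450 ns lag of
the state models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import KB, DEFAULT_TEMPERATURE
from .geometry import (BeadFrame, OrientationTrajectory, reflect_angle_deg,
                       wrap_angle_deg)

__all__ = [
    "KineticScheme",
    "EmissionSpec",
    "HiddenPath",
    "scheme_from_populations",
    "anionic_gtp_scheme",
    "popc_scheme",
    "anionic_gdp_scheme",
    "anionic_emission_spec",
    "popc_emission_spec",
    "simulate_hidden_jump_process",
    "emit_orientation",
    "make_bead_fixture",
    "sample_umbrella_windows",
    "simulate_langevin_on_potential",
    "generate_lipid_field",
]


# ---------------------------------------------------------------------------
# kinetic schemes
# ---------------------------------------------------------------------------

@dataclass
class KineticScheme:
    """Continuous-time Markov generator over orientational macrostates.

    ``rate_matrix`` holds per-pair transition rates in us^-1; off-diagonals
    are nonnegative and each diagonal equals minus its row sum.
    """

    rate_matrix: np.ndarray
    state_labels: list

    def __post_init__(self):
        Q = np.asarray(self.rate_matrix, dtype=float)
        if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
            raise ValueError("rate matrix must be square")
        off = Q - np.diag(np.diag(Q))
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be nonnegative")
        if not np.allclose(Q.sum(axis=1), 0.0, atol=1e-10):
            raise ValueError("rate-matrix rows must sum to zero")
        if len(self.state_labels) != Q.shape[0]:
            raise ValueError("one label per state required")
        self.rate_matrix = Q

    @property
    def n_macrostates(self) -> int:
        return self.rate_matrix.shape[0]

    def is_irreducible(self) -> bool:
        from scipy.sparse.csgraph import connected_components
        adj = (self.rate_matrix > 0).astype(int)
        n_comp, _ = connected_components(adj, directed=True, connection="strong")
        return n_comp == 1

    def stationary_distribution(self) -> np.ndarray:
        """Stationary distribution pi with pi Q = 0 (requires irreducibility)."""
        if not self.is_irreducible():
            raise ValueError("scheme is reducible; no unique stationary distribution")
        Q = self.rate_matrix
        n = Q.shape[0]
        # solve pi Q = 0 with sum(pi) = 1
        A = np.vstack([Q.T, np.ones(n)])
        b = np.zeros(n + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(A, b, rcond=None)
        pi = np.clip(pi, 0.0, None)
        return pi / pi.sum()


def scheme_from_populations(populations, exchange, overrides=None,
                            labels=None) -> KineticScheme:
    """Build a detailed-balance generator from target populations.

    ``exchange`` maps state pairs (i, j) to symmetric exchange coefficients
    c_ij, giving k(i->j) = c_ij / pi_i and k(j->i) = c_ij / pi_j (which
    satisfy detailed balance against ``populations`` exactly).  ``overrides``
    maps ordered pairs (i, j) to directly imposed rates, applied afterwards.
    """
    pi = np.asarray(populations, dtype=float)
    if np.any(pi <= 0) or not math.isclose(pi.sum(), 1.0, rel_tol=1e-9):
        raise ValueError("populations must be positive and sum to 1")
    n = len(pi)
    Q = np.zeros((n, n))
    for (i, j), c in exchange.items():
        if c < 0:
            raise ValueError("exchange coefficients must be nonnegative")
        Q[i, j] = c / pi[i]
        Q[j, i] = c / pi[j]
    for (i, j), k in (overrides or {}).items():
        Q[i, j] = k
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    if labels is None:
        labels = [f"state-{k}" for k in range(n)]
    return KineticScheme(rate_matrix=Q, state_labels=list(labels))


#: State order used by all 4-state presets.
FOUR_STATE_LABELS = ["transition-a", "transition-b", "occluded", "exposed"]


def anionic_gtp_scheme() -> KineticScheme:
    """4-state scheme for GTP-loaded protein on a 70:30 anionic membrane.

    Stationary split 5/5/23/67 % (transition-a, transition-b, occluded,
    exposed); the direct occluded->exposed and exposed->occluded rates are
    0.0027 and 0.00096 us^-1, while the pathway through the membrane-detached
    transition state is ~two orders of magnitude faster.
    """
    return scheme_from_populations(
        populations=(0.05, 0.05, 0.23, 0.67),
        exchange={(0, 1): 0.004, (0, 2): 0.008, (0, 3): 0.008,
                  (1, 2): 0.02, (1, 3): 0.015},
        overrides={(2, 3): 0.0027, (3, 2): 0.00096},
        labels=FOUR_STATE_LABELS,
    )


def popc_scheme() -> KineticScheme:
    """2-state scheme for the zwitterionic (pure POPC) membrane.

    The exposed state covers 91% of the stationary distribution and decays
    toward the short-lived non-specific state at 0.0143 us^-1.
    """
    k_exp_ns = 0.0143
    pi = np.array([0.09, 0.91])
    Q = np.array([[0.0, k_exp_ns * pi[1] / pi[0]],
                  [k_exp_ns, 0.0]])
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return KineticScheme(rate_matrix=Q, state_labels=["non-specific", "exposed"])


def anionic_gdp_scheme() -> KineticScheme:
    """4-state scheme for the GDP-loaded protein on the anionic membrane.

    The occluded population collapses to ~1% and the exposed population
    rises by ~20 percentage points relative to the GTP scheme (stationary
    split 6/6/1/87 %); the pathway from the exposed state toward the
    transition states is slowed by roughly an order of magnitude.
    """
    return scheme_from_populations(
        populations=(0.06, 0.06, 0.01, 0.87),
        exchange={(0, 1): 0.005, (0, 2): 0.0008, (0, 3): 0.001,
                  (1, 2): 0.002, (1, 3): 0.05, (2, 3): 0.0006},
        labels=FOUR_STATE_LABELS,
    )


# ---------------------------------------------------------------------------
# emissions
# ---------------------------------------------------------------------------

@dataclass
class EmissionSpec:
    """Per-macrostate Gaussian angle emission parameters (degrees).

    ``centers`` and ``sigmas`` are (M, 2) arrays over (theta_t, theta_r);
    theta_r is treated as periodic on (-180, 180], theta_t is reflected into
    [0, 180] at the boundaries.
    """

    centers: np.ndarray
    sigmas: np.ndarray
    state_labels: list = field(default_factory=list)

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=float)
        self.sigmas = np.asarray(self.sigmas, dtype=float)
        if self.centers.shape != self.sigmas.shape or self.centers.shape[1] != 2:
            raise ValueError("centers and sigmas must both be (M, 2)")
        if np.any(self.sigmas <= 0):
            raise ValueError("emission widths must be positive")
        if np.any(self.centers[:, 0] < 0) or np.any(self.centers[:, 0] > 180):
            raise ValueError("theta_t centers must lie in [0, 180]")
        if not self.state_labels:
            self.state_labels = [f"state-{k}" for k in range(len(self.centers))]

    @property
    def n_states(self) -> int:
        return len(self.centers)


def anionic_emission_spec() -> EmissionSpec:
    """Basin parameters for the 4-state anionic-membrane systems.

    The exposed basin spans theta_t 30-120 deg and theta_r -160 to -20 deg;
    the occluded basin spans theta_t 45-90 deg and theta_r 30-120 deg.
    Centers sit at basin midpoints with sigma = basin width / 4; the two
    transition states are placed in the remaining unspecific regions.
    """
    return EmissionSpec(
        centers=[(20.0, 60.0), (110.0, 170.0), (67.5, 75.0), (75.0, -90.0)],
        sigmas=[(10.0, 25.0), (15.0, 30.0), (11.25, 22.5), (22.5, 35.0)],
        state_labels=FOUR_STATE_LABELS,
    )


def popc_emission_spec() -> EmissionSpec:
    """Basin parameters for the 2-state zwitterionic system."""
    return EmissionSpec(
        centers=[(110.0, 170.0), (75.0, -90.0)],
        sigmas=[(15.0, 30.0), (22.5, 35.0)],
        state_labels=["non-specific", "exposed"],
    )


# ---------------------------------------------------------------------------
# hidden jump process
# ---------------------------------------------------------------------------

@dataclass
class HiddenPath:
    """Ground-truth macrostate path of one replica.

    ``jump_times_us`` are the entry times of each visited state (strictly
    increasing, starting at 0); ``states`` the visited-state sequence;
    ``frame_states`` the state labels sampled every ``dt_ns``.
    """

    jump_times_us: np.ndarray
    states: np.ndarray
    frame_states: np.ndarray
    dt_ns: float
    replica: int = 0
    seed: int | None = None

    def __post_init__(self):
        self.jump_times_us = np.asarray(self.jump_times_us, dtype=float)
        self.states = np.asarray(self.states, dtype=int)
        self.frame_states = np.asarray(self.frame_states, dtype=int)
        if len(self.jump_times_us) != len(self.states):
            raise ValueError("one state per jump time required")
        if len(self.jump_times_us) > 1 and not np.all(np.diff(self.jump_times_us) > 0):
            raise ValueError("jump times must be strictly increasing")

    @property
    def frame_times_ns(self) -> np.ndarray:
        return np.arange(len(self.frame_states)) * self.dt_ns


def simulate_hidden_jump_process(scheme: KineticScheme, duration_us: float,
                                 dt_ns: float, n_replicas: int = 1,
                                 init="stationary",
                                 seed: int | None = None) -> list:
    """Sample the macrostate jump process exactly and frame-sample it.

    The continuous-time chain is simulated with exponential waiting times
    (rate -Q_ii) and embedded-chain jumps, then labels are read off every
    ``dt_ns``.  Replicas use independent child seeds.  ``init`` is either
    "stationary" (requires an irreducible scheme), a probability vector, or
    an integer start state.
    """
    if dt_ns <= 0:
        raise ValueError("dt must be positive")
    dt_us = dt_ns * 1e-3
    if duration_us / dt_us < 1:
        raise ValueError("duration must cover at least one frame interval")
    Q = scheme.rate_matrix
    n = scheme.n_macrostates
    exit_rates = -np.diag(Q)

    if isinstance(init, str) and init == "stationary":
        init_dist = scheme.stationary_distribution()
    elif np.isscalar(init):
        init_dist = np.zeros(n)
        init_dist[int(init)] = 1.0
    else:
        init_dist = np.asarray(init, dtype=float)
        if init_dist.shape != (n,) or not math.isclose(init_dist.sum(), 1.0,
                                                       rel_tol=1e-9):
            raise ValueError("init must be a length-n probability vector")

    root = np.random.SeedSequence(seed)
    paths = []
    n_frames = int(np.floor(duration_us / dt_us)) + 1
    frame_times = np.arange(n_frames) * dt_us
    for rep, child in enumerate(root.spawn(n_replicas)):
        rng = np.random.default_rng(child)
        state = int(rng.choice(n, p=init_dist))
        t = 0.0
        jump_times = [0.0]
        states = [state]
        while t < duration_us:
            rate = exit_rates[state]
            if rate <= 0:
                break  # absorbing state
            t += rng.exponential(1.0 / rate)
            if t >= duration_us:
                break
            probs = Q[state].copy()
            probs[state] = 0.0
            probs /= probs.sum()
            state = int(rng.choice(n, p=probs))
            jump_times.append(t)
            states.append(state)
        jump_times = np.asarray(jump_times)
        states_arr = np.asarray(states)
        frame_states = states_arr[np.searchsorted(jump_times, frame_times,
                                                  side="right") - 1]
        paths.append(HiddenPath(jump_times_us=jump_times, states=states_arr,
                                frame_states=frame_states, dt_ns=dt_ns,
                                replica=rep, seed=seed))
    return paths


def emit_orientation(path: HiddenPath, spec: EmissionSpec,
                     seed: int | None = None) -> OrientationTrajectory:
    """Draw per-frame (theta_t, theta_r) given the hidden macrostate path.

    Angles are independent Gaussians around the state's basin center;
    theta_r is wrapped to (-180, 180] and theta_t reflected into [0, 180].
    """
    if path.frame_states.max(initial=0) >= spec.n_states:
        raise ValueError("emission spec does not cover all states in path")
    rng = np.random.default_rng(seed)
    centers = spec.centers[path.frame_states]
    sigmas = spec.sigmas[path.frame_states]
    raw = rng.normal(loc=centers, scale=sigmas)
    theta_t = reflect_angle_deg(raw[:, 0])
    theta_r = wrap_angle_deg(raw[:, 1])
    return OrientationTrajectory(time_ns=path.frame_times_ns,
                                 theta_t_deg=theta_t, theta_r_deg=theta_r,
                                 replica=path.replica, stride_ns=path.dt_ns)


# ---------------------------------------------------------------------------
# rigid bead fixture
# ---------------------------------------------------------------------------

def _pose_rotation(tilt_deg: float, rotation_deg: float) -> np.ndarray:
    """Rotation whose body axes (columns) realize the requested pose.

    Columns are the body axes (e1, e2, e3) in the lab frame, chosen so that
    the membrane normal expressed in body coordinates has polar angle
    ``tilt_deg`` and azimuth ``rotation_deg``.
    """
    t = np.radians(tilt_deg)
    r = np.radians(rotation_deg)
    ry = np.array([[np.cos(t), 0, -np.sin(t)],
                   [0, 1, 0],
                   [np.sin(t), 0, np.cos(t)]])  # Ry(-t)
    rz = np.array([[np.cos(r), np.sin(r), 0],
                   [-np.sin(r), np.cos(r), 0],
                   [0, 0, 1]])  # Rz(-r)
    return ry @ rz


def make_bead_fixture(tilt_deg: float, rotation_deg: float,
                      com_height_nm: float = 4.0) -> BeadFrame:
    """Rigid toy G-domain posed exactly at (tilt, rotation) above a bilayer.

    The body template has base beads at the origin, a tip bead 2 nm along
    the body axis and a face bead offset along the body x axis; the whole
    template is rotated so that ``compute_tilt_rotation`` recovers the
    requested pose identically, then translated so the G-domain COM sits
    ``com_height_nm`` above the membrane midplane (z = 0).
    """
    if not 0.0 <= tilt_deg <= 180.0:
        raise ValueError("tilt must lie in [0, 180] degrees")
    R = _pose_rotation(tilt_deg, rotation_deg)
    body = {
        "base": np.array([[0.0, 0.12, 0.0], [0.0, -0.12, 0.0]]),
        "tip": np.array([[0.0, 0.1, 2.0], [0.0, -0.1, 2.0]]),
        "face": np.array([[0.8, 0.0, 1.0]]),
    }
    names, pos = [], []
    for name, beads in body.items():
        for b in beads:
            names.append(name)
            pos.append(R @ b)
    pos = np.asarray(pos)
    pos = pos - pos.mean(axis=0) + np.array([5.0, 5.0, com_height_nm])

    # flat two-leaflet lipid slab
    grid = np.linspace(0.5, 9.5, 8)
    gx, gy = np.meshgrid(grid, grid)
    mem_names, mem_pos, mem_leaf = [], [], []
    for z, leaflet in ((1.0, "upper"), (-1.0, "lower")):
        for x, y in zip(gx.ravel(), gy.ravel()):
            mem_names.append("POPC")
            mem_pos.append([x, y, z])
            mem_leaf.append(leaflet)

    positions = np.vstack([pos, np.asarray(mem_pos)])
    group_names = np.array(names + mem_names, dtype=object)
    n_prot = len(names)
    resids = np.concatenate([np.zeros(n_prot, dtype=int),
                             np.arange(1, len(mem_names) + 1)])
    leaflets = np.array([""] * n_prot + mem_leaf, dtype=object)
    # the whole protein doubles as the "gdomain" COM group
    return BeadFrame(positions=positions, box=np.array([10.0, 10.0, 30.0]),
                     group_names=group_names, resids=resids, leaflets=leaflets)


# ---------------------------------------------------------------------------
# umbrella windows
# ---------------------------------------------------------------------------

def sample_umbrella_windows(pmf, centers, k_spring: float = 1000.0,
                            n_per_window: int = 2000,
                            temperature: float = DEFAULT_TEMPERATURE,
                            seed: int | None = None, grid_points: int = 4000):
    """Exact samples from the biased Boltzmann density of each window.

    Each window's density exp(-(pmf(x) + k/2 (x-c)^2) / kT) is tabulated on
    a fine grid spanning the window centers plus 5 thermal widths and sampled
    by inverse-CDF lookup (linear interpolation between grid points).
    Returns an :class:`~memorient.free_energy.UmbrellaWindowSet`.
    """
    from .free_energy import UmbrellaWindowSet

    if k_spring <= 0:
        raise ValueError("spring constant must be positive")
    centers = np.asarray(centers, dtype=float)
    kT = KB * temperature
    # per-window local grid: the biased density is confined to a few thermal
    # widths around the center, so a fine local grid keeps the piecewise
    # density representation from distorting the tails
    pad = 8.0 * math.sqrt(kT / k_spring)

    rng = np.random.default_rng(seed)
    samples = []
    for c in centers:
        grid = np.linspace(c - pad, c + pad, grid_points)
        dx = grid[1] - grid[0]
        base = np.asarray([pmf(x) for x in grid], dtype=float)
        if not np.all(np.isfinite(base)):
            raise ValueError("pmf must be finite on the sampling support")
        energy = base + 0.5 * k_spring * (grid - c) ** 2
        density = np.exp(-(energy - energy.min()) / kT)
        # exact inverse-CDF draw from the piecewise-linear density through
        # the grid nodes: trapezoidal CDF locates the interval, and the
        # within-interval quadratic is inverted in closed form
        cdf = np.concatenate([[0.0],
                              np.cumsum(0.5 * (density[1:] + density[:-1]) * dx)])
        cdf /= cdf[-1]
        u = rng.random(n_per_window)
        idx = np.clip(np.searchsorted(cdf, u, side="right") - 1, 0,
                      len(grid) - 2)
        t = (u - cdf[idx]) / (cdf[idx + 1] - cdf[idx])
        d0, d1 = density[idx], density[idx + 1]
        slope = d1 - d0
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(
                np.abs(slope) > 1e-12 * np.maximum(d0, d1),
                (np.sqrt(d0 ** 2 + t * (d1 ** 2 - d0 ** 2)) - d0) / slope,
                t)
        samples.append(grid[idx] + frac * dx)
    return UmbrellaWindowSet(centers=centers, k_spring=k_spring,
                             temperature=temperature, samples=samples)


# ---------------------------------------------------------------------------
# Langevin engine for metadynamics tests
# ---------------------------------------------------------------------------

def simulate_langevin_on_potential(potential, bias=None, steps: int = 100_000,
                                   dt: float = 1e-3,
                                   temperature: float = DEFAULT_TEMPERATURE,
                                   friction: float = 1.0, x0: float = 0.0,
                                   seed: int | None = None,
                                   deposition_stride: int = 500,
                                   grid=(-3.0, 3.0, 1201),
                                   bound: float = 50.0) -> np.ndarray:
    """Overdamped Langevin dynamics on a 1D potential, optionally biased.

    The deterministic force (and, when a
    :class:`~memorient.free_energy.BiasPotentialState` is supplied, the
    current bias force) is tabulated on a fixed grid and linearly
    interpolated; the bias table is refreshed after each deposition, which
    happens every ``deposition_stride`` steps through the well-tempered
    height rule.  Returns the CV trace (length ``steps + 1``).
    """
    from .free_energy import wt_metad_update

    if dt <= 0 or friction <= 0:
        raise ValueError("dt and friction must be positive")
    lo, hi, npts = grid
    xs = np.linspace(lo, hi, int(npts))
    dx = xs[1] - xs[0]
    base_force = -np.gradient(np.asarray([potential(x) for x in xs]), dx)
    # stability: the deterministic displacement per step must stay well
    # below the grid span
    max_step = np.max(np.abs(base_force)) * dt / friction
    if max_step > 0.2 * (hi - lo):
        raise ValueError(f"dt={dt} too large for stable integration")

    kT = KB * temperature
    noise_scale = math.sqrt(2.0 * kT * dt / friction)
    rng = np.random.default_rng(seed)
    force = base_force.copy()

    x = float(x0)
    trace = np.empty(steps + 1)
    trace[0] = x
    for step in range(1, steps + 1):
        if bias is not None and (step - 1) % deposition_stride == 0:
            wt_metad_update(bias, x)
            force = base_force - np.gradient(bias.bias_value(xs), dx)
        # linear interpolation of the force table
        f = np.interp(x, xs, force)
        x = x + f * dt / friction + noise_scale * rng.standard_normal()
        if abs(x) > bound:
            raise RuntimeError(
                f"trajectory diverged (|x| > {bound}); reduce dt={dt}")
        trace[step] = x
    return trace


# ---------------------------------------------------------------------------
# lipid fields
# ---------------------------------------------------------------------------

def generate_lipid_field(box, species_fractions: dict,
                         domain_structure: str = "mixed",
                         n_lipids: int = 1000, n_frames: int = 1,
                         enriched_species: str | None = None,
                         enrichment: float = 4.0,
                         seed: int | None = None) -> list:
    """Planar lipid point patterns, mixed or laterally demixed.

    "mixed" scatters every species uniformly over the box; "two-phase"
    places ``enriched_species`` (default: last listed) preferentially in the
    x < box_x/2 stripe with the stated enrichment ratio (stripe density /
    outside density).  Each lipid is one bead in the upper leaflet at
    z = 2 nm.  Returns a list of :class:`BeadFrame`.
    """
    fractions = dict(species_fractions)
    total = sum(fractions.values())
    if not math.isclose(total, 1.0, rel_tol=1e-9):
        raise ValueError("species fractions must sum to 1")
    box = np.asarray([box[0], box[1], 6.0]) if len(box) == 2 else np.asarray(box)
    if domain_structure not in ("mixed", "two-phase"):
        raise ValueError("domain_structure must be 'mixed' or 'two-phase'")
    species = list(fractions)
    if enriched_species is None:
        enriched_species = species[-1]

    rng = np.random.default_rng(seed)
    counts = {s: int(round(f * n_lipids)) for s, f in fractions.items()}
    frames = []
    for t in range(n_frames):
        names, pos = [], []
        for s in species:
            m = counts[s]
            x = rng.random(m) * box[0]
            if domain_structure == "two-phase" and s == enriched_species:
                # stripe density / outside density = enrichment
                p_stripe = enrichment / (enrichment + 1.0)
                in_stripe = rng.random(m) < p_stripe
                x = np.where(in_stripe, rng.random(m) * box[0] / 2,
                             box[0] / 2 + rng.random(m) * box[0] / 2)
            y = rng.random(m) * box[1]
            pos.append(np.column_stack([x, y, np.full(m, 2.0)]))
            names.extend([s] * m)
        positions = np.vstack(pos)
        frames.append(BeadFrame(
            positions=positions, box=box,
            group_names=np.array(names, dtype=object),
            resids=np.arange(len(names)),
            leaflets=np.array(["upper"] * len(names), dtype=object),
            time_ns=float(t)))
    return frames
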