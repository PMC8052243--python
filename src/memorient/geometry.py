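"""Geometric order parameters for membrane-anchored proteins.

The central observables are the G-domain tilt angle ``theta_t`` (polar angle
of the protein body axis away from the bilayer normal, taken as the box +z
axis) and the rotation angle ``theta_r`` (azimuth of the membrane normal
expressed in the protein body frame).  Around those sit the standard CG
membrane observables: COM-to-midplane distance, normalized residue/lipid
contact profiles, lateral radial distribution functions, lateral mean-square
displacement, and the preferential lipid partitioning constant

    P_A = (C_A / n_A) / sum_x (C_x / n_x)

where ``C_A`` is the time-averaged number of lipids of species A with any
bead within a cutoff of the probe and ``n_A`` the species total.

All distances are in nm, times in ns, angles in degrees.  Boxes are
orthorhombic; minimum-image distances are used throughout.  Beads carry
equal masses (CG convention), so COMs are plain coordinate means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "BeadFrame",
    "OrientationTrajectory",
    "ContactProfile",
    "PartitioningResult",
    "compute_tilt_rotation",
    "com_distance_normal",
    "contact_profile",
    "lateral_rdf",
    "lateral_msd",
    "lateral_msd_xy",
    "partition_constant",
    "wrap_angle_deg",
    "reflect_angle_deg",
]


def wrap_angle_deg(angle):
    """Wrap angles (degrees) into the half-open interval (-180, 180]."""
    wrapped = np.mod(np.asarray(angle, dtype=float) + 180.0, 360.0) - 180.0
    # mod maps 180 -> -180; restore the closed upper end of the convention
    wrapped = np.where(wrapped == -180.0, 180.0, wrapped)
    if np.isscalar(angle):
        return float(wrapped)
    return wrapped


def reflect_angle_deg(angle):
    """Reflect angles (degrees) into [0, 180] by folding at both boundaries."""
    a = np.abs(np.asarray(angle, dtype=float))
    period = np.mod(a, 360.0)
    reflected = np.where(period > 180.0, 360.0 - period, period)
    if np.isscalar(angle):
        return float(reflected)
    return reflected


@dataclass
class BeadFrame:
    """One frame of labeled coarse-grained bead coordinates.

    Parameters
    ----------
    positions : (N, 3) array, nm
    box : (3,) array, nm — orthorhombic box lengths; membrane normal is +z.
    group_names : (N,) str array — protein group name or lipid species.
    resids : (N,) int array — residue / lipid molecule index.
    leaflets : (N,) str array — "upper", "lower", or "" for non-membrane beads.
    time_ns : frame time.
    """

    positions: np.ndarray
    box: np.ndarray
    group_names: np.ndarray
    resids: np.ndarray
    leaflets: np.ndarray
    time_ns: float = 0.0

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        self.group_names = np.asarray(self.group_names, dtype=object)
        self.resids = np.asarray(self.resids, dtype=int)
        self.leaflets = np.asarray(self.leaflets, dtype=object)
        n = len(self.positions)
        if self.positions.shape != (n, 3):
            raise ValueError("positions must be (N, 3)")
        if not np.all(self.box > 0):
            raise ValueError("box lengths must be positive")
        for arr, name in ((self.group_names, "group_names"),
                          (self.resids, "resids"), (self.leaflets, "leaflets")):
            if len(arr) != n:
                raise ValueError(f"{name} must have one entry per bead")

    def indices(self, selection) -> np.ndarray:
        """Bead indices for a group name or an iterable of group names."""
        if isinstance(selection, str):
            selection = [selection]
        mask = np.isin(self.group_names.astype(str), list(selection))
        return np.flatnonzero(mask)

    def com(self, selection) -> np.ndarray:
        """Equal-mass center of mass of a selection."""
        idx = self.indices(selection)
        if len(idx) == 0:
            raise ValueError(f"empty selection: {selection!r}")
        return self.positions[idx].mean(axis=0)

    def membrane_indices(self) -> np.ndarray:
        mask = np.array([lf != "" for lf in self.leaflets])
        return np.flatnonzero(mask)


@dataclass
class OrientationTrajectory:
    """Per-replica time series of (theta_t, theta_r), the central observable."""

    time_ns: np.ndarray
    theta_t_deg: np.ndarray
    theta_r_deg: np.ndarray
    replica: int = 0
    stride_ns: float | None = None

    def __post_init__(self):
        self.time_ns = np.asarray(self.time_ns, dtype=float)
        self.theta_t_deg = np.asarray(self.theta_t_deg, dtype=float)
        self.theta_r_deg = np.asarray(self.theta_r_deg, dtype=float)
        if not (len(self.time_ns) == len(self.theta_t_deg) == len(self.theta_r_deg)):
            raise ValueError("time and angle arrays must have equal length")
        if len(self.time_ns) > 1 and not np.all(np.diff(self.time_ns) > 0):
            raise ValueError("time must be strictly increasing within a replica")
        finite_t = self.theta_t_deg[np.isfinite(self.theta_t_deg)]
        if finite_t.size and (finite_t.min() < 0 or finite_t.max() > 180):
            raise ValueError("theta_t must lie in [0, 180] degrees")
        finite_r = self.theta_r_deg[np.isfinite(self.theta_r_deg)]
        if finite_r.size and (finite_r.min() <= -180 or finite_r.max() > 180):
            raise ValueError("theta_r must lie in (-180, 180] degrees")
        if self.stride_ns is None and len(self.time_ns) > 1:
            self.stride_ns = float(self.time_ns[1] - self.time_ns[0])

    def __len__(self):
        return len(self.time_ns)

    def angles(self) -> np.ndarray:
        """(n_frames, 2) array of (theta_t, theta_r)."""
        return np.column_stack([self.theta_t_deg, self.theta_r_deg])


@dataclass
class ContactProfile:
    """Per-residue normalized contact frequency with a lipid selection."""

    resids: np.ndarray
    frequency: np.ndarray
    cutoff_nm: float
    protein_selection: object = None
    lipid_selection: object = None

    def __post_init__(self):
        self.frequency = np.asarray(self.frequency, dtype=float)
        if np.any(self.frequency < 0) or np.any(self.frequency > 1):
            raise ValueError("contact frequencies must lie in [0, 1]")
        if self.cutoff_nm <= 0:
            raise ValueError("cutoff must be positive")


@dataclass
class PartitioningResult:
    """Preferential lipid partitioning constants P_A per species."""

    species: list
    P: np.ndarray
    C: np.ndarray
    n: np.ndarray
    cutoff_nm: float = 0.55


# ---------------------------------------------------------------------------
# tilt / rotation
# ---------------------------------------------------------------------------

def compute_tilt_rotation(frame: BeadFrame,
                          axis_groups=("base", "tip"),
                          face_group="face",
                          eps_tilt_deg: float = 1.0):
    """Tilt and rotation of a protein body axis relative to the bilayer normal.

    The body axis ``a`` points from the COM of ``axis_groups[0]`` to the COM of
    ``axis_groups[1]``; ``theta_t`` is its angle from +z.  The body frame is
    (e1, e2, e3) with e3 = a and e1 the face vector (face COM minus base COM)
    orthogonalized against a; ``theta_r`` is the azimuth atan2(z.e2, z.e1) of
    the membrane normal in that frame, in (-180, 180].  When the axis is
    within ``eps_tilt_deg`` of the normal the azimuth is degenerate and
    ``theta_r`` is returned as NaN (the undefined marker).
    """
    base = frame.com(axis_groups[0])
    tip = frame.com(axis_groups[1])
    a = tip - base
    norm = np.linalg.norm(a)
    if norm < 1e-12:
        raise ValueError("axis groups have coincident centers of mass")
    a = a / norm
    theta_t = np.degrees(np.arccos(np.clip(a[2], -1.0, 1.0)))

    if theta_t < eps_tilt_deg:
        return float(theta_t), float("nan")

    f = frame.com(face_group) - base
    f_perp = f - np.dot(f, a) * a
    norm_f = np.linalg.norm(f_perp)
    if norm_f < 1e-10:
        raise ValueError("face vector is collinear with the body axis")
    e1 = f_perp / norm_f
    e2 = np.cross(a, e1)
    theta_r = np.degrees(np.arctan2(e2[2], e1[2]))
    return float(theta_t), float(wrap_angle_deg(theta_r))


def com_distance_normal(frame: BeadFrame, group="gdomain") -> float:
    """Signed z distance between a group COM and the membrane midplane.

    The midplane is the mean z of all membrane (leaflet-tagged) beads;
    beads carry equal masses.
    """
    idx = frame.indices(group)
    if len(idx) == 0:
        raise ValueError(f"empty group: {group!r}")
    mem = frame.membrane_indices()
    if len(mem) == 0:
        raise ValueError("no membrane beads in frame")
    leaf = frame.leaflets[mem].astype(str)
    if len(set(leaf)) < 2:
        raise ValueError("membrane beads present in only one leaflet")
    midplane = frame.positions[mem, 2].mean()
    return float(frame.positions[idx, 2].mean() - midplane)


# ---------------------------------------------------------------------------
# contacts and partitioning
# ---------------------------------------------------------------------------

def _wrapped(positions, box):
    return np.mod(positions, box[np.newaxis, :])


def contact_profile(frames, protein_selection, lipid_selection,
                    cutoff_nm: float = 0.55) -> ContactProfile:
    """Per-residue contact frequency of a protein selection with lipid beads.

    A residue is in contact in a frame when any of its beads lies within
    ``cutoff_nm`` (minimum image) of any bead of the lipid selection; the
    profile is the fraction of frames in contact.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("need at least one frame")
    first = frames[0]
    p_idx = first.indices(protein_selection)
    l_idx = first.indices(lipid_selection)
    if len(p_idx) == 0 or len(l_idx) == 0:
        raise ValueError("empty protein or lipid selection")

    resids = np.unique(first.resids[p_idx])
    hits = np.zeros(len(resids), dtype=int)
    resid_pos = {r: k for k, r in enumerate(resids)}
    for fr in frames:
        p_idx = fr.indices(protein_selection)
        l_idx = fr.indices(lipid_selection)
        tree = cKDTree(_wrapped(fr.positions[l_idx], fr.box), boxsize=fr.box)
        neighbors = tree.query_ball_point(
            _wrapped(fr.positions[p_idx], fr.box), r=cutoff_nm)
        touched = set()
        for bead, nb in zip(p_idx, neighbors):
            if nb:
                touched.add(fr.resids[bead])
        for r in touched:
            if r in resid_pos:
                hits[resid_pos[r]] += 1
    return ContactProfile(resids=resids, frequency=hits / len(frames),
                          cutoff_nm=cutoff_nm,
                          protein_selection=protein_selection,
                          lipid_selection=lipid_selection)


def partition_constant(frames, probe_selection, species,
                       cutoff_nm: float = 0.55) -> PartitioningResult:
    """Preferential lipid partitioning constants for the listed species.

    C_A is the time-averaged number of distinct lipids of species A with any
    bead within the cutoff of any probe bead; P_A = (C_A/n_A) / sum_x C_x/n_x.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("need at least one frame")
    species = list(species)
    first = frames[0]
    n = np.array([len(np.unique(first.resids[first.indices(s)])) for s in species],
                 dtype=float)
    for s, count in zip(species, n):
        if count == 0:
            raise ValueError(f"species {s!r} absent from frames")

    C = np.zeros(len(species))
    for fr in frames:
        probe = fr.indices(probe_selection)
        if len(probe) == 0:
            raise ValueError(f"empty probe selection: {probe_selection!r}")
        probe_tree = cKDTree(_wrapped(fr.positions[probe], fr.box), boxsize=fr.box)
        for k, sp in enumerate(species):
            sp_idx = fr.indices(sp)
            nb = probe_tree.query_ball_point(
                _wrapped(fr.positions[sp_idx], fr.box), r=cutoff_nm)
            in_contact = {fr.resids[i] for i, hits in zip(sp_idx, nb) if hits}
            C[k] += len(in_contact)
    C /= len(frames)
    ratio = C / n
    total = ratio.sum()
    if total == 0:
        raise ValueError("no contacts with any listed species")
    return PartitioningResult(species=species, P=ratio / total, C=C, n=n,
                              cutoff_nm=cutoff_nm)


# ---------------------------------------------------------------------------
# lateral structure and dynamics
# ---------------------------------------------------------------------------

def lateral_rdf(frames, reference_selection, target_species,
                r_max: float, bin_width: float):
    """Two-dimensional (xy-plane) radial distribution function.

    Pair counts in annuli around reference beads, normalized by the ideal-gas
    expectation at the target species' lateral density, averaged over frames.
    Returns (bin_centers, g) arrays.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("need at least one frame")
    box = frames[0].box
    if r_max > min(box[0], box[1]) / 2:
        raise ValueError("r_max exceeds half the smaller lateral box edge")
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    counts = np.zeros(len(edges) - 1)
    ideal_norm = 0.0
    for fr in frames:
        ref = fr.indices(reference_selection)
        tgt = fr.indices(target_species)
        if len(ref) == 0 or len(tgt) == 0:
            raise ValueError("empty reference or target selection")
        same = (len(ref) == len(tgt)) and np.array_equal(np.sort(ref), np.sort(tgt))
        n_pairs_possible = len(ref) * (len(tgt) - 1 if same else len(tgt))
        if n_pairs_possible == 0:
            raise ValueError("no pairs between reference and target")
        dx = fr.positions[tgt, 0][np.newaxis, :] - fr.positions[ref, 0][:, np.newaxis]
        dy = fr.positions[tgt, 1][np.newaxis, :] - fr.positions[ref, 1][:, np.newaxis]
        dx -= fr.box[0] * np.round(dx / fr.box[0])
        dy -= fr.box[1] * np.round(dy / fr.box[1])
        r = np.hypot(dx, dy)
        if same:
            np.fill_diagonal(r, np.inf)
        counts += np.histogram(r, bins=edges)[0]
        area = fr.box[0] * fr.box[1]
        density = (len(tgt) - (1 if same else 0)) / area
        ideal_norm += len(ref) * density
    annuli = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    g = counts / (annuli * ideal_norm)
    centers = 0.5 * (edges[1:] + edges[:-1])
    return centers, g


def _unwrap_xy(xy: np.ndarray, box_xy: np.ndarray) -> np.ndarray:
    """Correct periodic jumps larger than half a box edge (heuristic)."""
    d = np.diff(xy, axis=0)
    d -= box_xy[np.newaxis, :] * np.round(d / box_xy[np.newaxis, :])
    return np.vstack([xy[:1], xy[:1] + np.cumsum(d, axis=0)])


def lateral_msd_xy(xy_list, box_xy=None):
    """Lateral MSD from one or more xy tracks, averaged over time origins.

    ``xy_list`` is a list of (n_frames, 2) arrays (one per replica).  If
    ``box_xy`` is given, tracks are unwrapped by half-box jump detection
    first.  Returns (lags, msd) in frame units.
    """
    tracks = [np.asarray(xy, dtype=float) for xy in xy_list]
    if any(len(t) < 2 for t in tracks):
        raise ValueError("each track needs at least two frames")
    if box_xy is not None:
        box_xy = np.asarray(box_xy, dtype=float)
        tracks = [_unwrap_xy(t, box_xy) for t in tracks]
    n_lags = min(len(t) for t in tracks) - 1
    lags = np.arange(1, n_lags + 1)
    msd = np.zeros(n_lags)
    weights = np.zeros(n_lags)
    for t in tracks:
        for k, lag in enumerate(lags):
            d = t[lag:] - t[:-lag]
            msd[k] += np.sum(d[:, 0] ** 2 + d[:, 1] ** 2)
            weights[k] += len(d)
    return lags, msd / weights


def lateral_msd(frames, group):
    """Lateral MSD of a group's COM across a frame sequence.

    Returns (lag_times_ns, msd_nm2).  Coordinates are unwrapped assuming
    jumps larger than half a box edge are periodic images.
    """
    frames = list(frames)
    if len(frames) < 2:
        raise ValueError("need at least two frames")
    xy = np.array([fr.com(group)[:2] for fr in frames])
    times = np.array([fr.time_ns for fr in frames])
    lags, msd = lateral_msd_xy([xy], box_xy=frames[0].box[:2])
    dt = times[1] - times[0] if len(times) > 1 else 1.0
    return lags * dt, msd
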