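"""File interchange: TSV observables, JSON models, GRO/XTC and XYZ input.

Orientation trajectories travel as TSV with columns
``time_ns, theta_t_deg, theta_r_deg, replica``; hidden-path ground truth as
a sidecar TSV; umbrella windows as one TSV per window plus a manifest JSON;
transition and macrostate models as full-precision JSON.  Coordinate input
goes through MDAnalysis (GRO topology, optional XTC trajectory) with a JSON
group map assigning bead selections to group names, or through a plain
whitespace XYZ-per-frame fallback.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import BeadFrame, OrientationTrajectory
from .free_energy import BiasPotentialState, UmbrellaWindowSet

__all__ = [
    "write_orientation_tsv", "read_orientation_tsv",
    "write_hidden_path_tsv", "read_hidden_path_tsv",
    "write_umbrella_set", "read_umbrella_set",
    "write_labels_tsv", "read_labels_tsv",
    "transition_model_to_json", "macrostate_model_to_json",
    "bias_state_to_json", "bias_state_from_json",
    "write_json", "load_bead_frames", "read_xyz_frames",
]


def write_orientation_tsv(path, trajectories):
    """Write one or more replicas to a single angle table."""
    parts = []
    for t in trajectories:
        parts.append(pd.DataFrame({
            "time_ns": t.time_ns, "theta_t_deg": t.theta_t_deg,
            "theta_r_deg": t.theta_r_deg,
            "replica": np.full(len(t), t.replica, dtype=int)}))
    pd.concat(parts).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_orientation_tsv(path):
    df = pd.read_csv(path, sep="\t")
    required = {"time_ns", "theta_t_deg", "theta_r_deg", "replica"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"angle table missing columns: {sorted(missing)}")
    out = []
    for rep, grp in df.groupby("replica", sort=True):
        out.append(OrientationTrajectory(
            time_ns=grp["time_ns"].to_numpy(),
            theta_t_deg=grp["theta_t_deg"].to_numpy(),
            theta_r_deg=grp["theta_r_deg"].to_numpy(),
            replica=int(rep)))
    return out


def write_hidden_path_tsv(path, paths):
    """Ground-truth frame labels, one row per frame across replicas."""
    parts = []
    for p in paths:
        parts.append(pd.DataFrame({
            "time_ns": p.frame_times_ns, "state": p.frame_states,
            "replica": np.full(len(p.frame_states), p.replica, dtype=int)}))
    pd.concat(parts).to_csv(path, sep="\t", index=False)


def read_hidden_path_tsv(path):
    df = pd.read_csv(path, sep="\t")
    return [grp["state"].to_numpy()
            for _, grp in df.groupby("replica", sort=True)]


def write_labels_tsv(path, labels_per_replica):
    parts = []
    for rep, lab in enumerate(labels_per_replica):
        parts.append(pd.DataFrame({
            "frame": np.arange(len(lab)), "microstate": lab,
            "replica": np.full(len(lab), rep, dtype=int)}))
    pd.concat(parts).to_csv(path, sep="\t", index=False)


def read_labels_tsv(path):
    df = pd.read_csv(path, sep="\t")
    return [grp["microstate"].to_numpy()
            for _, grp in df.groupby("replica", sort=True)]


def write_umbrella_set(directory, windows: UmbrellaWindowSet):
    """One TSV per window plus a manifest JSON with layout metadata."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"k_spring_kJ_mol_nm2": windows.k_spring,
                "temperature_K": windows.temperature, "windows": []}
    for k, (c, s) in enumerate(zip(windows.centers, windows.samples)):
        name = f"window_{k:04d}.tsv"
        pd.DataFrame({"sample_nm": s}).to_csv(directory / name, sep="\t",
                                              index=False)
        manifest["windows"].append({"file": name, "center_nm": float(c)})
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def read_umbrella_set(directory) -> UmbrellaWindowSet:
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    centers, samples = [], []
    for w in manifest["windows"]:
        centers.append(w["center_nm"])
        samples.append(pd.read_csv(directory / w["file"],
                                   sep="\t")["sample_nm"].to_numpy())
    return UmbrellaWindowSet(centers=np.asarray(centers),
                             k_spring=manifest["k_spring_kJ_mol_nm2"],
                             temperature=manifest["temperature_K"],
                             samples=samples)


def transition_model_to_json(model) -> dict:
    return {
        "lag_ns": model.lag_ns,
        "active_set": model.active_set.tolist(),
        "transition_matrix": model.transition_matrix.tolist(),
        "stationary": model.stationary.tolist(),
        "reversible": bool(model.reversible),
    }


def macrostate_model_to_json(model, rates_ratio=None, rates_logm=None) -> dict:
    out = {
        "lag_ns": model.lag_ns,
        "transition_matrix": model.transition_matrix.tolist(),
        "emission_matrix": model.emission_matrix.tolist(),
        "initial": model.initial.tolist(),
        "converged": bool(model.converged),
        "n_iter": int(model.n_iter),
        "loglik_final": float(model.loglik_trace[-1]),
    }
    if rates_ratio is not None:
        out["rates_per_us_ratio"] = np.asarray(rates_ratio).tolist()
    if rates_logm is not None:
        out["rates_per_us_logm"] = np.asarray(rates_logm).tolist()
    return out


def bias_state_to_json(state: BiasPotentialState) -> dict:
    """Serializable checkpoint of an accumulated metadynamics bias."""
    return {
        "sigma": state.sigma.tolist(),
        "height0_kJ_mol": state.height0,
        "delta_T_K": state.delta_T,
        "temperature_K": state.temperature,
        "deposition_stride": state.deposition_stride,
        "periodic": state.periodic,
        "centers": [np.asarray(c).tolist() for c in state.centers],
        "heights_kJ_mol": list(state.heights),
    }


def bias_state_from_json(data: dict) -> BiasPotentialState:
    state = BiasPotentialState(sigma=data["sigma"],
                               height0=data["height0_kJ_mol"],
                               delta_T=data["delta_T_K"],
                               temperature=data["temperature_K"],
                               deposition_stride=data["deposition_stride"],
                               periodic=data["periodic"])
    state.centers = [np.asarray(c, dtype=float) for c in data["centers"]]
    state.heights = list(data["heights_kJ_mol"])
    return state


def write_json(path, obj):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# coordinate input
# ---------------------------------------------------------------------------

def load_bead_frames(topology, trajectory=None, group_map=None,
                     stride: int = 1):
    """Bead frames from a GRO topology and optional XTC/TRR trajectory.

    ``group_map`` is a dict (or path to a JSON file) mapping group names to
    MDAnalysis selection strings; beads outside every group keep their
    residue name as group tag.  Leaflets are assigned by bead z relative to
    the mean z of all beads whose group/residue name starts with a lipid
    tag found in the map's optional "__lipids__" list (defaults to every
    residue name that is not in the protein groups).
    """
    import MDAnalysis as mda

    if isinstance(group_map, (str, Path)):
        with open(group_map) as fh:
            group_map = json.load(fh)
    group_map = dict(group_map or {})
    lipid_names = group_map.pop("__lipids__", None)

    u = mda.Universe(str(topology)) if trajectory is None else \
        mda.Universe(str(topology), str(trajectory))
    n = len(u.atoms)
    names = np.array([r for r in u.atoms.resnames], dtype=object)
    for gname, sel in group_map.items():
        idx = u.select_atoms(sel).ix
        names[idx] = gname
    if lipid_names is None:
        lipid_names = sorted(set(u.atoms.resnames) - set(group_map))
    is_lipid = np.isin(names.astype(str), list(lipid_names))

    frames = []
    for ts in u.trajectory[::stride]:
        pos = u.atoms.positions / 10.0     # Angstrom -> nm
        box = ts.dimensions[:3] / 10.0
        leaflets = np.array([""] * n, dtype=object)
        if is_lipid.any():
            mid = pos[is_lipid, 2].mean()
            leaflets[is_lipid & (pos[:, 2] >= mid)] = "upper"
            leaflets[is_lipid & (pos[:, 2] < mid)] = "lower"
        frames.append(BeadFrame(positions=pos.copy(), box=box,
                                group_names=names.copy(),
                                resids=u.atoms.resids.copy(),
                                leaflets=leaflets, time_ns=ts.time / 1000.0))
    return frames


def read_xyz_frames(path, group_map, box, dt_ns: float = 1.0):
    """Plain whitespace XYZ-per-frame fallback reader.

    Format per frame: a line with the bead count, a comment line, then
    ``label x y z`` rows (nm).  ``group_map`` maps bead labels to
    (group_name, resid, leaflet) triples; unmapped labels become their own
    group with leaflet "".
    """
    box = np.asarray(box, dtype=float)
    frames = []
    with open(path) as fh:
        lines = [ln for ln in (l.strip() for l in fh) if ln]
    k = 0
    t = 0
    while k < len(lines):
        n = int(lines[k].split()[0])
        rows = lines[k + 2:k + 2 + n]
        labels, pos = [], []
        for row in rows:
            parts = row.split()
            labels.append(parts[0])
            pos.append([float(x) for x in parts[1:4]])
        names, resids, leaflets = [], [], []
        for i, lab in enumerate(labels):
            g, r, lf = group_map.get(lab, (lab, i, ""))
            names.append(g)
            resids.append(r)
            leaflets.append(lf)
        frames.append(BeadFrame(positions=np.asarray(pos), box=box,
                                group_names=np.array(names, dtype=object),
                                resids=np.asarray(resids),
                                leaflets=np.array(leaflets, dtype=object),
                                time_ns=t * dt_ns))
        k += 2 + n
        t += 1
    return frames
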