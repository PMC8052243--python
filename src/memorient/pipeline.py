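"""End-to-end orchestration: config-driven runs from angle trajectories to
state models, populations, rates and free-energy surfaces.

The single source of truth for a run is a YAML config; every parameter has
a validated default (400 microstates, 450 ns lag, 70x70 free-energy bins,
0.55 nm contact cutoff, 310 K).  ``run_pipeline`` executes

    angles -> k-means discretization -> MSM (lag ladder + chosen lag)
           -> macrostate-count selection -> PCCA+ -> Baum-Welch HMM
           -> populations / rates -> Boltzmann FES

and writes every artifact with metadata.  Runs are deterministic given the
config seeds.  ``recover_from_scheme`` wraps the same stages around the
synthetic generator for parameter-recovery experiments.
"""

from __future__ import annotations

import difflib
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import hmm as hmm_mod
from . import io as io_mod
from . import msm as msm_mod
from . import synthetic
from .constants import (CONTACT_CUTOFF_NM, DEFAULT_FES_BINS, DEFAULT_LAG_NS,
                        DEFAULT_N_MICROSTATES, DEFAULT_STRIDE_NS,
                        DEFAULT_TEMPERATURE)
from .free_energy import boltzmann_fes_2d

__all__ = ["RunConfig", "validate_config", "run_pipeline",
           "analyze_trajectories", "recover_from_scheme", "SCHEME_PRESETS"]

logger = logging.getLogger("memorient")

#: Named synthetic systems: (kinetic scheme factory, emission factory,
#: number of macrostates).
SCHEME_PRESETS = {
    "anionic-gtp": (synthetic.anionic_gtp_scheme,
                    synthetic.anionic_emission_spec, 4),
    "anionic-gdp": (synthetic.anionic_gdp_scheme,
                    synthetic.anionic_emission_spec, 4),
    "popc": (synthetic.popc_scheme, synthetic.popc_emission_spec, 2),
}

#: field -> (default, description, validator)
_CONFIG_SCHEMA = {
    "input_angles": (None, "path to an angle TSV (omit to simulate)",
                     lambda v: v is None or isinstance(v, str)),
    "scheme": ("anionic-gtp",
               "synthetic system preset used when no input is given",
               lambda v: v in SCHEME_PRESETS),
    "duration_us": (5000.0, "simulated duration per replica (us)",
                    lambda v: v > 0),
    "n_replicas": (10, "number of independent replicas",
                   lambda v: isinstance(v, int) and v >= 1),
    "stride_ns": (DEFAULT_STRIDE_NS, "frame stride of the trajectories (ns)",
                  lambda v: v > 0),
    "n_microstates": (DEFAULT_N_MICROSTATES,
                      "k-means microstates over (theta_t, theta_r)",
                      lambda v: isinstance(v, int) and v >= 2),
    "lag_ns": (DEFAULT_LAG_NS, "MSM/HMM lag time (ns)", lambda v: v > 0),
    "n_macrostates": ("auto",
                      "metastable state count, or 'auto' for timescale-gap "
                      "selection",
                      lambda v: v == "auto" or (isinstance(v, int) and v >= 1)),
    "lag_ladder_ns": (None, "lags for implied timescales (default: geometric, "
                            "10 points from the stride to 10x the model lag)",
                      lambda v: v is None or all(x > 0 for x in v)),
    "fes_bins": (list(DEFAULT_FES_BINS), "Boltzmann-histogram bin counts",
                 lambda v: len(v) == 2 and all(int(b) > 0 for b in v)),
    "cutoff_nm": (CONTACT_CUTOFF_NM, "contact cutoff (nm)", lambda v: v > 0),
    "temperature_K": (DEFAULT_TEMPERATURE, "system temperature (K)",
                      lambda v: v > 0),
    "seed": (0, "master seed for all stochastic stages",
             lambda v: isinstance(v, int) and v >= 0),
    "max_fit_samples": (200_000, "frame subsample used to fit k-means",
                        lambda v: isinstance(v, int) and v >= 1000),
    "hmm_tol": (1e-6, "per-frame EM convergence tolerance", lambda v: v > 0),
    "hmm_max_iter": (500, "EM iteration cap",
                     lambda v: isinstance(v, int) and v >= 1),
    "output_dir": ("run", "output directory", lambda v: isinstance(v, str)),
}


@dataclass
class RunConfig:
    """Validated pipeline parameters (see ``_CONFIG_SCHEMA`` for defaults)."""

    values: dict = field(default_factory=dict)

    def __getattr__(self, name):
        try:
            return self.values[name]
        except KeyError:
            raise AttributeError(name) from None

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        report = validate_config(raw)
        if report["errors"]:
            raise ValueError("; ".join(report["errors"]))
        return cls(values=report["resolved"])

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)


def validate_config(raw: dict) -> dict:
    """Schema and range validation of a raw config mapping.

    Returns a report with the resolved config, the list of defaulted fields
    (with their default and description), and any errors.  Unknown keys are
    errors with a closest-match suggestion — no silent typos.
    """
    raw = dict(raw or {})
    errors, defaulted, resolved = [], [], {}
    for key in raw:
        if key not in _CONFIG_SCHEMA:
            hint = difflib.get_close_matches(key, _CONFIG_SCHEMA, n=1)
            suffix = f"; did you mean {hint[0]!r}?" if hint else ""
            errors.append(f"unknown config key {key!r}{suffix}")
    for name, (default, desc, check) in _CONFIG_SCHEMA.items():
        if name in raw:
            value = raw[name]
            try:
                ok = check(value)
            except Exception:
                ok = False
            if not ok:
                errors.append(f"invalid value for {name!r}: {value!r} ({desc})")
                continue
        else:
            value = default
            defaulted.append({"field": name, "default": default,
                              "description": desc})
        resolved[name] = value
    return {"resolved": resolved, "defaulted": defaulted, "errors": errors}


# ---------------------------------------------------------------------------
# core analysis
# ---------------------------------------------------------------------------

def analyze_trajectories(trajectories, n_microstates: int = 400,
                         lag_ns: float = DEFAULT_LAG_NS,
                         n_macrostates="auto", seed: int | None = None,
                         max_fit_samples: int = 200_000,
                         lag_ladder_ns=None, hmm_tol: float = 1e-6,
                         hmm_max_iter: int = 500) -> dict:
    """Discretize, estimate the MSM, select/coarse-grain macrostates, fit
    the HMM and derive populations and rates.

    Returns a dict with the assignment, transition model, timescale
    spectrum, metastable sets, macrostate model, stationary populations and
    both rate estimates.
    """
    stride_ns = trajectories[0].stride_ns
    lag_frames = max(int(round(lag_ns / stride_ns)), 1)
    shortest = min(len(t) for t in trajectories)
    if lag_frames >= shortest:
        raise ValueError(
            f"lag of {lag_frames} frames is not shorter than the shortest "
            f"replica ({shortest} frames)")

    t0 = time.perf_counter()
    assignment = msm_mod.kmeans_discretize(
        trajectories, n_clusters=n_microstates, seed=seed,
        max_fit_samples=max_fit_samples)
    logger.info("discretize: %d frames -> %d microstates (%.1f s)",
                sum(len(t) for t in trajectories), assignment.n_clusters,
                time.perf_counter() - t0)

    C = msm_mod.count_matrix(assignment.labels, lag_frames)
    model = msm_mod.estimate_transition_matrix(C, reversible=True,
                                               lag_ns=lag_frames * stride_ns)
    logger.info("msm: active set %d/%d at lag %.0f ns", model.n_states,
                assignment.n_clusters, model.lag_ns)

    if lag_ladder_ns is None:
        lag_ladder_ns = np.unique(np.geomspace(
            stride_ns, 10 * lag_ns, 10).round() // stride_ns * stride_ns)
        lag_ladder_ns = lag_ladder_ns[lag_ladder_ns >= stride_ns]
    ladder_frames = sorted({max(int(round(l / stride_ns)), 1)
                            for l in lag_ladder_ns
                            if int(round(l / stride_ns)) < shortest})
    spectrum = msm_mod.implied_timescales(assignment.labels, ladder_frames,
                                          stride_ns)

    ts_at_lag = msm_mod.timescales_at_lag(model)
    if n_macrostates == "auto":
        M = msm_mod.select_n_macrostates(ts_at_lag, model.lag_ns)
        logger.info("selected %d macrostates from the timescale gap", M)
    else:
        M = int(n_macrostates)
    M = min(M, model.n_states)

    sets = msm_mod.pcca(model, M)
    # PCCA acts on the active set; map microstate labels into it, assigning
    # trimmed microstates to the macrostate of the nearest active microstate
    full_to_active = -np.ones(assignment.n_clusters, dtype=int)
    full_to_active[model.active_set] = np.arange(model.n_states)
    trimmed = np.flatnonzero(full_to_active < 0)
    if len(trimmed):
        act_centers = assignment.centers_embedded[model.active_set]
        for m in trimmed:
            d = np.linalg.norm(act_centers - assignment.centers_embedded[m],
                               axis=1)
            full_to_active[m] = int(np.argmin(d))
    active_labels = [full_to_active[lab] for lab in assignment.labels]

    t0 = time.perf_counter()
    macro = hmm_mod.fit_hmm(active_labels, M, lag_frames,
                            lag_ns=lag_frames * stride_ns, init=sets,
                            tol=hmm_tol, max_iter=hmm_max_iter, seed=seed)
    logger.info("hmm: %d EM iterations, converged=%s (%.1f s)",
                macro.n_iter, macro.converged, time.perf_counter() - t0)

    populations = hmm_mod.macrostate_populations(macro)
    return {
        "assignment": assignment,
        "transition_model": model,
        "timescale_spectrum": spectrum,
        "timescales_at_lag_ns": ts_at_lag,
        "n_macrostates": M,
        "metastable_sets": sets,
        "macrostate_model": macro,
        "populations": populations,
        "rates_ratio_per_us": hmm_mod.transition_rates(macro, "ratio"),
        "rates_logm_per_us": hmm_mod.transition_rates(macro, "logm"),
    }


def recover_from_scheme(scheme, emission, duration_us: float,
                        n_replicas: int = 10,
                        stride_ns: float = DEFAULT_STRIDE_NS,
                        n_macrostates="auto", seed: int = 0,
                        n_microstates: int = 400,
                        lag_ns: float = DEFAULT_LAG_NS,
                        max_fit_samples: int = 50_000,
                        hmm_tol: float = 3e-8,
                        hmm_max_iter: int = 500,
                        compute_spectrum: bool = False) -> dict:
    """Parameter-recovery experiment on one synthetic kinetic scheme.

    Simulates ``n_replicas`` replicas initialized from the stationary
    distribution, runs the full pipeline, and aligns recovered macrostates
    to the generator basins by emission location.  Populations and rate
    matrices in the result are re-ordered to generator state order.
    """
    root = np.random.SeedSequence(seed)
    sim_seed, emit_seed, ana_seed = [int(s.generate_state(1)[0] % (2**31 - 1))
                                     for s in root.spawn(3)]
    paths = synthetic.simulate_hidden_jump_process(
        scheme, duration_us, stride_ns, n_replicas=n_replicas,
        init="stationary", seed=sim_seed)
    emit_rng = np.random.SeedSequence(emit_seed)
    trajs = [synthetic.emit_orientation(p, emission, seed=int(
        c.generate_state(1)[0] % (2**31 - 1)))
        for p, c in zip(paths, emit_rng.spawn(len(paths)))]

    result = analyze_trajectories(
        trajs, n_microstates=n_microstates, lag_ns=lag_ns,
        n_macrostates=n_macrostates, seed=ana_seed,
        max_fit_samples=max_fit_samples,
        lag_ladder_ns=None if compute_spectrum else
        [lag_ns],  # the model lag only; ladder optional for speed
        hmm_tol=hmm_tol, hmm_max_iter=hmm_max_iter)

    model = result["macrostate_model"]
    assignment = result["assignment"]
    active_centers = assignment.centers[result["transition_model"].active_set]
    mapping = hmm_mod.match_states_to_basins(model, active_centers,
                                             emission.centers)
    M = model.n_macrostates
    order = np.empty(M, dtype=int)
    order[mapping] = np.arange(M)  # order[basin] = hidden state index
    result["basin_mapping"] = mapping
    result["populations_by_basin"] = result["populations"][order]
    result["rates_ratio_by_basin"] = \
        result["rates_ratio_per_us"][np.ix_(order, order)]
    result["rates_logm_by_basin"] = \
        result["rates_logm_per_us"][np.ix_(order, order)]
    result["paths"] = paths
    result["trajectories"] = trajs
    return result


# ---------------------------------------------------------------------------
# config-driven run
# ---------------------------------------------------------------------------

def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(type(o))


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured run and write artifacts to the output dir.

    Writes the resolved config, angle table (when simulating), microstate
    labels, MSM JSON, timescale table, HMM JSON and a summary JSON; every
    stochastic stage derives its seed from the config seed, so reruns are
    byte-identical.  Returns the run directory.
    """
    cfg = config.values
    outdir = Path(cfg["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter(
        "%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        config_text = json.dumps(cfg, indent=1, sort_keys=True)
        (outdir / "resolved_config.json").write_text(config_text + "\n")
        # hash the analysis parameters only, so identical runs into
        # different directories produce identical summaries
        hashed = {k: v for k, v in cfg.items() if k != "output_dir"}
        config_hash = hashlib.sha256(
            json.dumps(hashed, sort_keys=True).encode()).hexdigest()[:16]
        logger.info("run start (config hash %s)", config_hash)

        ground_truth = None
        if cfg["input_angles"]:
            trajs = io_mod.read_orientation_tsv(cfg["input_angles"])
            logger.info("loaded %d replicas from %s", len(trajs),
                        cfg["input_angles"])
        else:
            scheme_f, emit_f, _ = SCHEME_PRESETS[cfg["scheme"]]
            scheme, emission = scheme_f(), emit_f()
            root = np.random.SeedSequence(cfg["seed"])
            s1, s2 = [int(c.generate_state(1)[0] % (2**31 - 1))
                      for c in root.spawn(2)]
            paths = synthetic.simulate_hidden_jump_process(
                scheme, cfg["duration_us"], cfg["stride_ns"],
                n_replicas=cfg["n_replicas"], init="stationary", seed=s1)
            emit_rng = np.random.SeedSequence(s2)
            trajs = [synthetic.emit_orientation(
                p, emission,
                seed=int(c.generate_state(1)[0] % (2**31 - 1)))
                for p, c in zip(paths, emit_rng.spawn(len(paths)))]
            ground_truth = paths
            io_mod.write_orientation_tsv(outdir / "orientation.tsv", trajs)
            io_mod.write_hidden_path_tsv(outdir / "hidden_states.tsv", paths)
            logger.info("simulated %d replicas of %.0f us (%s scheme)",
                        len(trajs), cfg["duration_us"], cfg["scheme"])

        shortest_ns = min(len(t) for t in trajs) * trajs[0].stride_ns
        if cfg["lag_ns"] >= shortest_ns:
            raise ValueError(
                f"lag_ns={cfg['lag_ns']} must be shorter than the shortest "
                f"replica ({shortest_ns:.0f} ns)")

        result = analyze_trajectories(
            trajs, n_microstates=cfg["n_microstates"], lag_ns=cfg["lag_ns"],
            n_macrostates=cfg["n_macrostates"], seed=cfg["seed"],
            max_fit_samples=cfg["max_fit_samples"],
            lag_ladder_ns=cfg["lag_ladder_ns"], hmm_tol=cfg["hmm_tol"],
            hmm_max_iter=cfg["hmm_max_iter"])

        io_mod.write_labels_tsv(outdir / "microstates.tsv",
                                result["assignment"].labels)
        io_mod.write_json(outdir / "msm.json",
                          io_mod.transition_model_to_json(
                              result["transition_model"]))
        spec = result["timescale_spectrum"]
        ts_rows = [{"lag_ns": float(l),
                    "timescales_ns": [float(x) if np.isfinite(x) else None
                                      for x in ts[:6]]}
                   for l, ts in zip(spec.lags_ns, spec.timescales)]
        io_mod.write_json(outdir / "timescales.json", ts_rows)
        io_mod.write_json(outdir / "hmm.json", io_mod.macrostate_model_to_json(
            result["macrostate_model"],
            rates_ratio=result["rates_ratio_per_us"],
            rates_logm=result["rates_logm_per_us"]))

        fes = boltzmann_fes_2d(trajs, bins=tuple(cfg["fes_bins"]),
                               temperature=cfg["temperature_K"])
        np.savetxt(outdir / "fes.tsv",
                   np.column_stack([np.repeat(fes.bin_centers[0],
                                              len(fes.bin_centers[1])),
                                    np.tile(fes.bin_centers[1],
                                            len(fes.bin_centers[0])),
                                    fes.F.ravel(), fes.counts.ravel()]),
                   header="theta_t_deg\ttheta_r_deg\tF_kJ_mol\tcount",
                   delimiter="\t", comments="")

        summary = {
            "config_hash": config_hash,
            "n_replicas": len(trajs),
            "n_frames": int(sum(len(t) for t in trajs)),
            "n_microstates": int(result["assignment"].n_clusters),
            "active_set_size": int(result["transition_model"].n_states),
            "n_macrostates": int(result["n_macrostates"]),
            "populations": result["populations"],
            "rates_per_us_ratio": result["rates_ratio_per_us"],
            "rates_per_us_logm": result["rates_logm_per_us"],
            "timescales_at_lag_ns": [
                float(x) if np.isfinite(x) else None
                for x in result["timescales_at_lag_ns"][:6]],
            "hmm_converged": bool(result["macrostate_model"].converged),
        }
        if ground_truth is not None:
            scheme_f, emit_f, _ = SCHEME_PRESETS[cfg["scheme"]]
            summary["generator_stationary"] = \
                scheme_f().stationary_distribution()
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True,
                      default=_json_default)
            fh.write("\n")
        logger.info("run complete: %s", outdir)
        return outdir
    finally:
        logger.removeHandler(handler)
        handler.close()
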