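"""Synthetic generators: jump-process statistics, emissions, umbrella
sampling, Langevin dynamics and lipid fields."""

import numpy as np
import pytest
from scipy import stats

from memorient.constants import KB
from memorient.geometry import lateral_rdf
from memorient.synthetic import (EmissionSpec, KineticScheme,
                                 anionic_gdp_scheme, anionic_emission_spec,
                                 anionic_gtp_scheme, emit_orientation,
                                 generate_lipid_field, popc_scheme,
                                 sample_umbrella_windows,
                                 scheme_from_populations,
                                 simulate_hidden_jump_process,
                                 simulate_langevin_on_potential)


# ---------------------------------------------------------------------------
# kinetic schemes
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("factory,target", [
    (anionic_gtp_scheme, (0.05, 0.05, 0.23, 0.67)),
    (anionic_gdp_scheme, (0.06, 0.06, 0.01, 0.87)),
    (popc_scheme, (0.09, 0.91)),
])
def test_preset_schemes_valid_and_stationary(factory, target):
    scheme = factory()
    Q = scheme.rate_matrix
    assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)
    off = Q - np.diag(np.diag(Q))
    assert np.all(off >= 0)
    assert scheme.is_irreducible()
    # overriding the slow direct rates perturbs the stationary split by <0.1%
    assert scheme.stationary_distribution() == pytest.approx(target, abs=1e-3)


def test_gtp_scheme_has_printed_direct_rates():
    Q = anionic_gtp_scheme().rate_matrix
    assert Q[2, 3] == pytest.approx(0.0027)
    assert Q[3, 2] == pytest.approx(0.00096)


def test_scheme_from_populations_detailed_balance():
    pi = (0.2, 0.3, 0.5)
    scheme = scheme_from_populations(pi, {(0, 1): 0.01, (1, 2): 0.02,
                                          (0, 2): 0.005})
    Q = scheme.rate_matrix
    for i in range(3):
        for j in range(3):
            if i != j:
                assert pi[i] * Q[i, j] == pytest.approx(pi[j] * Q[j, i])


def test_reducible_scheme_rejected_for_stationary_init():
    Q = np.array([[0.0, 0.0], [1.0, -1.0]])
    scheme = KineticScheme(rate_matrix=Q, state_labels=["sink", "b"])
    assert not scheme.is_irreducible()
    with pytest.raises(ValueError, match="reducible"):
        simulate_hidden_jump_process(scheme, 10.0, 15.0, init="stationary",
                                     seed=0)


# ---------------------------------------------------------------------------
# jump process
# ---------------------------------------------------------------------------

def test_absorbing_degenerate_case():
    Q = np.zeros((2, 2))
    scheme = KineticScheme(rate_matrix=Q, state_labels=["a", "b"])
    (path,) = simulate_hidden_jump_process(scheme, 100.0, 15.0, init=0, seed=3)
    assert np.all(path.frame_states == 0)


def test_invalid_dt_raises(two_state_scheme):
    with pytest.raises(ValueError, match="dt"):
        simulate_hidden_jump_process(two_state_scheme, 10.0, 0.0, seed=0)


def test_mean_dwell_time_two_state(two_state_scheme):
    """k = 0.01 /us symmetric: mean dwell 100 us within 3 SE."""
    paths = simulate_hidden_jump_process(two_state_scheme, 10_000.0, 15.0,
                                         n_replicas=1, init=0, seed=5)
    jt = paths[0].jump_times_us
    dwells = np.diff(jt)
    se = dwells.std(ddof=1) / np.sqrt(len(dwells))
    assert abs(dwells.mean() - 100.0) < 3 * se


def test_dwell_times_are_exponential():
    """KS test at alpha=0.01 on ~1e4 pooled dwell events."""
    Q = np.array([[-0.5, 0.5], [0.5, -0.5]])
    scheme = KineticScheme(rate_matrix=Q, state_labels=["a", "b"])
    paths = simulate_hidden_jump_process(scheme, 20_000.0, 15.0,
                                         n_replicas=1, init=0, seed=8)
    dwells = np.diff(paths[0].jump_times_us)
    assert len(dwells) > 8000
    _, p = stats.kstest(dwells, "expon", args=(0, 2.0))
    assert p > 0.01


def test_frame_fractions_match_stationary_4state():
    """Frame-label marginals of the printed-rate scheme reach the
    analytic stationary distribution within ~3 SE of the visit count."""
    scheme = anionic_gtp_scheme()
    paths = simulate_hidden_jump_process(scheme, 2000.0, 15.0, n_replicas=10,
                                         init="stationary", seed=12)
    frames = np.concatenate([p.frame_states for p in paths])
    frac = np.bincount(frames, minlength=4) / len(frames)
    pi = scheme.stationary_distribution()
    # the slowest state (exposed, dwell ~22 us) dominates the error budget
    assert frac == pytest.approx(pi, abs=0.03)


def test_jump_process_reproducible(two_state_scheme):
    a = simulate_hidden_jump_process(two_state_scheme, 500.0, 15.0,
                                     n_replicas=3, seed=42)
    b = simulate_hidden_jump_process(two_state_scheme, 500.0, 15.0,
                                     n_replicas=3, seed=42)
    for pa, pb in zip(a, b):
        assert np.array_equal(pa.jump_times_us, pb.jump_times_us)
        assert np.array_equal(pa.frame_states, pb.frame_states)
    c = simulate_hidden_jump_process(two_state_scheme, 500.0, 15.0,
                                     n_replicas=3, seed=43)
    assert not all(np.array_equal(pa.frame_states, pc.frame_states)
                   for pa, pc in zip(a, c))


# ---------------------------------------------------------------------------
# emissions
# ---------------------------------------------------------------------------

def test_emission_sigma_to_zero_hits_centers(two_state_scheme):
    spec = EmissionSpec(centers=[(30.0, -40.0), (120.0, 100.0)],
                        sigmas=[(1e-9, 1e-9), (1e-9, 1e-9)])
    (path,) = simulate_hidden_jump_process(two_state_scheme, 300.0, 15.0,
                                           init=0, seed=1)
    traj = emit_orientation(path, spec, seed=2)
    expect = spec.centers[path.frame_states]
    assert np.allclose(traj.theta_t_deg, expect[:, 0], atol=1e-6)
    assert np.allclose(traj.theta_r_deg, expect[:, 1], atol=1e-6)


def test_emission_wrapping_circular_mean():
    """Center at theta_r=175, sigma=10: circular mean of 1e5 samples
    recovers 175 within 3 SE despite wrapping."""
    Q = np.zeros((1, 1))
    scheme = KineticScheme(rate_matrix=Q, state_labels=["x"])
    (path,) = simulate_hidden_jump_process(scheme, 1.5e3, 15.0, init=0,
                                           seed=3)
    assert len(path.frame_states) >= 100_000
    spec = EmissionSpec(centers=[(90.0, 175.0)], sigmas=[(5.0, 10.0)])
    traj = emit_orientation(path, spec, seed=4)
    assert traj.theta_r_deg.min() > -180.0 and traj.theta_r_deg.max() <= 180.0
    rad = np.radians(traj.theta_r_deg)
    mean = np.degrees(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean()))
    se = 10.0 / np.sqrt(len(rad))
    assert abs((mean - 175.0 + 180.0) % 360.0 - 180.0) < 3 * se


def test_exposed_basin_emission_contained():
    """With sigma at basin-width/4, >=95% of exposed-state samples fall
    inside the theta_t 30-120 degree basin."""
    spec = anionic_emission_spec()
    Q = np.zeros((4, 4))
    scheme = KineticScheme(rate_matrix=Q, state_labels=list("abcd"))
    (path,) = simulate_hidden_jump_process(scheme, 750.0, 15.0, init=3,
                                           seed=6)
    traj = emit_orientation(path, spec, seed=7)
    inside = (traj.theta_t_deg >= 30.0) & (traj.theta_t_deg <= 120.0)
    assert inside.mean() >= 0.95


def test_emission_missing_state_raises(two_state_scheme):
    (path,) = simulate_hidden_jump_process(two_state_scheme, 300.0, 15.0,
                                           seed=1)
    spec = EmissionSpec(centers=[(30.0, 0.0)], sigmas=[(5.0, 5.0)])
    with pytest.raises(ValueError, match="cover"):
        emit_orientation(path, spec, seed=0)


# ---------------------------------------------------------------------------
# umbrella sampling
# ---------------------------------------------------------------------------

def test_umbrella_flat_pmf_means_at_centers():
    centers = np.array([1.0, 2.0, 3.0])
    ws = sample_umbrella_windows(lambda x: 0.0, centers, k_spring=1000.0,
                                 n_per_window=4000, seed=9)
    sigma = np.sqrt(KB * 310.0 / 1000.0)
    for c, s in zip(centers, ws.samples):
        se = sigma / np.sqrt(len(s))
        assert abs(s.mean() - c) < 3.5 * se
        assert s.std() == pytest.approx(sigma, rel=0.05)


def test_umbrella_harmonic_pmf_closed_form_posterior():
    """pmf = a/2 (x-x0)^2 under bias k/2 (x-c)^2: exact Gaussian with
    mean (a x0 + k c)/(a+k) and variance kT/(a+k)."""
    a, x0, k, T = 400.0, 1.0, 1000.0, 310.0
    centers = np.array([0.5, 1.5])
    ws = sample_umbrella_windows(lambda x: 0.5 * a * (x - x0) ** 2, centers,
                                 k_spring=k, n_per_window=8000,
                                 temperature=T, seed=10)
    var = KB * T / (a + k)
    for c, s in zip(centers, ws.samples):
        mean = (a * x0 + k * c) / (a + k)
        se = np.sqrt(var / len(s))
        assert abs(s.mean() - mean) < 3.5 * se
        assert s.var() == pytest.approx(var, rel=0.08)


def test_umbrella_nonfinite_pmf_raises():
    with pytest.raises(ValueError, match="finite"):
        sample_umbrella_windows(lambda x: np.inf if x > 1 else 0.0,
                                [1.0], n_per_window=10, seed=0)


def test_default_window_layout_spacing():
    """100 windows spaced 0.1 nm apart sample without gaps."""
    centers = np.arange(100) * 0.1 + 0.05
    ws = sample_umbrella_windows(lambda x: 0.0, centers, k_spring=1000.0,
                                 n_per_window=50, seed=1)
    assert len(ws.samples) == 100
    assert np.diff(ws.centers) == pytest.approx(0.1)


# ---------------------------------------------------------------------------
# Langevin engine
# ---------------------------------------------------------------------------

def test_langevin_zero_potential_zero_temperature_is_static():
    trace = simulate_langevin_on_potential(lambda x: 0.0, steps=100, dt=1e-3,
                                           temperature=0.0, x0=0.7, seed=0)
    assert np.allclose(trace, 0.7)


def test_langevin_harmonic_equipartition():
    """Sampled variance of an overdamped harmonic well is kT/a."""
    a, T = 10.0, 310.0
    trace = simulate_langevin_on_potential(
        lambda x: 0.5 * a * x * x, steps=200_000, dt=1e-3, temperature=T,
        friction=1.0, seed=13)
    burn = trace[2000:]
    var_true = KB * T / a
    # ~1000 effective samples given the 0.1 time-unit relaxation time
    assert burn.var() == pytest.approx(var_true, rel=0.15)


def test_langevin_divergence_names_dt():
    # either the stability pre-check or the runtime bound fires; both name dt
    with pytest.raises((RuntimeError, ValueError), match="dt"):
        simulate_langevin_on_potential(lambda x: -100.0 * x * x,
                                       steps=10_000, dt=5e-3,
                                       temperature=310.0, x0=1.0, seed=1,
                                       grid=(-60.0, 60.0, 2001), bound=50.0)
    with pytest.raises(RuntimeError, match="dt"):
        simulate_langevin_on_potential(lambda x: -2.0 * x * x,
                                       steps=100_000, dt=1e-3,
                                       temperature=310.0, x0=1.0, seed=1,
                                       grid=(-30.0, 30.0, 2001), bound=20.0)


# ---------------------------------------------------------------------------
# lipid fields
# ---------------------------------------------------------------------------

def test_lipid_field_mixed_single_species_rdf_flat():
    frames = generate_lipid_field((20.0, 20.0), {"DOPC": 1.0},
                                  n_lipids=3000, seed=14)
    r, g = lateral_rdf(frames, "DOPC", "DOPC", r_max=5.0, bin_width=0.5)
    assert np.all(np.abs(g[2:] - 1.0) < 0.1)


def test_lipid_field_two_phase_enrichment():
    frames = generate_lipid_field(
        (20.0, 20.0), {"DPPC": 0.5, "DOPS": 0.5}, domain_structure="two-phase",
        enriched_species="DOPS", enrichment=4.0, n_lipids=4000, seed=15)
    fr = frames[0]
    dops = fr.positions[fr.indices("DOPS")]
    in_stripe = (dops[:, 0] < 10.0).mean()
    # stripe fraction = enrichment/(enrichment+1) = 0.8
    assert in_stripe == pytest.approx(0.8, abs=0.03)
    dppc = fr.positions[fr.indices("DPPC")]
    assert (dppc[:, 0] < 10.0).mean() == pytest.approx(0.5, abs=0.04)


def test_lipid_field_fraction_validation():
    with pytest.raises(ValueError, match="sum to 1"):
        generate_lipid_field((10, 10), {"A": 0.6, "B": 0.6}, seed=0)


def test_raft_composition_counts():
    frames = generate_lipid_field(
        (30.0, 30.0), {"DPPC": 0.40, "DOPC": 0.25, "DOPS": 0.05,
                       "CHOL": 0.30}, n_lipids=2000, seed=16)
    fr = frames[0]
    assert len(fr.indices("DPPC")) == 800
    assert len(fr.indices("DOPC")) == 500
    assert len(fr.indices("DOPS")) == 100
    assert len(fr.indices("CHOL")) == 600
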