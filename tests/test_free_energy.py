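"""Free-energy estimators: Boltzmann FES, WHAM, block averaging,
well-tempered metadynamics and PT-MetaD exchange."""

import numpy as np
import pytest

from memorient.constants import KB
from memorient.free_energy import (BiasPotentialState, ReplicaState,
                                   UmbrellaWindowSet, block_convergence,
                                   boltzmann_fes_2d, ptmetad_acceptance,
                                   wham, wt_metad_fes, wt_metad_update)
from memorient.geometry import OrientationTrajectory
from memorient.synthetic import sample_umbrella_windows


def _traj_from_angles(tt, tr):
    n = len(tt)
    return OrientationTrajectory(time_ns=np.arange(n) * 15.0,
                                 theta_t_deg=np.asarray(tt, float),
                                 theta_r_deg=np.asarray(tr, float))


# ---------------------------------------------------------------------------
# Boltzmann FES
# ---------------------------------------------------------------------------

def test_fes_uniform_histogram_flat_zero():
    rng = np.random.default_rng(0)
    # fill every bin of a coarse grid evenly
    tt = np.tile(np.repeat(np.linspace(10, 170, 8), 8), 10)
    tr = np.tile(np.tile(np.linspace(-150, 150, 8), 8), 10)
    surf = boltzmann_fes_2d([_traj_from_angles(tt, tr)], bins=(8, 8),
                            ranges=((0, 180), (-180, 180)))
    occ = np.isfinite(surf.F)
    assert np.allclose(surf.F[occ], 0.0)


def test_fes_count_ratio_energy_difference():
    """Counts N and N/e at 310 K differ by exactly k_B T = 2.577 kJ/mol."""
    n1, n2 = 2718, 1000
    tt = np.concatenate([np.full(n1, 45.0), np.full(n2, 135.0)])
    tr = np.concatenate([np.full(n1, -90.0), np.full(n2, 90.0)])
    surf = boltzmann_fes_2d([_traj_from_angles(tt, tr)], bins=(2, 2),
                            temperature=310.0)
    vals = np.sort(surf.F[np.isfinite(surf.F)])
    dF = vals[1] - vals[0]
    assert dF == pytest.approx(KB * 310.0 * np.log(n1 / n2), abs=1e-12)
    assert dF == pytest.approx(2.577, abs=2e-3)


def test_fes_default_grid_and_empty_bins():
    rng = np.random.default_rng(1)
    tt = rng.uniform(60, 80, 500)
    tr = rng.uniform(-100, -60, 500)
    surf = boltzmann_fes_2d([_traj_from_angles(tt, tr)])
    assert surf.F.shape == (70, 70)
    assert np.isnan(surf.F).any()          # unexplored regions stay blank
    assert np.nanmin(surf.F) == 0.0
    assert np.nanmin(surf.F) == surf.occupied_min()
    assert np.all(surf.F[np.isfinite(surf.F)] >= 0.0)


def test_fes_single_occupied_bin():
    tt = np.full(50, 90.0)
    tr = np.full(50, 0.0)
    surf = boltzmann_fes_2d([_traj_from_angles(tt, tr)], bins=(10, 10))
    occ = np.isfinite(surf.F)
    assert occ.sum() == 1
    assert surf.F[occ][0] == 0.0


# ---------------------------------------------------------------------------
# WHAM
# ---------------------------------------------------------------------------

def test_wham_single_window_negligible_spring_is_histogram():
    rng = np.random.default_rng(2)
    samples = rng.normal(5.0, 0.5, 40_000)
    ws = UmbrellaWindowSet(centers=[5.0], k_spring=1e-9, temperature=310.0,
                           samples=[samples])
    mids, pmf, _ = wham(ws, n_bins=40)
    hist, edges = np.histogram(samples, bins=40,
                               range=(samples.min(), samples.max()))
    ref = -KB * 310.0 * np.log(np.where(hist > 0, hist, np.nan))
    ref -= np.nanmin(ref)
    mask = np.isfinite(pmf) & np.isfinite(ref)
    assert np.allclose(pmf[mask], ref[mask], atol=1e-6)


def test_wham_flat_pmf_recovered_flat():
    centers = np.arange(30) * 0.1
    ws = sample_umbrella_windows(lambda x: 0.0, centers, k_spring=1000.0,
                                 n_per_window=20000, seed=3)
    mids, pmf, _ = wham(ws)
    interior = (mids >= centers[0]) & (mids <= centers[-1]) & np.isfinite(pmf)
    # peak-to-peak inside the window-covered span (the global min-shift may
    # sit on a sparsely sampled edge bin outside it)
    # the window-offset random walk over 30 windows dominates; flat means
    # well below the thermal energy scale (kT = 2.58 kJ/mol)
    assert np.ptp(pmf[interior]) < 1.0


def test_wham_double_well_small_layout():
    """30-window exact-sampling fixture recovers the PMF shape."""
    def pmf_true(x):
        return 6.0 * (((x - 1.5) / 1.0) ** 2 - 1.0) ** 2
    centers = np.arange(30) * 0.1 + 0.05
    ws = sample_umbrella_windows(pmf_true, centers, k_spring=1000.0,
                                 n_per_window=5000, seed=4)
    mids, est, _ = wham(ws)
    mask = np.isfinite(est) & (mids >= centers[0]) & (mids <= centers[-1])
    truth = pmf_true(mids[mask])
    shift = np.mean(est[mask] - truth)
    rms = np.sqrt(np.mean((est[mask] - truth - shift) ** 2))
    assert rms < 0.35


def test_wham_nonoverlapping_windows_name_gap():
    rng = np.random.default_rng(5)
    ws = UmbrellaWindowSet(centers=[0.0, 5.0], k_spring=1000.0,
                           temperature=310.0,
                           samples=[rng.normal(0, 0.05, 200),
                                    rng.normal(5, 0.05, 200)])
    with pytest.raises(ValueError, match="do not overlap"):
        wham(ws)


def test_block_convergence_identical_blocks_zero_spread():
    rng = np.random.default_rng(6)
    block = rng.normal(1.0, 0.05, 400)
    ws = UmbrellaWindowSet(centers=[0.95, 1.05], k_spring=1000.0,
                           temperature=310.0,
                           samples=[np.tile(block, 3),
                                    np.tile(block + 0.1, 3)])
    mids, pmfs, spread = block_convergence(ws, n_blocks=3)
    assert np.nanmax(spread) == pytest.approx(0.0, abs=1e-9)


def test_block_convergence_spread_shrinks_with_samples():
    def pmf_true(x):
        return 4.0 * ((x - 1.0) ** 2 - 0.25) ** 2
    centers = np.arange(20) * 0.1 + 0.05
    spreads = []
    for n in (600, 38400):
        ws = sample_umbrella_windows(pmf_true, centers, k_spring=1000.0,
                                     n_per_window=n, seed=7)
        _, _, spread = block_convergence(ws, n_blocks=3)
        spreads.append(np.nanmedian(spread))
    # 64x more data: ~8x smaller Monte-Carlo spread (loose factor-4 band)
    assert spreads[1] < spreads[0] / 4.0


def test_block_convergence_too_few_samples():
    ws = UmbrellaWindowSet(centers=[1.0], k_spring=1000.0, temperature=310.0,
                           samples=[np.array([1.0, 1.01])])
    with pytest.raises(ValueError, match="at least"):
        block_convergence(ws, n_blocks=3)


# ---------------------------------------------------------------------------
# well-tempered metadynamics
# ---------------------------------------------------------------------------

def test_wt_height_rule():
    """First height is W0; a pre-existing bias of k_B DeltaT gives W0/e."""
    state = BiasPotentialState(sigma=[0.2], height0=1.2, delta_T=4340.0,
                               temperature=310.0)
    wt_metad_update(state, 0.5)
    assert state.heights[0] == pytest.approx(1.2)
    # deposit exactly k_B*DeltaT of bias at a point, then update there
    state2 = BiasPotentialState(sigma=[0.2], height0=1.2, delta_T=4340.0)
    state2.centers.append(np.array([0.5]))
    state2.heights.append(KB * 4340.0)
    wt_metad_update(state2, 0.5)
    assert state2.heights[-1] == pytest.approx(1.2 / np.e, rel=1e-12)


def test_bias_factor_relation():
    """gamma = 15 at 310 K corresponds to DeltaT = 4340 K."""
    state = BiasPotentialState(sigma=[0.1], height0=1.0, delta_T=4340.0,
                               temperature=310.0)
    assert state.gamma == pytest.approx(15.0, abs=1e-12)


def test_wt_update_validation():
    state = BiasPotentialState(sigma=[0.1], height0=1.0, delta_T=4340.0)
    with pytest.raises(ValueError, match="dimensionality"):
        wt_metad_update(state, [0.1, 0.2])
    bad = BiasPotentialState(sigma=[0.1], height0=1.0, delta_T=4340.0)
    bad.delta_T = -1.0
    with pytest.raises(ValueError, match="DeltaT"):
        wt_metad_update(bad, 0.1)


def test_wt_fes_no_gaussians_flat_and_gamma_guard():
    state = BiasPotentialState(sigma=[0.1], height0=1.0, delta_T=4340.0)
    surf = wt_metad_fes(state, np.linspace(-1, 1, 11))
    assert np.allclose(surf.F, 0.0)
    flat = BiasPotentialState(sigma=[0.1], height0=1.0, delta_T=4340.0)
    flat.delta_T = 0.0
    with pytest.raises(ValueError, match="gamma"):
        wt_metad_fes(flat, np.linspace(-1, 1, 5))


def test_wt_fes_single_gaussian_closed_form():
    state = BiasPotentialState(sigma=[0.25], height0=2.0, delta_T=4340.0,
                               temperature=310.0)
    wt_metad_update(state, 0.0)
    grid = np.linspace(-1.0, 1.0, 201)
    surf = wt_metad_fes(state, grid)
    gamma = state.gamma
    V = 2.0 * np.exp(-0.5 * (grid / 0.25) ** 2)
    expect = -(gamma / (gamma - 1.0)) * V
    expect -= expect.min()
    assert np.allclose(surf.F, expect, atol=1e-12)


def test_wt_bias_periodic_cv():
    state = BiasPotentialState(sigma=[0.3], height0=1.0, delta_T=4340.0,
                               periodic=[2 * np.pi])
    wt_metad_update(state, 3.0)
    # point at -3.1 is within 2*pi - 6.1 = 0.18 of the deposit
    near = state.bias_value(np.array([[-3.1]]))
    far = state.bias_value(np.array([[0.0]]))
    assert near > far


# ---------------------------------------------------------------------------
# PT-MetaD exchange
# ---------------------------------------------------------------------------

def test_ptmetad_identical_replicas():
    bias = BiasPotentialState(sigma=[0.1], height0=1.0, delta_T=4340.0)
    wt_metad_update(bias, 0.3)
    r = ReplicaState(temperature=310.0, energy=5.0, cv=[0.3], bias=bias)
    delta, acc = ptmetad_acceptance(r, r)
    assert delta == pytest.approx(0.0, abs=1e-12)
    assert acc == 1.0


def test_ptmetad_zero_bias_reduces_to_parallel_tempering():
    ri = ReplicaState(temperature=300.0, energy=10.0, cv=[0.0])
    rj = ReplicaState(temperature=400.0, energy=14.0, cv=[1.0])
    delta, _ = ptmetad_acceptance(ri, rj)
    expect = (1 / (KB * 300.0) - 1 / (KB * 400.0)) * (10.0 - 14.0)
    assert delta == pytest.approx(expect, abs=1e-12)


def test_ptmetad_hand_computed_bias_correction():
    """V_G^i = (1, 2) and V_G^j = (5, 3) kJ/mol at (s_i, s_j), equal
    temperatures: Delta - Delta_PT = (-1 + 2)/k_B T = +0.38797."""
    class TableBias:
        def __init__(self, table):
            self.table = table

        def bias_value(self, pts):
            x = float(np.atleast_2d(pts)[0, 0])
            return np.array([self.table[round(x)]])

    bi = TableBias({0: 1.0, 1: 2.0})
    bj = TableBias({1: 5.0, 0: 3.0})
    ri = ReplicaState(temperature=310.0, energy=7.0, cv=[0.0], bias=bi)
    rj = ReplicaState(temperature=310.0, energy=7.0, cv=[1.0], bias=bj)
    delta, _ = ptmetad_acceptance(ri, rj)
    assert delta == pytest.approx(0.38797, abs=5e-6)
    assert delta == pytest.approx(1.0 / (KB * 310.0), rel=1e-12)


def test_ptmetad_cv_dimension_mismatch():
    ri = ReplicaState(temperature=310.0, energy=0.0, cv=[0.0])
    rj = ReplicaState(temperature=310.0, energy=0.0, cv=[0.0, 1.0])
    with pytest.raises(ValueError, match="dimensionality"):
        ptmetad_acceptance(ri, rj)


def test_ptmetad_detailed_balance_two_replica_mc():
    """Two replicas over two sites with static biases: MC with local moves
    plus bias-corrected swaps reproduces the exact joint distribution."""
    rng = np.random.default_rng(8)
    U = np.array([0.0, 2.0])
    V = [np.array([0.0, 1.5]), np.array([0.8, 0.0])]   # static biases
    T = [310.0, 450.0]
    beta = [1.0 / (KB * t) for t in T]

    # exact joint stationary distribution over (x0, x1)
    joint = np.zeros((2, 2))
    for a in range(2):
        for b in range(2):
            joint[a, b] = np.exp(-beta[0] * (U[a] + V[0][a])
                                 - beta[1] * (U[b] + V[1][b]))
    joint /= joint.sum()

    x = [0, 0]
    counts = np.zeros((2, 2))
    n_sweeps = 40_000
    for _ in range(n_sweeps):
        for i in (0, 1):
            prop = 1 - x[i]
            dE = (U[prop] + V[i][prop]) - (U[x[i]] + V[i][x[i]])
            if rng.random() < np.exp(-beta[i] * dE):
                x[i] = prop
        ri = ReplicaState(temperature=T[0], energy=U[x[0]], cv=[float(x[0])])
        rj = ReplicaState(temperature=T[1], energy=U[x[1]], cv=[float(x[1])])
        ri.bias_at = lambda cv, i=0: float(V[0][int(round(float(np.atleast_1d(cv)[0])))])
        rj.bias_at = lambda cv, j=1: float(V[1][int(round(float(np.atleast_1d(cv)[0])))])
        _, acc = ptmetad_acceptance(ri, rj)
        if rng.random() < acc:
            x = [x[1], x[0]]
        counts[x[0], x[1]] += 1
    freq = counts / counts.sum()
    # 3-4 SE band given the sweep-to-sweep correlation
    assert np.max(np.abs(freq - joint)) < 0.015
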