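"""Generator assembly, closed-form propagation, and the reference solvers."""

import math

import numpy as np
import pytest
import scipy.integrate

from rlkin.coarse_grain import build_basins, macrorate_matrix
from rlkin.energy_model import Thermo, partition_function
from rlkin.errors import InputError
from rlkin.fixtures import make_random_connected
from rlkin.kinetics import (
    assemble,
    micro_basin_marginals,
    micro_generator,
    propagate,
    propagate_bimolecular,
    propagate_micro,
    read_rate_matrix,
    read_trajectory,
    stationary,
    write_rate_matrix,
    write_trajectory,
)
from rlkin.landscape import GraphLandscape
from rlkin.ligand_coupling import (
    RateModel,
    build_dimer_world,
    cross_rate_matrices,
    equilibrium_kd,
)

from conftest import UNIT_RT

RM = RateModel(A_R=1.0, A_a=2.0, theta=-2.0, thermo=UNIT_RT)


def small_system(seed=0, n=25):
    """Abstract monomer/dimer system used throughout (moderate rates)."""
    fx = make_random_connected(n=n, seed=seed)
    world = build_dimer_world(fx.landscape, fx.pocket, theta=RM.theta)
    mono_cg = build_basins(fx.landscape, UNIT_RT)
    dim_cg = build_basins(world, UNIT_RT)
    return fx, world, mono_cg, dim_cg


def test_assemble_two_state_block_structure():
    """n = m = 1: R(l0) = [[-l0 a, d], [l0 a, -d]]."""
    land = GraphLandscape({"a": 0.0, "b": -1.0}, {"a": ["b"]})
    world = build_dimer_world(land, {"a", "b"}, theta=RM.theta)
    mono_cg = build_basins(land, UNIT_RT)
    dim_cg = build_basins(world, UNIT_RT)
    l0 = 0.3
    Rm = assemble(mono_cg, dim_cg, None, RM, l0)
    a = RM.A_a  # alpha fully pocket-bearing
    d = RM.A_d * math.exp(UNIT_RT.beta * RM.theta)
    expected = np.array([[-l0 * a, d], [l0 * a, -d]])
    np.testing.assert_allclose(Rm.assembled, expected, rtol=1e-14)


def test_assemble_matches_naive_ode_sums():
    """The assembled matrix equals a hand-built one following the ODE term
    by term (off-diagonal rates plus the displayed diagonal drains)."""
    fx, world, mono_cg, dim_cg = small_system(seed=2)
    l0 = 0.7
    Rm = assemble(mono_cg, dim_cg, None, RM, l0)
    n, m = len(mono_cg), len(dim_cg)
    mono = macrorate_matrix(mono_cg, RM)  # [a, b] = r(alpha_a -> alpha_b)
    dim = macrorate_matrix(dim_cg, RM)
    assoc, dissoc = cross_rate_matrices(mono_cg, dim_cg, RM)
    R = np.zeros((n + m, n + m))
    for i in range(n):
        for k in range(n):
            if k != i:
                R[i, k] += mono[k, i]          # inflow alpha_k -> alpha_i
        for k in range(m):
            R[i, n + k] += dissoc[i, k]        # inflow L beta_k -> alpha_i
        R[i, i] = -sum(mono[i, k] for k in range(n) if k != i) - sum(
            l0 * assoc[k, i] for k in range(m)
        )
    for j in range(m):
        for k in range(n):
            R[n + j, k] += l0 * assoc[j, k]
        for k in range(m):
            if k != j:
                R[n + j, n + k] += dim[k, j]
        R[n + j, n + j] = -sum(dissoc[k, j] for k in range(n)) - sum(
            dim[j, k] for k in range(m) if k != j
        )
    np.testing.assert_allclose(Rm.assembled, R, rtol=1e-12, atol=1e-15)


@pytest.mark.parametrize("seed", range(5))
@pytest.mark.parametrize("l0", [0.0, 1e-3, 0.5, 10.0])
def test_generator_properties(seed, l0):
    """Zero column sums, non-negative off-diagonals, nonpositive spectrum,
    and detailed balance with the Boltzmann-with-ligand weights."""
    fx, world, mono_cg, dim_cg = small_system(seed=seed)
    Rm = assemble(mono_cg, dim_cg, None, RM, l0)
    R = Rm.assembled
    col = np.abs(R.sum(axis=0)).max()
    assert col <= 1e-12 * max(np.abs(R).max(), 1.0)
    off = R - np.diag(np.diag(R))
    assert off.min() >= 0
    if l0 > 0:
        pi = Rm.pi
        np.testing.assert_allclose(R * pi[None, :], (R * pi[None, :]).T, rtol=1e-9)
        s = np.sqrt(pi / pi.max())
        M = R * s[None, :] / s[:, None]
        w = np.linalg.eigvalsh(0.5 * (M + M.T))
        assert w.max() <= 1e-10 * np.abs(w).max()
        assert (np.abs(w) < 1e-10 * np.abs(w).max()).sum() == 1  # connected


def test_l0_zero_decouples_monomer_world():
    fx, world, mono_cg, dim_cg = small_system(seed=1)
    Rm = assemble(mono_cg, dim_cg, None, RM, 0.0)
    n = len(mono_cg)
    assert np.all(Rm.assembled[n:, :n] == 0.0)  # no association inflow
    c0 = np.zeros(Rm.size)
    c0[n:] = 1.0 / len(dim_cg.macrostates)  # start fully bound
    traj = propagate(Rm, c0, np.logspace(-2, 3, 40))
    bound = traj.concentrations[:, n:].sum(axis=1)
    assert np.all(np.diff(bound) <= 1e-12)  # complex mass only drains
    assert bound[-1] < 1e-6


def test_propagate_identity_at_t_zero():
    fx, world, mono_cg, dim_cg = small_system(seed=0)
    Rm = assemble(mono_cg, dim_cg, None, RM, 0.2)
    c0 = np.zeros(Rm.size)
    c0[0] = 1.0
    traj = propagate(Rm, c0, np.array([0.0, 1.0]))
    np.testing.assert_allclose(traj.concentrations[0], c0, atol=1e-12)
    with pytest.raises(InputError):
        propagate(Rm, -c0, np.array([1.0]))


def test_propagate_two_state_closed_form():
    """Textbook relaxation of a two-basin monomer system:
    c1(t) = pi1 + (c1(0) - pi1) exp(-(k1+k2) t)."""
    land = GraphLandscape(
        {"a": -1.0, "m": 1.5, "b": 0.0}, {"a": ["m"], "m": ["b"]}
    )
    cg = build_basins(land, UNIT_RT)
    assert len(cg) == 2
    Rm = assemble(cg, None, None, RM, 0.0)
    k1, k2 = Rm.assembled[1, 0], Rm.assembled[0, 1]
    c0 = np.array([1.0, 0.0])
    times = np.linspace(0.0, 30.0, 50)
    traj = propagate(Rm, c0, times)
    pi0 = k2 / (k1 + k2)
    expected = pi0 + (c0[0] - pi0) * np.exp(-(k1 + k2) * times)
    np.testing.assert_allclose(traj.concentrations[:, 0], expected, atol=1e-10)


def test_propagate_matches_stiff_integrator():
    fx, world, mono_cg, dim_cg = small_system(seed=4)
    Rm = assemble(mono_cg, dim_cg, None, RM, 0.4)
    c0 = np.zeros(Rm.size)
    c0[len(mono_cg) - 1] = 1.0
    times = np.logspace(-3, 2, 30)
    traj = propagate(Rm, c0, times)
    sol = scipy.integrate.solve_ivp(
        lambda _t, y: Rm.assembled @ y,
        (0.0, times[-1]),
        c0,
        method="LSODA",
        t_eval=times,
        rtol=1e-12,
        atol=1e-14,
    )
    assert sol.success
    assert np.abs(traj.concentrations - sol.y.T).max() < 1e-8


def test_stationary_equals_boltzmann_prediction():
    fx, world, mono_cg, dim_cg = small_system(seed=3)
    l0 = 0.05
    Rm = assemble(mono_cg, dim_cg, None, RM, l0)
    st = stationary(Rm)
    pi = Rm.pi / Rm.pi.sum()
    np.testing.assert_allclose(st, pi, rtol=1e-8, atol=1e-14)


def test_stationary_l0_zero_is_monomer_boltzmann():
    fx, world, mono_cg, dim_cg = small_system(seed=0)
    Rm = assemble(mono_cg, dim_cg, None, RM, 0.0)
    st = stationary(Rm)
    n = len(mono_cg)
    z = np.array([m.Z for m in mono_cg.macrostates])
    np.testing.assert_allclose(st[:n], z / z.sum(), rtol=1e-8)
    np.testing.assert_allclose(st[n:], 0.0, atol=1e-12)


def test_stationary_symmetric_double_basin_is_half_half():
    land = GraphLandscape(
        {"a": -1.0, "m1": 1.0, "m2": 1.0, "b": -1.0},
        {"a": ["m1"], "m1": ["m2"], "m2": ["b"]},
    )
    cg = build_basins(land, UNIT_RT)
    assert len(cg) == 2 and cg.macrostates[0].Z == cg.macrostates[1].Z
    Rm = assemble(cg, None, None, RM, 0.0)
    np.testing.assert_allclose(stationary(Rm), [0.5, 0.5], rtol=1e-10)


def test_equilibrium_bound_fraction_closed_form():
    """Stationary bound fraction equals l0 / (l0 + Kd_eff) with
    Kd_eff = exp(b theta) Z[X] / Z[X+]."""
    fx, world, mono_cg, dim_cg = small_system(seed=5)
    kd = equilibrium_kd(RM.theta, fx.landscape, world, UNIT_RT)
    for l0 in (1e-3, 0.1, 1.0, 100.0):
        Rm = assemble(mono_cg, dim_cg, None, RM, l0)
        st = stationary(Rm)
        bound = st[len(mono_cg) :].sum()
        assert bound == pytest.approx(l0 / (l0 + kd), rel=1e-8)


# ---------------------------------------------------------------------------
# micro-vs-macro
# ---------------------------------------------------------------------------


def test_micro_and_macro_identical_when_basins_are_singletons():
    """On a flat landscape every state is its own basin and the coarse
    graining is the identity: trajectories coincide exactly."""
    n = 8
    energies = {f"s{i}": 0.0 for i in range(n)}
    adj = {f"s{i}": [f"s{i+1}"] for i in range(n - 1)}
    land = GraphLandscape(energies, adj)
    pocket = {"s2", "s3"}
    world = build_dimer_world(land, pocket, theta=RM.theta)
    mono_cg = build_basins(land, UNIT_RT)
    dim_cg = build_basins(world, UNIT_RT)
    assert all(len(m) == 1 for m in mono_cg.macrostates)
    l0 = 0.3
    c0 = np.zeros(n + len(pocket))
    c0[0] = 1.0
    times = np.logspace(-2, 2, 25)
    micro = propagate_micro(land, world, RM, l0, c0, times)
    marg = micro_basin_marginals(micro, land, world, mono_cg, dim_cg)
    # macro initial condition: the basin holding s0
    c0_macro = np.zeros(len(mono_cg) + len(dim_cg))
    c0_macro[mono_cg.assignment["s0"]] = 1.0
    macro = propagate(assemble(mono_cg, dim_cg, None, RM, l0), c0_macro, times)
    np.testing.assert_allclose(macro.concentrations, marg, rtol=1e-9, atol=1e-12)


def test_micro_and_macro_share_stationary_basin_marginals():
    fx, world, mono_cg, dim_cg = small_system(seed=6, n=50)
    l0 = 0.2
    micro_Rm = micro_generator(fx.landscape, world, RM, l0)
    macro_Rm = assemble(mono_cg, dim_cg, None, RM, l0)
    micro_st = stationary(micro_Rm)
    macro_st = stationary(macro_Rm)
    # sum the micro stationary vector over basins
    summed = np.zeros(macro_Rm.size)
    for i, x in enumerate(fx.landscape.states):
        summed[mono_cg.assignment[x]] += micro_st[i]
    off = len(fx.landscape.states)
    for j, x in enumerate(world.states):
        summed[len(mono_cg) + dim_cg.assignment[x]] += micro_st[off + j]
    np.testing.assert_allclose(macro_st, summed, rtol=1e-10, atol=1e-14)


def _double_funnel_50():
    """Two hub-and-spoke wells joined through one gateway saddle.

    The gateway descends into fifteen parallel mid states of the deeper
    well, so a crossing walker commits to the target basin instead of
    recrossing; intra-basin relaxation is a single downhill move.  Under
    this timescale separation the gradient-basin approximation is accurate.
    """
    energies = {"hubA": -4.0, "hubB": -5.0, "gate": 2.0}
    adj = {"gate": ["hubA"]}
    for i in range(15):
        energies[f"mid{i:02d}"] = -4.5
        adj[f"mid{i:02d}"] = ["gate", "hubB"]
    for i in range(24):
        energies[f"spA{i:02d}"] = -1.5
        adj[f"spA{i:02d}"] = ["hubA"]
    for i in range(8):
        energies[f"spB{i:02d}"] = -2.0
        adj[f"spB{i:02d}"] = ["hubB"]
    land = GraphLandscape(energies, adj)
    pocket = (
        {"hubB"}
        | {f"spB{i:02d}" for i in range(8)}
        | {f"mid{i:02d}" for i in range(15)}
    )
    return land, pocket


def test_macro_tracks_micro_after_intra_basin_relaxation():
    """Beyond the intra-basin relaxation time (a single downhill move here)
    the coarse-grained trajectory follows the micro basin marginals within
    5% on a 50-state double-funnel landscape."""
    land, pocket = _double_funnel_50()
    world = build_dimer_world(land, pocket, theta=RM.theta)
    mono_cg = build_basins(land, UNIT_RT)
    dim_cg = build_basins(world, UNIT_RT)
    assert len(land.states) == 50 and len(mono_cg) == 2
    l0 = 0.2
    c0 = np.zeros(len(land.states) + len(world.states))
    c0[list(land.states).index("spA10")] = 1.0
    times = np.logspace(1, 5.5, 40)  # from ~10x the intra-basin time
    micro = propagate_micro(land, world, RM, l0, c0, times)
    marg = micro_basin_marginals(micro, land, world, mono_cg, dim_cg)
    c0m = np.zeros(len(mono_cg) + len(dim_cg))
    c0m[mono_cg.assignment["spA10"]] = 1.0
    macro = propagate(assemble(mono_cg, dim_cg, None, RM, l0), c0m, times)
    assert np.abs(macro.concentrations - marg).max() < 0.05


def test_micro_size_guard():
    fx, world, mono_cg, dim_cg = small_system(seed=0)
    with pytest.raises(InputError):
        micro_generator(fx.landscape, world, RM, 0.1, max_states=3)


# ---------------------------------------------------------------------------
# bimolecular reference
# ---------------------------------------------------------------------------


def _pfo_vs_bimolecular_deviation(ratio: float, seed: int = 7) -> float:
    fx = make_random_connected(n=15, seed=seed)
    world = build_dimer_world(fx.landscape, fx.pocket, theta=RM.theta)
    N, M = len(fx.landscape.states), len(world.states)
    l0 = 1.0
    rna_total = l0 / ratio
    c0 = np.zeros(N + M)
    c0[0] = rna_total
    times = np.logspace(-2, math.log10(50.0), 25)
    pfo = propagate_micro(fx.landscape, world, RM, l0, c0, times)
    bim, ligand = propagate_bimolecular(fx.landscape, world, RM, l0, c0, times)
    return float(np.abs(pfo.concentrations - bim.concentrations).max() / rna_total)


def test_pseudo_first_order_error_shrinks_with_ligand_excess():
    """The ligand-excess approximation improves monotonically with the
    excess ratio and is below 1e-4 relative at a 1e5-fold excess."""
    devs = [_pfo_vs_bimolecular_deviation(r) for r in (1e2, 1e3, 1e4, 1e5)]
    assert all(d1 > d2 for d1, d2 in zip(devs, devs[1:]))
    assert devs[-1] < 1e-4


def test_bimolecular_ligand_constant_without_rna():
    fx = make_random_connected(n=10, seed=8)
    world = build_dimer_world(fx.landscape, fx.pocket, theta=RM.theta)
    N, M = len(fx.landscape.states), len(world.states)
    c0 = np.zeros(N + M)
    c0[0] = 1e-30
    times = np.linspace(0.0, 10.0, 10)
    _, ligand = propagate_bimolecular(fx.landscape, world, RM, 1.0, c0, times)
    assert np.abs(ligand - 1.0).max() < 1e-12


# ---------------------------------------------------------------------------
# file round trips
# ---------------------------------------------------------------------------


def test_rate_matrix_and_trajectory_round_trip(tmp_path):
    fx, world, mono_cg, dim_cg = small_system(seed=0)
    Rm = assemble(mono_cg, dim_cg, None, RM, 0.25)
    p = tmp_path / "rates.tsv"
    write_rate_matrix(p, Rm)
    R2, l0, n, m = read_rate_matrix(p)
    assert (l0, n, m) == (0.25, Rm.n, Rm.m)
    np.testing.assert_allclose(R2, Rm.assembled, rtol=1e-11, atol=1e-18)
    c0 = np.zeros(Rm.size)
    c0[0] = 1.0
    traj = propagate(Rm, c0, np.logspace(-2, 2, 10))
    p2 = tmp_path / "traj.trk"
    write_trajectory(p2, traj, header="demo")
    traj2 = read_trajectory(p2)
    assert traj2.n_monomer == traj.n_monomer
    np.testing.assert_allclose(traj2.concentrations, traj.concentrations, rtol=1e-7)
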