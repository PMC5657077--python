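"""Shared fixtures and independent oracles for the test-suite.

Oracles here are deliberately written as straightforward brute-force code,
independent of the package internals they are used to check.
"""

from __future__ import annotations

import math

import pytest

from rlkin.energy_model import GAS_CONSTANT, PairStackEnergy, Thermo
from rlkin.fixtures import (
    TOY_SWITCH_POCKET,
    TOY_SWITCH_SEQ,
    make_random_connected,
)
from rlkin.coarse_grain import build_basins
from rlkin.landscape import GraphLandscape, landscape_from_enumeration
from rlkin.ligand_coupling import PocketConstraint, RateModel, build_dimer_world

#: Thermodynamic state with RT = 1 kcal/mol, convenient for hand values.
UNIT_RT = Thermo(1.0 / GAS_CONSTANT)


@pytest.fixture(scope="session")
def thermo_unit() -> Thermo:
    return UNIT_RT


@pytest.fixture(scope="session")
def toy_switch():
    """Fully assembled toy-switch system (shared, treated as read-only)."""
    thermo = Thermo(313.15)
    model = PairStackEnergy()
    landscape = landscape_from_enumeration(TOY_SWITCH_SEQ, model)
    rate_model = RateModel(A_R=1e6, A_a=600.0, theta=-9.59, thermo=thermo)
    world = build_dimer_world(
        landscape, PocketConstraint(TOY_SWITCH_POCKET), rate_model.theta
    )
    return {
        "seq": TOY_SWITCH_SEQ,
        "thermo": thermo,
        "model": model,
        "rate_model": rate_model,
        "landscape": landscape,
        "monomer_cg": build_basins(landscape, thermo),
        "world": world,
        "dimer_cg": build_basins(world, thermo),
    }


@pytest.fixture
def chain3(thermo_unit):
    """Three-state chain x - y - z with energies (0, 1, -1)."""
    return GraphLandscape({"x": 0.0, "y": 1.0, "z": -1.0}, {"x": ["y"], "y": ["z"]})


def random_fixture_systems(n_fixtures: int = 20, n_states: int = 25):
    """Seeded random landscapes with pocket subsets (study conditions for
    the invariance checks)."""
    out = []
    for seed in range(n_fixtures):
        fx = make_random_connected(n=n_states, seed=seed)
        out.append(fx)
    return out


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

_COMPLEMENT = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def oracle_all_structures(seq: str, nolp: bool = False) -> set[frozenset]:
    """All valid pair sets of ``seq`` by brute force over pair subsets.

    Candidate pairs are every complementary (i, j) with j - i >= 4; subsets
    are grown pair by pair with compatibility filtering (shared positions,
    crossings), then the noLP filter is applied to the complete set.
    """
    candidates = [
        (i, j)
        for i in range(1, len(seq) + 1)
        for j in range(i + 4, len(seq) + 1)
        if (seq[i - 1], seq[j - 1]) in _COMPLEMENT
    ]

    def compatible(p, q):
        i, j = p
        k, l = q
        if {i, j} & {k, l}:
            return False
        return not ((i < k < j < l) or (k < i < l < j))

    results: set[frozenset] = set()

    def grow(chosen: tuple, start: int):
        results.add(frozenset(chosen))
        for idx in range(start, len(candidates)):
            p = candidates[idx]
            if all(compatible(p, q) for q in chosen):
                grow(chosen + (p,), idx + 1)

    grow((), 0)
    if nolp:
        results = {
            ps
            for ps in results
            if all(
                (i - 1, j + 1) in ps or (i + 1, j - 1) in ps for i, j in ps
            )
        }
    return results


def oracle_steepest_descent(energies: dict, adjacency: dict, key=str) -> dict:
    """Exhaustive steepest-descent basin labels on an explicit graph.

    ``adjacency`` must be symmetric.  Ties among equally low neighbors break
    on ``key`` (the deterministic ordering convention of the landscape
    under test).
    """
    labels = {}
    for x0 in energies:
        x = x0
        while True:
            lower = [
                y for y in adjacency[x] if round(energies[y], 9) < round(energies[x], 9)
            ]
            if not lower:
                break
            x = min(lower, key=lambda y: (round(energies[y], 9), key(y)))
        labels[x0] = x
    return labels


def oracle_macrorate(
    alpha_members, beta_members, energies: dict, adjacency: dict, A: float, beta_inv_T: float
) -> float:
    """Naive double-loop macrorate: sum Pr[x|alpha] k(x->y) over all pairs."""
    zs = [math.exp(-beta_inv_T * energies[x]) for x in alpha_members]
    z_alpha = math.fsum(zs)
    total = 0.0
    beta_set = set(beta_members)
    for x, wx in zip(alpha_members, zs):
        for y in adjacency[x]:
            if y in beta_set:
                k = A * math.exp(
                    -beta_inv_T * max(0.0, energies[y] - energies[x])
                )
                total += (wx / z_alpha) * k
    return total


def graph_of(landscape) -> tuple[dict, dict]:
    """Explicit (energies, adjacency) view of a landscape for the oracles."""
    energies = {x: landscape.energy(x) for x in landscape.states}
    adjacency = {x: list(landscape.neighbors(x)) for x in landscape.states}
    return energies, adjacency
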