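"""Deterministic fixture landscapes with planted ground truth.

These generators produce the study conditions for the test-suite and the
demos: small abstract energy landscapes whose basins, barriers, and pocket
subsets are known by construction, and a toy switch sequence whose full
structure space is exhaustively enumerable.  Everything is deterministic
given the seed; the planted answers ship alongside the landscape so tests
never have to trust the code under test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .landscape import GraphLandscape

KINDS = ("double_well", "staircase", "random_connected", "toy_switch")


@dataclass
class AbstractLandscapeFixture:
    """A graph landscape plus its planted answers.

    ``answer`` holds kind-specific ground truth (basin membership keyed by
    local minimum, barriers, pocket subset, connection sets, ...), computed
    at construction time independently of the coarse-graining code.
    """

    kind: str
    seed: int
    landscape: GraphLandscape
    pocket: tuple = ()
    answer: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "kind": self.kind,
            "seed": self.seed,
            "nodes": {str(x): self.landscape.energy(x) for x in self.landscape.states},
            "edges": sorted(
                [sorted([str(a), str(b)]) for a, b in self.landscape.edges()]
            ),
            "pocket": sorted(str(x) for x in self.pocket),
            "answer": self.answer,
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def _steepest_descent_labels(energies: dict, adj: dict) -> dict:
    """Plain exhaustive steepest-descent labeling (fixture-side oracle)."""
    def walk(x):
        while True:
            lower = [y for y in adj[x] if round(energies[y], 9) < round(energies[x], 9)]
            if not lower:
                return x
            x = min(lower, key=lambda y: (round(energies[y], 9), str(y)))

    return {x: walk(x) for x in energies}


def _basin_answer(energies: dict, adj: dict) -> dict:
    labels = _steepest_descent_labels(energies, adj)
    basins: dict[str, list[str]] = {}
    for x, m in labels.items():
        basins.setdefault(str(m), []).append(str(x))
    return {m: sorted(ms) for m, ms in basins.items()}


def make_double_well(barrier: float = 0.5, seed: int = 0) -> AbstractLandscapeFixture:
    """A five-state chain with two planted wells.

    The shallow well bottoms out at -1.0, the deep one at -2.0; the single
    ridge state sits ``barrier`` kcal/mol above the shallow minimum, so
    ``merge_shallow`` with ``minh > barrier`` collapses the landscape to one
    macrostate.
    """
    if barrier <= 0:
        raise InputError("barrier must be positive")
    energies = {
        "w0": -0.5,
        "w1": -1.0,
        "ridge": -1.0 + barrier,
        "v1": -2.0,
        "v0": -1.2,
    }
    adj = {"w0": ["w1"], "w1": ["ridge"], "ridge": ["v1"], "v1": ["v0"]}
    landscape = GraphLandscape(energies, adj)
    full_adj = {x: set(landscape.neighbors(x)) for x in landscape.states}
    answer = {
        "basins": _basin_answer(energies, full_adj),
        "barrier_shallow": barrier,
        "n_basins": 2,
        "merged_n_basins_if_minh_exceeds_barrier": 1,
    }
    return AbstractLandscapeFixture("double_well", seed, landscape, (), answer)


def make_staircase(seed: int = 0) -> AbstractLandscapeFixture:
    """A descending 1-D staircase with one extra state above the band.

    The explored part covers energies up to 1.0; the extra state ``x`` sits
    two basins away, reachable only through the planted ridge sequence
    ``x - rB - mA - rA``.  A high dead-end branch hangs off ``rB`` so that a
    flooding search must prefer the low route.
    """
    energies = {
        "e0": 0.0,
        "e1": 0.5,
        "e2": 1.0,
        "rA": 2.5,
        "mA": 1.5,
        "rB": 3.0,
        "x": 3.5,
        "dead": 6.0,
    }
    adj = {
        "e0": ["e1"],
        "e1": ["e2"],
        "e2": ["rA"],
        "rA": ["mA"],
        "mA": ["rB"],
        "rB": ["x", "dead"],
    }
    landscape = GraphLandscape(energies, adj)
    answer = {
        "explored": ["e0", "e1", "e2"],
        "extra": "x",
        "connection": ["x", "rB", "mA", "rA"],
    }
    return AbstractLandscapeFixture("staircase", seed, landscape, (), answer)


def make_random_connected(
    n: int = 30, seed: int = 0, pocket_prob: float = 0.4
) -> AbstractLandscapeFixture:
    """A random connected landscape with a random pocket subset.

    Built from a random spanning tree plus ``~n/2`` extra edges; energies
    are uniform on [-3, 3] kcal/mol, rounded to 3 decimals (well above the
    1e-9 comparison resolution).  The pocket subset marks each state with
    probability ``pocket_prob`` and is forced non-empty.  Basin labels in
    the answer come from exhaustive steepest descent at build time.
    """
    if n < 2:
        raise InputError("need at least two states")
    rng = np.random.default_rng(seed)
    names = [f"s{i:03d}" for i in range(n)]
    energies = {x: round(float(e), 3) for x, e in zip(names, rng.uniform(-3, 3, n))}
    adj: dict[str, set[str]] = {x: set() for x in names}
    for i in range(1, n):
        j = int(rng.integers(0, i))
        adj[names[i]].add(names[j])
    for _ in range(n // 2):
        i, j = rng.integers(0, n, 2)
        if i != j:
            adj[names[int(i)]].add(names[int(j)])
    landscape = GraphLandscape(energies, adj)
    pocket = tuple(x for x in names if rng.random() < pocket_prob)
    if not pocket:
        pocket = (min(names, key=lambda x: energies[x]),)
    full_adj = {x: set(landscape.neighbors(x)) for x in landscape.states}
    answer = {"basins": _basin_answer(energies, full_adj)}
    return AbstractLandscapeFixture("random_connected", seed, landscape, pocket, answer)


#: Toy switch: two mutually exclusive hairpins share the middle C-stretch;
#: the 5' stem is the designated binding pocket.  The full structure space
#: under the built-in energy model is small enough to enumerate exhaustively.
TOY_SWITCH_SEQ = "GGGAAACCCAAGGGAAACCC"
TOY_SWITCH_POCKET = "(((...)))..........."


def make_toy_switch(seed: int = 0) -> dict:
    """The toy switch sequence, pocket constraint, and basic counts.

    Validated by exhaustive enumeration at build time: both the monomer
    world and the pocket-constrained world are non-empty.
    """
    from .energy_model import PairStackEnergy
    from .ligand_coupling import PocketConstraint, has_pocket
    from .structure_space import enumerate_structures

    model = PairStackEnergy()
    entries = enumerate_structures(TOY_SWITCH_SEQ, model, band=None)
    constraint = PocketConstraint(TOY_SWITCH_POCKET)
    pocket_count = sum(1 for st, _ in entries if has_pocket(st, constraint))
    if pocket_count == 0 or pocket_count == len(entries):
        raise InputError("toy switch pocket must be a proper non-empty subset")
    return {
        "sequence": TOY_SWITCH_SEQ,
        "pocket": TOY_SWITCH_POCKET,
        "n_structures": len(entries),
        "n_pocket_structures": pocket_count,
    }


def make_fixture(kind: str, params: dict | None = None, seed: int = 0):
    """Dispatch to one of the fixture generators by kind."""
    params = dict(params or {})
    if kind == "double_well":
        return make_double_well(seed=seed, **params)
    if kind == "staircase":
        return make_staircase(seed=seed, **params)
    if kind == "random_connected":
        return make_random_connected(seed=seed, **params)
    if kind == "toy_switch":
        return make_toy_switch(seed=seed, **params)
    raise InputError(f"unknown fixture kind {kind!r}; choose from {KINDS}")
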