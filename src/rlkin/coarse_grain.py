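"""Gradient-basin coarse graining of an energy landscape.

Every microstate is assigned to the basin of the local minimum reached by
its gradient walk (repeatedly stepping to the strictly lowest-energy
neighbor, ties broken by the landscape's deterministic sort key).  Basins
become the macrostates of the coarse-grained Markov process; the rate from
basin ``alpha`` to basin ``beta`` is the Boltzmann-weighted sum of
Metropolis microrates over the basin boundary,

    r(alpha -> beta) = sum_{x in alpha, y in beta} Pr[x | alpha] k(x -> y).

Because the microrates satisfy detailed balance, so do the macrorates:
``Z[alpha] r(alpha -> beta) = Z[beta] r(beta -> alpha)``.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

from .energy_model import Thermo, boltzmann_weights, partition_function
from .errors import ConnectivityError, InputError
from .landscape import Landscape
from .rate_model import RateModel, metropolis


def _res(e: float) -> float:
    """Energy rounded to the comparison resolution."""
    return round(e, 9)


@dataclass(frozen=True)
class Macrostate:
    """One gradient basin: its members, local minimum, and partition function."""

    id: int
    members: tuple
    local_min: object
    Z: float

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, x) -> bool:
        return x in set(self.members)


class CoarseGraining:
    """Partition of a landscape into gradient-basin macrostates.

    Macrostates are ordered (and numbered) by local-minimum energy
    ascending, ties broken by the sort key of the minimum.
    """

    def __init__(self, landscape: Landscape, macrostates: list[Macrostate]):
        self.landscape = landscape
        self.macrostates = macrostates
        self.assignment: dict = {}
        for m in macrostates:
            for x in m.members:
                self.assignment[x] = m.id

    def __len__(self) -> int:
        return len(self.macrostates)

    def macrostate_of(self, x) -> Macrostate:
        return self.macrostates[self.assignment[x]]

    @property
    def total_Z(self) -> float:
        return float(sum(m.Z for m in self.macrostates))


def _descend_step(x, landscape: Landscape):
    """Lowest strictly-lower neighbor of ``x``, or ``None`` at a minimum."""
    ex = _res(landscape.energy(x))
    best = None
    best_key = None
    for y in landscape.neighbors(x):
        ey = _res(landscape.energy(y))
        if ey >= ex:
            continue
        key = (ey, landscape.sort_key(y))
        if best_key is None or key < best_key:
            best, best_key = y, key
    return best


def gradient_walk(x, landscape: Landscape):
    """Follow steepest descent from ``x`` to its local minimum.

    At each step the walk moves to the neighbor of strictly lowest energy
    (deterministic tie-break); it stops at the first microstate with no
    strictly lower neighbor.  Terminates because the energy strictly
    decreases.
    """
    while True:
        y = _descend_step(x, landscape)
        if y is None:
            return x
        x = y


def build_basins(landscape: Landscape, thermo: Thermo) -> CoarseGraining:
    """Decompose a landscape into gradient basins.

    Walks are memoized with path compression, so each microstate is visited
    O(1) times beyond its own descent.
    """
    minimum: dict = {}
    for x0 in landscape.states:
        path = []
        x = x0
        while x not in minimum:
            y = _descend_step(x, landscape)
            if y is None:
                minimum[x] = x
                break
            path.append(x)
            x = y
        m = minimum[x]
        for s in path:
            minimum[s] = m

    groups: dict = {}
    for x, m in minimum.items():
        groups.setdefault(m, []).append(x)

    order = sorted(groups, key=lambda m: (_res(landscape.energy(m)), landscape.sort_key(m)))
    macrostates = []
    for idx, m in enumerate(order):
        members = tuple(sorted(groups[m], key=landscape.sort_key))
        z = partition_function((landscape.energy(x) for x in members), thermo)
        if z <= 0.0:
            raise InputError("macrostate with zero partition function")
        macrostates.append(Macrostate(idx, members, m, z))
    return CoarseGraining(landscape, macrostates)


def macrorate(
    alpha: Macrostate, beta: Macrostate, landscape: Landscape, rate_model: RateModel
) -> float:
    """Macrorate constant ``r(alpha -> beta)`` between two basins (1/s).

    Zero when no elementary move crosses the boundary.
    """
    if alpha.id == beta.id:
        raise InputError("macrorate requires two distinct macrostates")
    in_beta = set(beta.members)
    weights = boltzmann_weights(
        [landscape.energy(x) for x in alpha.members], rate_model.thermo
    )
    total = 0.0
    for x, w in zip(alpha.members, weights):
        ex = landscape.energy(x)
        for y in landscape.neighbors(x):
            if y in in_beta:
                total += w * metropolis(ex, landscape.energy(y), rate_model.A_R, rate_model.beta)
    return float(total)


def macrorate_matrix(cg: CoarseGraining, rate_model: RateModel) -> np.ndarray:
    """All intra-world macrorates as an ``(n, n)`` array, zero diagonal.

    Entry ``[a, b]`` is ``r(alpha_a -> alpha_b)``.  One sweep over the move
    graph; equivalent to calling :func:`macrorate` for every ordered pair.
    """
    n = len(cg)
    landscape = cg.landscape
    weights: dict = {}
    for m in cg.macrostates:
        w = boltzmann_weights([landscape.energy(x) for x in m.members], rate_model.thermo)
        for x, wx in zip(m.members, w):
            weights[x] = wx
    R = np.zeros((n, n))
    for x in landscape.states:
        a = cg.assignment[x]
        ex = landscape.energy(x)
        wx = weights[x]
        for y in landscape.neighbors(x):
            b = cg.assignment[y]
            if b != a:
                R[a, b] += wx * metropolis(ex, landscape.energy(y), rate_model.A_R, rate_model.beta)
    return R


def flood_connect(
    extra,
    explored: Landscape,
    *,
    level_cap_offset: float = 10.0,
) -> list:
    """Connect one extra microstate to an explored landscape by flooding.

    Starting from ``extra`` (typically a structure of interest above the
    enumerated energy band, such as the open chain), the heuristic explores
    the unrestricted move graph in order of the lowest saddle reachable so
    far — i.e. it floods into neighboring basins whenever their entry point
    lies below the current flood level, always descending first — and stops
    as soon as it touches a microstate already inside ``explored``.  The
    returned list of microstates (including ``extra``, excluding members of
    ``explored``) forms a neighborhood path from ``extra`` into the explored
    set, so adding them keeps the landscape connected.

    The flood level is capped at the highest explored energy plus
    ``level_cap_offset`` kcal/mol; exceeding it raises
    :class:`ConnectivityError`.
    """
    if extra in explored:
        raise InputError("extra microstate is already part of the landscape")
    cap = max(explored.energy(x) for x in explored.states) + level_cap_offset

    e0 = explored.full_energy(extra)
    if e0 > cap:
        raise ConnectivityError(
            f"start energy {e0:.3f} exceeds the flood level cap {cap:.3f}"
        )
    # best-first search minimizing the maximum energy along the path
    # (the lowest saddle route), then the current energy, then the key
    start_key = (_res(e0), _res(e0), explored.sort_key(extra))
    heap = [(start_key, extra)]
    parent: dict = {extra: None}
    best_seen = {extra: _res(e0)}
    while heap:
        (saddle, _, _), x = heapq.heappop(heap)
        if saddle > best_seen.get(x, np.inf):
            continue
        if x in explored:
            path = []
            cur = parent[x]
            while cur is not None:
                path.append(cur)
                cur = parent[cur]
            return list(reversed(path))
        for y in explored.full_neighbors(x):
            ey = _res(explored.full_energy(y))
            if ey > cap:
                continue
            new_saddle = max(saddle, ey)
            if new_saddle < best_seen.get(y, np.inf):
                best_seen[y] = new_saddle
                parent[y] = x
                heapq.heappush(heap, ((new_saddle, ey, explored.sort_key(y)), y))
    raise ConnectivityError(
        f"no path from {extra!r} into the explored landscape below the "
        f"flood level cap {cap:.3f} kcal/mol"
    )


def merge_shallow(cg: CoarseGraining, minh: float, thermo: Thermo) -> CoarseGraining:
    """Merge shallow basins into deeper neighbors (optional post-processing).

    A basin whose lowest saddle towards a deeper adjacent basin lies less
    than ``minh`` kcal/mol above its own local minimum is absorbed by that
    neighbor; repeated to a fixpoint.  ``minh = 0`` is the identity.  Total
    partition function is conserved.
    """
    if minh < 0:
        raise InputError("minh must be non-negative")
    landscape = cg.landscape
    group = dict(cg.assignment)  # state -> current group id (initial basin ids)

    def group_min(gid_members):
        return min(
            gid_members,
            key=lambda x: (_res(landscape.energy(x)), landscape.sort_key(x)),
        )

    if minh > 0:
        while True:
            members: dict[int, list] = {}
            for x, g in group.items():
                members.setdefault(g, []).append(x)
            gmin = {g: group_min(ms) for g, ms in members.items()}
            gmin_e = {g: _res(landscape.energy(m)) for g, m in gmin.items()}
            # lowest saddle between each adjacent group pair
            saddle: dict[tuple[int, int], float] = {}
            for x, y in landscape.edges():
                gx, gy = group[x], group[y]
                if gx == gy:
                    continue
                s = max(_res(landscape.energy(x)), _res(landscape.energy(y)))
                k = (min(gx, gy), max(gx, gy))
                saddle[k] = min(saddle.get(k, np.inf), s)
            merged = False
            for g in sorted(members, key=lambda g: (gmin_e[g], landscape.sort_key(gmin[g]))):
                # deeper adjacent groups, preferred by lowest saddle
                options = []
                for (a, b), s in saddle.items():
                    other = b if a == g else (a if b == g else None)
                    if other is None or gmin_e[other] >= gmin_e[g]:
                        continue
                    options.append((s, gmin_e[other], landscape.sort_key(gmin[other]), other))
                if not options:
                    continue
                s, _, _, target = min(options)
                if s - gmin_e[g] < minh - 1e-12:
                    for x in members[g]:
                        group[x] = target
                    merged = True
                    break
            if not merged:
                break

    members = {}
    for x, g in group.items():
        members.setdefault(g, []).append(x)
    order = sorted(
        members.values(),
        key=lambda ms: (
            _res(landscape.energy(group_min(ms))),
            landscape.sort_key(group_min(ms)),
        ),
    )
    macrostates = []
    for idx, ms in enumerate(order):
        mem = tuple(sorted(ms, key=landscape.sort_key))
        z = partition_function((landscape.energy(x) for x in mem), thermo)
        macrostates.append(Macrostate(idx, mem, group_min(ms), z))
    return CoarseGraining(landscape, macrostates)


def write_bar_file(path: str, cg: CoarseGraining) -> None:
    """Write one line per macrostate: ``id local_min energy``."""
    landscape = cg.landscape
    with open(path, "w") as fh:
        for m in cg.macrostates:
            label = getattr(m.local_min, "dotbracket", str(m.local_min))
            fh.write(f"{m.id} {label} {landscape.energy(m.local_min):.2f}\n")
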