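"""Finite energy landscapes: microstates, energies, and the move graph.

Two concrete landscape flavors share one interface:

* :class:`StructureLandscape` — microstates are RNA secondary structures of
  one sequence, neighborhood is the elementary base-pair move set, energies
  come from an energy model.
* :class:`GraphLandscape` — microstates are arbitrary labels with an explicit
  adjacency list; used for abstract test landscapes with planted basins.

The neighborhood exposed by a landscape is always restricted to microstates
that are members of the landscape; :meth:`Landscape.full_neighbors` gives the
unrestricted move graph where one exists (needed by the flooding heuristic,
which must step outside the explored set).
"""

from __future__ import annotations

from typing import Hashable, Iterable, Mapping, Sequence

from .errors import InputError
from .structure_space import DEFAULT_PAIRS, Structure, neighbors as _structure_neighbors

#: Energies are compared at this resolution (kcal/mol); exact ties are broken
#: by the landscape's deterministic sort key.
ENERGY_RESOLUTION = 1e-9


class Landscape:
    """Base class; subclasses fill ``_energies`` and implement neighbors."""

    def __init__(self, energies: Mapping[Hashable, float]):
        self._energies = dict(energies)
        if not self._energies:
            raise InputError("landscape must contain at least one microstate")
        self.states: tuple = tuple(sorted(self._energies, key=self.sort_key))

    # -- interface ---------------------------------------------------------
    def sort_key(self, x):
        return str(x)

    def energy(self, x) -> float:
        return self._energies[x]

    def neighbors(self, x) -> list:
        raise NotImplementedError

    def full_neighbors(self, x) -> list:
        """Neighbors in the unrestricted move graph (default: none beyond
        the landscape members)."""
        return self.neighbors(x)

    # -- conveniences ------------------------------------------------------
    def __len__(self) -> int:
        return len(self._energies)

    def __contains__(self, x) -> bool:
        return x in self._energies

    def __iter__(self):
        return iter(self.states)

    @property
    def energies(self) -> dict:
        return dict(self._energies)

    def edges(self):
        """Each unordered neighbor pair within the landscape, once."""
        seen = set()
        for x in self.states:
            for y in self.neighbors(x):
                if (y, x) not in seen:
                    seen.add((x, y))
                    yield x, y


class GraphLandscape(Landscape):
    """Abstract landscape over labeled nodes with explicit adjacency."""

    def __init__(
        self,
        energies: Mapping[Hashable, float],
        adjacency: Mapping[Hashable, Iterable[Hashable]],
    ):
        super().__init__(energies)
        adj: dict[Hashable, set] = {x: set() for x in self._energies}
        for x, ys in adjacency.items():
            for y in ys:
                if x == y:
                    raise InputError("a microstate cannot neighbor itself")
                if x in adj and y in adj:
                    adj[x].add(y)
                    adj[y].add(x)
        self._adj = {x: tuple(sorted(ys, key=self.sort_key)) for x, ys in adj.items()}

    def neighbors(self, x) -> list:
        return [y for y in self._adj[x]]

    def restrict(self, subset: Iterable[Hashable]) -> "GraphLandscape":
        """Induced sub-landscape on ``subset`` (adjacency inherited)."""
        keep = set(subset)
        missing = keep - set(self._energies)
        if missing:
            raise InputError(f"states not in landscape: {sorted(map(str, missing))}")
        sub = GraphLandscape(
            {x: self._energies[x] for x in keep},
            {x: [y for y in self._adj[x] if y in keep] for x in keep},
        )
        sub._parent = self  # full move graph for flooding
        return sub

    def full_neighbors(self, x) -> list:
        parent = getattr(self, "_parent", None)
        if parent is not None:
            return parent.full_neighbors(x)
        return self.neighbors(x)

    def full_energy(self, x) -> float:
        parent = getattr(self, "_parent", None)
        if parent is not None:
            return parent.full_energy(x)
        return self._energies[x]


class StructureLandscape(Landscape):
    """Landscape of secondary structures of one RNA sequence.

    Membership is by structure identity; the move set is the elementary
    base-pair neighborhood (single moves, plus helix-of-two double moves
    when ``nolp`` is set), restricted to members.
    """

    def __init__(
        self,
        seq: str,
        entries: Sequence[tuple[Structure, float]],
        *,
        nolp: bool = False,
        allowed_pairs: frozenset = DEFAULT_PAIRS,
        energy_model=None,
    ):
        self.seq = seq
        self.nolp = nolp
        self.allowed_pairs = allowed_pairs
        self.energy_model = energy_model
        super().__init__({st: e for st, e in entries})
        self._members = {st.dotbracket: st for st in self._energies}
        self._neighbor_cache: dict[Structure, tuple] = {}

    def sort_key(self, x):
        return x.key if isinstance(x, Structure) else str(x)

    def neighbors(self, x: Structure) -> list[Structure]:
        cached = self._neighbor_cache.get(x)
        if cached is None:
            cached = tuple(
                self._members[y.dotbracket]
                for y in _structure_neighbors(
                    x, self.seq, nolp=self.nolp, allowed_pairs=self.allowed_pairs
                )
                if y.dotbracket in self._members
            )
            self._neighbor_cache[x] = cached
        return list(cached)

    def full_neighbors(self, x: Structure) -> list[Structure]:
        return _structure_neighbors(
            x, self.seq, nolp=self.nolp, allowed_pairs=self.allowed_pairs
        )

    def full_energy(self, x: Structure) -> float:
        if x in self._energies:
            return self._energies[x]
        if self.energy_model is None:
            raise InputError(
                "no energy model attached; cannot score structures outside "
                "the enumerated set"
            )
        return float(self.energy_model.energy(x, self.seq))

    def restrict(self, subset: Iterable[Structure]) -> "StructureLandscape":
        keep = {st.dotbracket for st in subset}
        sub = StructureLandscape(
            self.seq,
            [(st, e) for st, e in self._energies.items() if st.dotbracket in keep],
            nolp=self.nolp,
            allowed_pairs=self.allowed_pairs,
            energy_model=self.energy_model,
        )
        return sub


def landscape_from_enumeration(
    seq: str,
    energy_model,
    band: float | None = None,
    *,
    nolp: bool = False,
    allowed_pairs: frozenset = DEFAULT_PAIRS,
) -> StructureLandscape:
    """Enumerate the bounded structure space of ``seq`` and wrap it."""
    from .structure_space import enumerate_structures

    entries = enumerate_structures(
        seq, energy_model, band, nolp=nolp, allowed_pairs=allowed_pairs
    )
    return StructureLandscape(
        seq, entries, nolp=nolp, allowed_pairs=allowed_pairs, energy_model=energy_model
    )
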