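"""Coupling of the free-RNA world to the RNA-ligand complex world.

The complex ("dimer") world contains exactly the conformations that carry
the ligand binding pocket, each energy-shifted by the binding energy
``theta < 0``.  Because the shift is a constant, microrates, basin
probabilities, and macrorates inside the dimer world are identical to those
computed from the unshifted energies; only the rates that cross between the
worlds see ``theta``:

* association  ``k(x -> Lx) = A_a``           (downhill, pocket present),
* dissociation ``k(Lx -> x) = A_d exp(b*theta)``,

and on basins, with ``Z`` over unshifted energies,

* ``r(alpha -> L beta) = A_a Z[alpha ^ beta] / Z[alpha]``,
* ``r(L beta -> alpha) = A_d Z[alpha ^ beta] / Z[beta] * exp(b*theta)``.

The module also derives model parameters from empirical measurements: the
binding energy from an aptamer dissociation constant, the effective
dissociation constant of the full switch, and bounds on the association
prefactor.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .coarse_grain import CoarseGraining, Macrostate
from .energy_model import GAS_CONSTANT, Thermo, partition_function
from .errors import ConfigError, InputError, ValidityError
from .landscape import GraphLandscape, Landscape, StructureLandscape
from .rate_model import RateModel, metropolis
from .structure_space import Structure, enumerate_structures

__all__ = [
    "PocketConstraint",
    "RateModel",
    "has_pocket",
    "build_dimer_world",
    "microrate",
    "association_microrate",
    "dissociation_microrate",
    "cross_macrorates",
    "cross_rate_matrices",
    "binding_energy_from_kd",
    "effective_kd",
    "effective_kd_from_measurement",
    "equilibrium_kd",
    "bound_fraction",
    "prefactor_bounds",
]


class PocketConstraint:
    """Structural requirements defining the ligand binding pocket.

    One character per sequence position:

    * ``(`` / ``)`` — the matched pair must be present in the structure,
    * ``x``         — the position must be unpaired,
    * ``<`` / ``>`` — the position must pair downstream / upstream,
    * ``.`` / ``?`` — unconstrained.
    """

    def __init__(self, constraint: str):
        self.constraint = constraint
        stack: list[int] = []
        pairs: set[tuple[int, int]] = set()
        for pos, c in enumerate(constraint, start=1):
            if c == "(":
                stack.append(pos)
            elif c == ")":
                if not stack:
                    raise ValidityError(f"unbalanced ')' in constraint {constraint!r}")
                pairs.add((stack.pop(), pos))
            elif c not in ".?x<>":
                raise ValidityError(f"illegal constraint character {c!r}")
        if stack:
            raise ValidityError(f"unbalanced '(' in constraint {constraint!r}")
        for (i, j), (k, l) in itertools.combinations(pairs, 2):
            if (i < k < j < l) or (k < i < l < j):
                raise ValidityError(f"crossing constraint pairs ({i},{j}), ({k},{l})")
        for i, j in pairs:
            if j - i < 4:
                raise ValidityError(f"constraint pair ({i},{j}) violates hairpin size")
        self.required_pairs = frozenset(pairs)
        self.unpaired = frozenset(
            pos for pos, c in enumerate(constraint, start=1) if c == "x"
        )
        self.pair_down = frozenset(
            pos for pos, c in enumerate(constraint, start=1) if c == "<"
        )
        self.pair_up = frozenset(
            pos for pos, c in enumerate(constraint, start=1) if c == ">"
        )

    def __len__(self) -> int:
        return len(self.constraint)

    def __repr__(self) -> str:
        return f"PocketConstraint({self.constraint!r})"


def has_pocket(x: Structure, c: PocketConstraint) -> bool:
    """Does structure ``x`` contain the binding pocket described by ``c``?"""
    if len(x) != len(c):
        raise InputError(
            f"structure length {len(x)} and constraint length {len(c)} differ"
        )
    if not c.required_pairs <= x.pairs:
        return False
    partner = x.partner
    if any(p in partner for p in c.unpaired):
        return False
    if any(partner.get(p, -1) <= p for p in c.pair_down):
        return False
    if any(not (0 < partner.get(p, 0) < p) for p in c.pair_up):
        return False
    return True


def build_dimer_world(
    monomer_landscape: Landscape,
    pocket,
    theta: float,
    extra_band: float = 0.0,
) -> Landscape:
    """Construct the RNA-ligand complex landscape.

    The dimer microstates are exactly the pocket-carrying structures up to
    ``extra_band`` kcal/mol above the highest monomer energy (a higher
    ceiling than the monomer band helps keep the constrained world
    connected).  Returned energies are the *unshifted* RNA energies: the
    constant shift ``theta`` cancels from every probability and rate inside
    the world, so all downstream computations use the monomer energy scale.
    The binding energy is recorded on the returned landscape as ``.theta``.

    ``pocket`` is a :class:`PocketConstraint` for structure landscapes, or
    an explicit collection of member states for abstract graph landscapes.
    """
    if extra_band < 0:
        raise InputError("extra_band must be non-negative")

    if isinstance(pocket, PocketConstraint):
        if not isinstance(monomer_landscape, StructureLandscape):
            raise InputError("a pocket constraint requires a structure landscape")
        seq = monomer_landscape.seq
        if monomer_landscape.energy_model is None:
            raise ConfigError("monomer landscape has no attached energy model")
        energies = [monomer_landscape.energy(x) for x in monomer_landscape.states]
        ceiling = max(energies) + extra_band
        entries = enumerate_structures(
            seq,
            monomer_landscape.energy_model,
            band=None,
            nolp=monomer_landscape.nolp,
            allowed_pairs=monomer_landscape.allowed_pairs,
        )
        members = [
            (st, e) for st, e in entries if e <= ceiling + 1e-9 and has_pocket(st, pocket)
        ]
        if not members:
            raise ConfigError("no structure satisfies the pocket constraint")
        world: Landscape = StructureLandscape(
            seq,
            members,
            nolp=monomer_landscape.nolp,
            allowed_pairs=monomer_landscape.allowed_pairs,
            energy_model=monomer_landscape.energy_model,
        )
    else:
        pocket_states = set(pocket)
        if not pocket_states:
            raise ConfigError("empty pocket subset: dimer world would be empty")
        if not isinstance(monomer_landscape, GraphLandscape):
            raise InputError("explicit pocket subsets require a graph landscape")
        world = monomer_landscape.restrict(pocket_states)

    world.theta = float(theta)
    return world


# ---------------------------------------------------------------------------
# microrates
# ---------------------------------------------------------------------------


def microrate(x, y, landscape: Landscape, rate_model: RateModel) -> float:
    """Metropolis microrate of the conformational move ``x -> y`` (1/s).

    Zero unless ``x`` and ``y`` are elementary-move neighbors within the
    landscape.  Satisfies ``k(x->y)/k(y->x) = exp(-b (E(y)-E(x)))``.
    """
    if y not in landscape.neighbors(x):
        return 0.0
    return metropolis(
        landscape.energy(x), landscape.energy(y), rate_model.A_R, rate_model.beta
    )


def association_microrate(pocket_member: bool, rate_model: RateModel) -> float:
    """Microrate of ligand association ``x -> Lx`` in 1/(M s).

    Binding is downhill by ``theta < 0``, so the Metropolis activation
    energy vanishes and the rate is the bare prefactor ``A_a`` for every
    pocket-carrying conformation; zero for conformations without pocket.
    """
    return rate_model.A_a if pocket_member else 0.0


def dissociation_microrate(pocket_member: bool, rate_model: RateModel) -> float:
    """Microrate of dissociation ``Lx -> x`` in 1/s.

    Uphill by ``-theta``, hence ``A_d exp(b*theta)``; zero without pocket.
    """
    if not pocket_member:
        return 0.0
    return rate_model.A_d * math.exp(rate_model.beta * rate_model.theta)


# ---------------------------------------------------------------------------
# cross-world macrorates
# ---------------------------------------------------------------------------


def _intersection_Z(
    alpha: Macrostate, lbeta: Macrostate, landscape: Landscape, thermo: Thermo
) -> float:
    common = set(alpha.members) & set(lbeta.members)
    if not common:
        return 0.0
    return partition_function((landscape.energy(x) for x in common), thermo)


def cross_macrorates(
    alpha: Macrostate,
    lbeta: Macrostate,
    monomer_landscape: Landscape,
    rate_model: RateModel,
) -> tuple[float, float]:
    """Association and dissociation macrorates between one monomer basin and
    one dimer basin.

    Returns ``(r(alpha -> L beta), r(L beta -> alpha))`` in (1/(M s), 1/s).
    The overlap ``alpha ^ beta`` is taken by microstate identity; all
    partition functions are over unshifted energies, the binding energy
    entering only through the ``exp(b*theta)`` dissociation factor.
    """
    z_common = _intersection_Z(alpha, lbeta, monomer_landscape, rate_model.thermo)
    if z_common == 0.0:
        return 0.0, 0.0
    assoc = rate_model.A_a * z_common / alpha.Z
    dissoc = (
        rate_model.A_d
        * z_common
        / lbeta.Z
        * math.exp(rate_model.beta * rate_model.theta)
    )
    return float(assoc), float(dissoc)


def cross_rate_matrices(
    monomer_cg: CoarseGraining,
    dimer_cg: CoarseGraining,
    rate_model: RateModel,
) -> tuple[np.ndarray, np.ndarray]:
    """All cross-world macrorates at once.

    Returns ``(assoc, dissoc)`` where ``assoc[j, i] = r(alpha_i -> L beta_j)``
    (shape ``(m, n)``, units 1/(M s)) and ``dissoc[i, j] = r(L beta_j ->
    alpha_i)`` (shape ``(n, m)``, units 1/s).
    """
    n, m = len(monomer_cg), len(dimer_cg)
    thermo = rate_model.thermo
    landscape = monomer_cg.landscape
    # Z[alpha_i ^ beta_j] accumulated over the dimer microstates
    z_common = np.zeros((n, m))
    for lb in dimer_cg.macrostates:
        for x in lb.members:
            # dimer states above the monomer band have no monomer partner
            a = monomer_cg.assignment.get(x)
            if a is None:
                continue
            z_common[a, lb.id] += math.exp(-thermo.beta * landscape.energy(x))
    z_alpha = np.array([ms.Z for ms in monomer_cg.macrostates])
    z_beta = np.array([ms.Z for ms in dimer_cg.macrostates])
    assoc = rate_model.A_a * (z_common / z_alpha[:, None]).T
    dissoc = (
        rate_model.A_d
        * math.exp(rate_model.beta * rate_model.theta)
        * z_common
        / z_beta[None, :]
    )
    return assoc, dissoc


# ---------------------------------------------------------------------------
# parameters from empirical measurements
# ---------------------------------------------------------------------------


def binding_energy_from_kd(kd_A: float, pocket_prob_A: float, T_A: float) -> float:
    """Binding energy from an aptamer dissociation constant, kcal/mol.

    ``theta = R T_A ln(Kd_A * Pr[pocket | aptamer, T_A])`` with ``Kd_A`` on
    the 1 M standard-state scale.  The pocket probability corrects the
    macroscopic measurement for the fraction of aptamer conformations that
    actually present the binding pocket.
    """
    if kd_A <= 0 or T_A <= 0:
        raise InputError("dissociation constant and temperature must be positive")
    if not 0 < pocket_prob_A <= 1:
        raise InputError("pocket probability must lie in (0, 1]")
    theta = GAS_CONSTANT * T_A * math.log(kd_A * pocket_prob_A)
    if theta >= 0:
        warnings.warn(
            f"derived binding energy {theta:.3f} kcal/mol is non-negative; "
            "the ligand would be non-binding",
            stacklevel=2,
        )
    return theta


def effective_kd(theta: float, pocket_prob_RS: float, T_R: float) -> float:
    """Effective dissociation constant of the full switch at ``T_R``, in M.

    ``Kd_RS = exp(theta / (R T_R)) / Pr[pocket | RS, T_R]``: the binding
    equilibrium is diluted by the (typically tiny) probability that the full
    riboswitch presents the pocket at all.
    """
    if pocket_prob_RS <= 0 or T_R <= 0:
        raise InputError("pocket probability and temperature must be positive")
    return math.exp(theta / (GAS_CONSTANT * T_R)) / pocket_prob_RS


def effective_kd_from_measurement(
    kd_A: float, pocket_prob_A: float, T_A: float, pocket_prob_RS: float, T_R: float
) -> float:
    """Effective switch Kd directly from the aptamer measurement.

    ``(Kd_A * Pr_A)^(T_A/T_R) / Pr_RS`` — algebraically identical to
    chaining :func:`binding_energy_from_kd` and :func:`effective_kd`.
    """
    if pocket_prob_RS <= 0:
        raise InputError("pocket probability must be positive")
    return (kd_A * pocket_prob_A) ** (T_A / T_R) / pocket_prob_RS


def equilibrium_kd(
    theta: float, monomer_landscape: Landscape, dimer_world: Landscape, thermo: Thermo
) -> float:
    """Microscopic effective Kd of an assembled system, in M.

    ``Kd = exp(b*theta) Z[X] / Z[X+]`` with both partition functions over
    unshifted energies; the equilibrium bound fraction at ligand
    concentration ``l0`` is ``l0 / (l0 + Kd)``.
    """
    z_x = partition_function(
        (monomer_landscape.energy(x) for x in monomer_landscape.states), thermo
    )
    z_plus = partition_function(
        (dimer_world.energy(x) for x in dimer_world.states), thermo
    )
    return math.exp(thermo.beta * theta) * z_x / z_plus


def bound_fraction(l0: float, kd: float) -> float:
    """Equilibrium fraction of RNA bound to the ligand at concentration l0."""
    if l0 < 0 or kd <= 0:
        raise InputError("l0 must be non-negative and Kd positive")
    return l0 / (l0 + kd)


def prefactor_bounds(
    apparent_rate: float, pocket_prob_aptamer: float
) -> tuple[float, float]:
    """Bounds on the microscopic association prefactor ``A_a`` in 1/(M s).

    The measured apparent association rate is the microscopic rate times a
    pocket-availability factor between ``Pr[pocket]`` and 1, so
    ``apparent <= A_a <= apparent / Pr[pocket | aptamer]``.
    """
    if apparent_rate <= 0 or not 0 < pocket_prob_aptamer <= 1:
        raise InputError("apparent rate must be positive, probability in (0, 1]")
    return apparent_rate, apparent_rate / pocket_prob_aptamer
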