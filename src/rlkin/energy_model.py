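"""Free energies, Boltzmann weights, partition functions.

The built-in energy model is a deliberately simple pair/stack surrogate: it
rewards helix formation the way nearest-neighbor models do qualitatively,
while remaining exactly computable and self-contained.  Realistic Turner
nearest-neighbor energies can be supplied either through a table file (any
pre-computed structure/energy list) or through the external adapter that
shells out to an installed ``RNAeval``.
"""

from __future__ import annotations

import math
import shutil
import subprocess
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .errors import InputError, NumericalError
from .structure_space import Structure

#: Universal gas constant in kcal/(mol*K).
GAS_CONSTANT = 1.98717e-3


@dataclass(frozen=True)
class Thermo:
    """Thermodynamic state: absolute temperature and inverse temperature.

    ``beta`` is :math:`\\mathfrak{b} = 1/(R T)` in mol/kcal, with the gas
    constant R in kcal/(mol K).
    """

    T: float = 310.15

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise InputError(f"absolute temperature must be positive, got {self.T}")

    @property
    def RT(self) -> float:
        return GAS_CONSTANT * self.T

    @property
    def beta(self) -> float:
        return 1.0 / self.RT


class PairStackEnergy:
    """Built-in surrogate energy model.

    Energy of a structure is ``stack_energy`` per stacked-pair quartet (two
    adjacent pairs ``(i,j)`` and ``(i+1,j-1)``) plus ``lone_pair_energy`` per
    pair that has no stacking neighbor.  The open chain has energy 0.  This
    is a surrogate capturing the qualitative shape of helix energetics, not
    the Turner nearest-neighbor model.
    """

    kind = "pair_stack_builtin"

    def __init__(self, stack_energy: float = -2.0, lone_pair_energy: float = -1.0):
        self.stack_energy = float(stack_energy)
        self.lone_pair_energy = float(lone_pair_energy)

    def energy(self, x: Structure, seq: str | None = None) -> float:
        pairs = x.pairs
        n_stacks = sum(1 for (i, j) in pairs if (i + 1, j - 1) in pairs)
        n_lone = sum(
            1
            for (i, j) in pairs
            if (i + 1, j - 1) not in pairs and (i - 1, j + 1) not in pairs
        )
        return self.stack_energy * n_stacks + self.lone_pair_energy * n_lone


class TableEnergy:
    """Energy lookup from an explicit dot-bracket -> kcal/mol table."""

    kind = "table_lookup"

    def __init__(self, table: Mapping[str, float]):
        self.table = dict(table)

    @classmethod
    def from_subopt_file(cls, path: str) -> "TableEnergy":
        from .structure_space import read_subopt

        _, entries = read_subopt(path)
        return cls({st.dotbracket: e for st, e in entries})

    def energy(self, x: Structure, seq: str | None = None) -> float:
        try:
            return self.table[x.dotbracket]
        except KeyError:
            raise InputError(f"structure {x.dotbracket!r} not in energy table") from None


class ViennaEnergy:
    """Optional adapter evaluating energies with an external ``RNAeval``.

    Energies come from whatever Turner parameter set and dangle model the
    installed engine defaults to; the engine's version is recorded on first
    use for provenance.
    """

    kind = "external_adapter"

    def __init__(self, executable: str = "RNAeval", extra_args: Iterable[str] = ("-d2",)):
        if shutil.which(executable) is None:
            raise InputError(f"external energy engine {executable!r} not on PATH")
        self.executable = executable
        self.extra_args = list(extra_args)
        self.engine_version: str | None = None

    def energy(self, x: Structure, seq: str) -> float:
        proc = subprocess.run(
            [self.executable, *self.extra_args],
            input=f"{seq}\n{x.dotbracket}\n",
            capture_output=True,
            text=True,
            check=True,
        )
        # output: "SEQ\nSTRUCT ( -1.20)\n"
        line = proc.stdout.strip().splitlines()[-1]
        try:
            value = line.split("(")[-1].rstrip(")").strip()
            return float(value)
        except (IndexError, ValueError):
            raise NumericalError(f"cannot parse RNAeval output {line!r}") from None


def partition_function(energies: Iterable[float], thermo: Thermo) -> float:
    """Boltzmann partition function ``Z[S] = sum_x exp(-beta E(x))``.

    An empty set yields 0.  When the energy spread exceeds ``400 RT`` the sum
    is evaluated on a shifted (log-sum-exp) path to avoid overflow; the
    returned value may then underflow to 0 only if every term does.
    """
    es = np.asarray(list(energies), dtype=float)
    if es.size == 0:
        return 0.0
    b = thermo.beta
    spread = float(es.max() - es.min())
    if spread > 400.0 * thermo.RT:
        # exp(-b*e) = exp(-b*e_min) * exp(-b*(e - e_min))
        shifted = np.exp(-b * (es - es.min()))
        return float(math.exp(-b * es.min()) * shifted.sum())
    return float(np.exp(-b * es).sum())


def microstate_probability(x, S: Mapping, thermo: Thermo) -> float:
    """Boltzmann probability ``Pr[x | S]`` of one microstate within a set.

    ``S`` maps microstates to energies (kcal/mol).  Returns 0 when ``x`` is
    not a member.  Probabilities over the whole set sum to one and are
    invariant under a constant energy offset.
    """
    if x not in S:
        return 0.0
    z = partition_function(S.values(), thermo)
    if z <= 0.0:
        raise NumericalError("partition function is zero; probabilities undefined")
    return math.exp(-thermo.beta * S[x]) / z


def boltzmann_weights(energies: Iterable[float], thermo: Thermo) -> np.ndarray:
    """Normalized Boltzmann distribution over a finite state set.

    Computed stably by shifting to the minimum energy before exponentiating.
    """
    es = np.asarray(list(energies), dtype=float)
    if es.size == 0:
        return np.zeros(0)
    w = np.exp(-thermo.beta * (es - es.min()))
    return w / w.sum()
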