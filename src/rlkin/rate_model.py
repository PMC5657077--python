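"""Kinetic parameters and the Metropolis microrate rule.

All elementary transition rates follow the Metropolis rule

    k(x -> y) = A * exp(-beta * max{0, E(y) - E(x)}),

so downhill moves run at the reaction-type prefactor ``A`` and uphill moves
are Arrhenius-suppressed by the energy difference.  Three prefactors are
distinguished: ``A_R`` (1/s) for conformation changes in either world,
``A_a`` (1/(M s)) for ligand association, and ``A_d`` (1/s) for dissociation.
Detailed balance of the dimerization reaction forces ``A_d = A_a`` on the
1 M standard-state concentration scale, which is the default here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .energy_model import Thermo
from .errors import InputError


@dataclass(frozen=True)
class RateModel:
    """All kinetic and thermodynamic parameters of the interaction model.

    Parameters
    ----------
    A_R:
        Pre-exponential factor for RNA conformation changes, 1/s.
    A_a:
        Pre-exponential factor for ligand association, 1/(M s).
    A_d:
        Pre-exponential factor for dissociation, 1/s.  If ``None`` (the
        default) it is set equal to ``A_a``, as required by detailed balance
        of the dimerization reaction on the 1 M standard-state scale.
    theta:
        Ligand binding energy in kcal/mol; negative for a binding ligand.
    thermo:
        Temperature of the kinetic system.
    """

    A_R: float = 1.0e6
    A_a: float = 600.0
    A_d: float | None = None
    theta: float = -9.59
    thermo: Thermo = field(default_factory=Thermo)

    def __post_init__(self) -> None:
        if self.A_d is None:
            object.__setattr__(self, "A_d", self.A_a)
        if self.A_R <= 0 or self.A_a <= 0 or self.A_d <= 0:
            raise InputError("pre-exponential factors must be positive")
        if self.theta >= 0:
            warnings.warn(
                f"binding energy theta = {self.theta} kcal/mol is not negative; "
                "the ligand is effectively non-binding",
                stacklevel=2,
            )

    @property
    def beta(self) -> float:
        return self.thermo.beta


def metropolis(e_from: float, e_to: float, A: float, beta: float) -> float:
    """Metropolis rate for one elementary move between given energies."""
    return A * math.exp(-beta * max(0.0, e_to - e_from))
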