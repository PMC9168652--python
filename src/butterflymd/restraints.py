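"""Flat-bottom ("NMR-type") upper-wall distance restraints.

The sampling protocol behind the butterfly analysis keeps the substrate
vinyl carbons near the Cpd I oxygen with a one-sided harmonic wall: the
restraint contributes nothing while the pair distance is at or below
the target, and grows quadratically beyond it,

    E(d) = 0                      for d <= d0
    E(d) = k (d - d0)^2           for d >  d0

with the Amber convention (no 1/2 prefactor), so a force constant
("restraint weight") of k = 3.0 kcal mol^-1 Å^-2 costs 3.0 kcal/mol at
1 Å beyond the target.  Only the upper wall is implemented; there is no
penalty for short distances.  The pure quadratic form is used with no
linearisation at large displacement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = ["RestraintSpec", "RestraintEnergy", "flat_bottom_energy"]

#: Default restraint weight, kcal mol^-1 Å^-2.
DEFAULT_FORCE_CONSTANT = 3.0


@dataclass(frozen=True)
class RestraintSpec:
    """One flat-bottom distance restraint.

    ``atom_pair`` names the restrained pair by site role (e.g.
    ``("c8", "o_cpd")``); ``target_distance`` in Å, ``force_constant``
    in kcal mol^-1 Å^-2.
    """

    target_distance: float
    force_constant: float = DEFAULT_FORCE_CONSTANT
    atom_pair: tuple[str, str] = ("c8", "o_cpd")

    def __post_init__(self) -> None:
        if not self.target_distance > 0:
            raise ValueError(f"target_distance must be positive, got {self.target_distance}")
        if self.force_constant < 0:
            raise ValueError(f"force_constant must be non-negative, got {self.force_constant}")
        if len(self.atom_pair) != 2 or self.atom_pair[0] == self.atom_pair[1]:
            raise ValueError(f"atom_pair must name two distinct sites, got {self.atom_pair}")


class RestraintEnergy(NamedTuple):
    """Energy (kcal/mol) and the scalar force magnitude dE/dd (kcal mol^-1 Å^-1) along the pair axis."""

    energy: float
    force: float


def flat_bottom_energy(d, spec: RestraintSpec) -> RestraintEnergy:
    """Evaluate the upper-wall restraint at distance ``d`` (Å; scalar or array).

    Zero at and below the target distance; ``k (d - d0)^2`` above it,
    with force magnitude ``2 k (d - d0)``.  The energy is continuous and
    once-differentiable at the wall.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    excess = np.maximum(d - spec.target_distance, 0.0)
    energy = spec.force_constant * excess**2
    force = 2.0 * spec.force_constant * excess
    if energy.ndim == 0:
        return RestraintEnergy(float(energy), float(force))
    return RestraintEnergy(energy, force)
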