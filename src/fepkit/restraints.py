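"""Flat-bottom distance restraints for hypermobile side chains.

During an alchemical transformation the decoupled nonbonded interactions
of a dual-topology hybrid free flexible charged side chains (Arg, Lys)
from their native salt bridges, letting them wander into unphysical
configurations that wreck forward/reverse overlap. A flat-bottom
restraint leaves the native dynamics untouched — zero energy anywhere
inside the wall — and penalizes only excursions beyond it with a
half-harmonic wall.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = ["FlatBottomRestraint", "restraint_energy", "propose_upper_walls"]

#: Default wall force constant, kcal/mol/A^2.
DEFAULT_FORCE_CONSTANT = 10.0

#: Default margin added above the maximum observed equilibrium distance
#: when proposing walls, Angstrom.
DEFAULT_MARGIN = 0.5


@dataclass(frozen=True)
class FlatBottomRestraint:
    """One-sided flat-bottom restraint on an atom-pair distance.

    Zero energy for distances up to ``upper_wall``; half-harmonic with
    force constant ``force_constant`` (kcal/mol/A^2) beyond it.
    """

    pair_label: str
    upper_wall: float
    force_constant: float = DEFAULT_FORCE_CONSTANT

    def __post_init__(self) -> None:
        if self.upper_wall <= 0:
            raise ValueError("upper_wall must be positive")
        if self.force_constant < 0:
            raise ValueError("force_constant must be non-negative")

    def to_dict(self) -> dict:
        return {
            "pair_label": self.pair_label,
            "upper_wall": self.upper_wall,
            "force_constant": self.force_constant,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FlatBottomRestraint":
        return cls(
            pair_label=str(d["pair_label"]),
            upper_wall=float(d["upper_wall"]),
            force_constant=float(d.get("force_constant", DEFAULT_FORCE_CONSTANT)),
        )


def restraint_energy(distance: float, restraint: FlatBottomRestraint) -> float:
    """Flat-bottom restraint energy (kcal/mol) at the given distance (A).

    0 for distance <= upper_wall, (k/2)(d - wall)^2 beyond: continuous
    and once-differentiable at the wall, convex and monotone increasing
    outside it.
    """
    if distance < 0:
        raise ValueError(f"distance must be non-negative, got {distance}")
    excess = distance - restraint.upper_wall
    if excess <= 0.0:
        return 0.0
    return 0.5 * restraint.force_constant * excess * excess


def propose_upper_walls(
    distance_samples: Mapping[str, Sequence[float]],
    margin: float = DEFAULT_MARGIN,
    force_constant: float = DEFAULT_FORCE_CONSTANT,
) -> list[FlatBottomRestraint]:
    """Choose wall positions from equilibrium distance series.

    Each wall is placed at the maximum observed distance plus ``margin``,
    guaranteeing zero restraint energy on every calibration frame while
    still confining excursions beyond the equilibrium range.
    """
    if margin < 0:
        raise ValueError("margin must be non-negative")
    out = []
    for label, series in distance_samples.items():
        arr = np.asarray(series, dtype=float)
        if arr.size == 0:
            raise ValueError(f"empty distance series for pair {label!r}")
        out.append(
            FlatBottomRestraint(
                pair_label=label,
                upper_wall=float(arr.max()) + margin,
                force_constant=force_constant,
            )
        )
    return out
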