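"""Lambda-window grids and the dual-topology coupling schedule.

An alchemical transformation morphs an initial chemical state (lambda = 0)
into a final state (lambda = 1) through a series of intermediate
Hamiltonians. In the dual-topology scheme both end-state atom sets are
present but never interact with each other; their nonbonded interactions
with the environment are scaled in opposite directions as lambda advances.
Electrostatics of the outgoing atoms are switched off linearly over the
first half of the transformation, after which electrostatics of the
incoming atoms are switched on linearly over the second half. Van der
Waals interactions are scaled across the full lambda range, with a
soft-core modification keeping partially coupled pair energies finite at
zero separation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LambdaSchedule",
    "CouplingState",
    "make_windows",
    "coupling_at",
    "softcore_pair_energy",
    "simulation_time_budget",
]


@dataclass(frozen=True)
class LambdaSchedule:
    """Equally spaced lambda-window grid from 0 to 1 inclusive."""

    n_windows: int
    edges: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.edges) != self.n_windows + 1:
            raise ValueError("edges length must be n_windows + 1")
        e = np.asarray(self.edges)
        if e[0] != 0.0 or e[-1] != 1.0:
            raise ValueError("schedule must span [0, 1]")
        if not np.all(np.diff(e) > 0):
            raise ValueError("edges must be strictly increasing")

    def windows(self) -> list[tuple[float, float]]:
        """(lambda_low, lambda_high) pairs, one per window, in order."""
        return list(zip(self.edges[:-1], self.edges[1:]))

    def to_dict(self) -> dict:
        return {"n_windows": self.n_windows, "edges": list(self.edges)}

    @classmethod
    def from_dict(cls, d: dict) -> "LambdaSchedule":
        return cls(n_windows=int(d["n_windows"]), edges=tuple(float(x) for x in d["edges"]))


@dataclass(frozen=True)
class CouplingState:
    """Scale factors applied to the two dual-topology atom sets at one lambda.

    ``outgoing`` refers to the annihilating (initial-state) atoms and
    ``incoming`` to the appearing (final-state) atoms. The electrostatic
    factors are never simultaneously nonzero.
    """

    elec_outgoing: float
    elec_incoming: float
    vdw_outgoing: float
    vdw_incoming: float

    def __post_init__(self) -> None:
        for name in ("elec_outgoing", "elec_incoming", "vdw_outgoing", "vdw_incoming"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.elec_outgoing * self.elec_incoming != 0.0:
            raise ValueError("outgoing and incoming electrostatics cannot both be on")


def make_windows(n_windows: int) -> LambdaSchedule:
    """Build an equally spaced schedule of ``n_windows`` lambda windows.

    With 40 windows the first window spans [0, 0.025] and the last
    [0.975, 1], each of width exactly 1/40.
    """
    if n_windows < 1:
        raise ValueError(f"n_windows must be >= 1, got {n_windows}")
    edges = np.linspace(0.0, 1.0, n_windows + 1)
    # force exact endpoints (linspace already guarantees them)
    return LambdaSchedule(n_windows=n_windows, edges=tuple(edges.tolist()))


def coupling_at(lam: float) -> CouplingState:
    """Dual-topology coupling factors at coupling parameter ``lam``.

    vdW factors interpolate linearly over the whole range; outgoing
    electrostatics decouple linearly on [0, 0.5] and incoming
    electrostatics couple linearly on [0.5, 1].
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    return CouplingState(
        elec_outgoing=max(0.0, 1.0 - 2.0 * lam),
        elec_incoming=max(0.0, 2.0 * lam - 1.0),
        vdw_outgoing=1.0 - lam,
        vdw_incoming=lam,
    )


def softcore_pair_energy(
    r: float,
    lambda_vdw: float,
    epsilon: float,
    sigma: float,
    alpha: float = 0.5,
) -> float:
    """Soft-core Lennard-Jones pair energy at separation ``r``.

    Beutler-style form with the shift applied to the r^6 term only:

        E = 4 eps lam [ s^2 - s ],   s = sigma^6 / (alpha (1 - lam) sigma^6 + r^6)

    At full coupling (lambda_vdw = 1) this is exactly the 12-6
    Lennard-Jones potential; at partial coupling the energy stays finite
    down to r = 0, avoiding the end-point singularity of linearly scaled
    interactions; at lambda_vdw = 0 the pair is fully decoupled.

    Parameters
    ----------
    r : separation in Angstrom (>= 0)
    lambda_vdw : coupling factor in [0, 1]
    epsilon : well depth, kcal/mol
    sigma : zero-crossing distance, Angstrom
    alpha : soft-core stiffness (dimensionless, default 0.5)
    """
    if r < 0:
        raise ValueError(f"r must be non-negative, got {r}")
    if not 0.0 <= lambda_vdw <= 1.0:
        raise ValueError(f"lambda_vdw must lie in [0, 1], got {lambda_vdw}")
    if lambda_vdw == 0.0:
        return 0.0
    denom = alpha * (1.0 - lambda_vdw) * sigma**6 + r**6
    s = sigma**6 / denom
    return 4.0 * epsilon * lambda_vdw * (s * s - s)


def simulation_time_budget(
    n_windows: int = 40,
    ns_per_window: float = 5.0,
    n_directions: int = 2,
    n_mutations: int = 1,
    n_systems: int = 1,
) -> dict[str, float]:
    """Aggregate-sampling bookkeeping for a window-based protocol.

    Returns per-mutation nanoseconds (windows x ns/window x directions)
    and the grand total in microseconds across mutations and systems
    (e.g. apo plus each ligand tautomer).
    """
    per_mutation_ns = n_windows * ns_per_window * n_directions
    total_ns = per_mutation_ns * n_mutations * n_systems
    return {
        "per_mutation_ns": per_mutation_ns,
        "total_ns": total_ns,
        "total_us": total_ns / 1000.0,
    }
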