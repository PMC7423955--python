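"""Thermodynamic-cycle assembly of relative binding free energies.

A receptor mutation's effect on ligand binding, ddG = dG(bind, mutant) -
dG(bind, wild type), is obtained without simulating binding itself:
alchemically mutate the residue once in the ligand-free (apo) receptor,
giving dG3, and once in the ligand-bound (holo) receptor, giving dG4.
Cycle closure then gives ddG = dG4 - dG3, with the uncertainty taken as
the root sum square of the two legs' standard errors.

This module also handles the bookkeeping around that subtraction: sign
orientation for transformations run in the mutant -> wild-type
direction, additive finite-size charge corrections for
charge-changing mutations in periodic electrostatics, and comparison
statistics (per-mutation deviation, mean absolute error, fold-change
band flags) against an experimental mutagenesis table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import KB
from .estimators import FreeEnergyEstimate

__all__ = [
    "LegResult",
    "MutationRecord",
    "CorrectionSet",
    "DeltaDeltaG",
    "ComparisonResult",
    "ddg",
    "orient",
    "apply_corrections",
    "compare_to_experiment",
    "fold_change_threshold",
]

logger = logging.getLogger(__name__)

Leg = Literal["apo", "holo"]
Direction = Literal["forward", "reversed"]

#: Temperature used for the fold-change band (simulation temperature, K).
BAND_TEMPERATURE = 300.0


@dataclass(frozen=True)
class LegResult:
    """Accumulated free energy of one alchemical leg.

    ``leg='apo'`` is the ligand-free mutation (dG3); ``leg='holo'`` is
    the mutation with the ligand bound (dG4). ``system_label`` names the
    mutation plus, for holo legs, the ligand species.
    """

    leg: Leg
    estimate: FreeEnergyEstimate
    system_label: str
    mutation: str = ""

    def __post_init__(self) -> None:
        if self.leg not in ("apo", "holo"):
            raise ValueError(f"leg must be 'apo' or 'holo', got {self.leg!r}")
        if not self.mutation:
            object.__setattr__(self, "mutation", self.system_label)


@dataclass(frozen=True)
class MutationRecord:
    """Experimental reference for one mutation: ddG_expt = dG2 - dG1."""

    mutation: str
    ddg_expt: float
    err_expt: float
    direction: Direction = "forward"

    def __post_init__(self) -> None:
        if self.err_expt < 0:
            raise ValueError("experimental stderr must be non-negative")
        if self.direction not in ("forward", "reversed"):
            raise ValueError(f"direction must be forward/reversed, got {self.direction!r}")


@dataclass(frozen=True)
class DeltaDeltaG:
    """A relative binding free energy with its standard error."""

    mutation: str
    value: float
    stderr: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.stderr < 0:
            raise ValueError("stderr must be non-negative")


class CorrectionSet:
    """Additive per-leg free-energy corrections keyed by system label.

    Holds analytical finite-size corrections for charge-changing
    transformations under periodic electrostatics, applied additively to
    each leg after estimation. Labels absent from the set default to a
    correction of zero with a logged warning (charge-conserving
    mutations need none).
    """

    def __init__(self, corrections: Mapping[str, float] | None = None):
        self._corr: dict[str, float] = {}
        for label, value in (corrections or {}).items():
            if not math.isfinite(value):
                raise ValueError(f"non-finite correction for {label!r}")
            self._corr[str(label)] = float(value)

    def get(self, label: str) -> float:
        if label not in self._corr:
            logger.warning("no correction for leg %r; defaulting to 0", label)
            return 0.0
        return self._corr[label]

    def __contains__(self, label: str) -> bool:
        return label in self._corr

    def items(self):
        return self._corr.items()

    @classmethod
    def from_csv(cls, path) -> "CorrectionSet":
        df = pd.read_csv(path)
        required = {"system_label", "correction_kcal_mol"}
        if not required.issubset(df.columns):
            raise ValueError(f"correction CSV must have columns {sorted(required)}")
        return cls(dict(zip(df["system_label"].astype(str), df["correction_kcal_mol"].astype(float))))


def ddg(apo: LegResult, holo: LegResult) -> DeltaDeltaG:
    """Relative binding free energy ddG = dG4(holo) - dG3(apo).

    Standard error is the root sum square of the two legs' errors. Both
    legs must refer to the same mutation.
    """
    if apo.leg != "apo" or holo.leg != "holo":
        raise ValueError("ddg expects one apo leg and one holo leg, in that order")
    if apo.mutation != holo.mutation:
        raise ValueError(
            f"mismatched mutations: apo={apo.mutation!r} holo={holo.mutation!r}"
        )
    value = holo.estimate.value - apo.estimate.value
    stderr = math.sqrt(apo.estimate.stderr**2 + holo.estimate.stderr**2)
    return DeltaDeltaG(mutation=apo.mutation, value=value, stderr=stderr)


def orient(result: DeltaDeltaG, direction: Direction) -> DeltaDeltaG:
    """Express a ddG in the canonical wild-type -> mutant direction.

    A transformation run mutant -> wild type (``direction='reversed'``)
    is negated (its stderr is unchanged) and labeled "-1x" so plots and
    tables make the sign convention explicit. Applying the reversed
    orientation twice recovers the original value.
    """
    if direction == "forward":
        return result
    if direction != "reversed":
        raise ValueError(f"direction must be forward/reversed, got {direction!r}")
    label = result.label[4:] if result.label.startswith("-1x ") else f"-1x {result.mutation}"
    return replace(result, value=-result.value, label=label)


def apply_corrections(
    legs: Sequence[LegResult], corrections: CorrectionSet
) -> list[LegResult]:
    """Shift each leg by its additive finite-size correction.

    Standard errors are unchanged (the corrections are analytic
    constants). The induced change in any ddG built from the corrected
    legs is holo_correction - apo_correction, so equal corrections on
    both legs cancel exactly — individually sizable corrections can be
    negligible at the ddG level.
    """
    out = []
    for leg in legs:
        c = corrections.get(leg.system_label)
        est = leg.estimate
        out.append(
            replace(leg, estimate=replace(est, value=est.value + c))
        )
    return out


def ddg_correction_shift(
    apo_correction: float, holo_correction: float
) -> float:
    """Net effect of per-leg corrections on the assembled ddG."""
    return holo_correction - apo_correction


def fold_change_threshold(temperature: float, fold: float) -> float:
    """Free-energy equivalent (kcal/mol) of a fold-change in K_eq.

    k_B T ln(fold): at 300 K a 10-fold change in the equilibrium
    constant corresponds to about 1.4 kcal/mol.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if fold <= 0:
        raise ValueError("fold must be positive")
    return KB * temperature * math.log(fold)


@dataclass(frozen=True)
class ComparisonResult:
    """Per-mutation deviations and the mean absolute error vs experiment."""

    table: pd.DataFrame
    mae: float
    mae_rounded: float
    included: tuple[str, ...]

    def __str__(self) -> str:
        lines = [self.table.to_string(index=False, float_format=lambda v: f"{v:8.2f}")]
        lines.append(f"MAE = {self.mae_rounded:.1f} kcal/mol over {len(self.included)} mutations")
        return "\n".join(lines)


def compare_to_experiment(
    computed: Iterable[DeltaDeltaG],
    table: Sequence[MutationRecord],
    exclude: Iterable[str] = (),
    band_fold: float = 10.0,
    band_temperature: float = BAND_TEMPERATURE,
) -> ComparisonResult:
    """Deviations and MAE of computed ddG values against experiment.

    MAE is the mean absolute deviation over the included mutations,
    computed at full precision and also reported rounded to one decimal.
    The band flag marks mutations whose deviation lies within
    k_B T ln(band_fold) — by default the +-1.4 kcal/mol corridor
    corresponding to a 10-fold change in the equilibrium constant at
    300 K.
    """
    expt = {rec.mutation: rec for rec in table}
    excluded = set(exclude)
    rows = []
    for c in computed:
        if c.mutation not in expt:
            raise KeyError(f"mutation {c.mutation!r} absent from the experimental table")
        if c.mutation in excluded:
            continue
        rec = expt[c.mutation]
        dev = c.value - rec.ddg_expt
        rows.append(
            {
                "mutation": c.mutation,
                "ddg_calc": c.value,
                "stderr_calc": c.stderr,
                "ddg_expt": rec.ddg_expt,
                "err_expt": rec.err_expt,
                "deviation": dev,
            }
        )
    if not rows:
        raise ValueError("no mutations left to compare after exclusions")
    df = pd.DataFrame(rows)
    band = fold_change_threshold(band_temperature, band_fold)
    df["within_band"] = df["deviation"].abs() <= band
    mae = float(df["deviation"].abs().mean())
    return ComparisonResult(
        table=df,
        mae=mae,
        mae_rounded=round(mae, 1),
        included=tuple(df["mutation"]),
    )
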