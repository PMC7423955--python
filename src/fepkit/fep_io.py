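"""File formats, run manifests, and pipeline orchestration.

Formats
-------
fepout dialect
    Plain-text per-window energy differences modeled on MD FEP output.
    A window opens with a header line::

        #NEW FEP WINDOW: LAMBDA SET TO <from> LAMBDA2 <to>

    followed by data lines::

        FepEnergy: <step> <elec_from> <elec_to> <vdw_from> <vdw_to> <dE> <dE_avg> <T> <dG>

    The energy difference dE (kcal/mol) is the 6th numeric field and the
    temperature T (K) the 8th; the component columns are written as
    zeros by this package and ignored on parse. Numeric fields are
    serialized with 6 decimals, which is the round-trip precision
    contract. Forward and reverse directions live in separate streams;
    a reverse stream has LAMBDA SET TO greater than LAMBDA2.

plain CSV
    Headerless ``lambda_low,lambda_high,step,dU`` rows, one direction
    per file.

experiment table CSV
    Columns ``mutation, ddg_expt_kcal_mol, err_expt_kcal_mol,
    direction``; extra columns are preserved. The packaged reference
    table carries the six Hv1/2GBI mutations with experimental and
    published computed values for both ligand tautomers.
"""

from __future__ import annotations

import io
import logging
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal, Mapping, Sequence, TextIO

import numpy as np
import pandas as pd
import yaml

from .cycle import (
    ComparisonResult,
    CorrectionSet,
    DeltaDeltaG,
    LegResult,
    MutationRecord,
    compare_to_experiment,
    ddg,
    orient,
    apply_corrections,
)
from .estimators import Method, estimate_window, accumulate
from .synthetic import ToyPotentialSpec, WindowSamples, generate_transformation

__all__ = [
    "FepoutWindow",
    "RunManifest",
    "parse_fepout",
    "write_fepout",
    "fepout_to_window_samples",
    "read_samples_csv",
    "write_samples_csv",
    "read_experiment_table",
    "load_reference_table",
    "load_reference_corrections",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

PRECISION = 6
_HEADER_PREFIX = "#NEW FEP WINDOW:"
_DATA_PREFIX = "FepEnergy:"


@dataclass(frozen=True)
class FepoutWindow:
    """One window parsed from a fepout stream.

    ``lambda_low``/``lambda_high`` are the window bounds in canonical
    order; ``direction`` records whether the stream sampled at the low
    end (forward) or the high end (reverse). Records are
    (step, dU, temperature) tuples with strictly increasing steps.
    """

    lambda_low: float
    lambda_high: float
    direction: Literal["forward", "reverse"]
    records: tuple[tuple[int, float, float], ...]

    @property
    def dU(self) -> np.ndarray:
        return np.array([r[1] for r in self.records])

    @property
    def temperature(self) -> float:
        return self.records[0][2] if self.records else math.nan


def parse_fepout(stream: TextIO | str) -> list[FepoutWindow]:
    """Parse a fepout-dialect text stream into windows in file order."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    windows: list[FepoutWindow] = []
    current: dict | None = None

    def _close(cur: dict) -> None:
        if not cur["records"]:
            warnings.warn(
                f"empty fepout window [{cur['lo']}, {cur['hi']}] ({cur['dir']})"
            )
        windows.append(
            FepoutWindow(
                lambda_low=cur["lo"],
                lambda_high=cur["hi"],
                direction=cur["dir"],
                records=tuple(cur["records"]),
            )
        )

    last_step = None
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(_HEADER_PREFIX):
            if current is not None:
                _close(current)
            parts = line.split()
            try:
                lam_from = float(parts[parts.index("TO") + 1])
                lam_to = float(parts[parts.index("LAMBDA2") + 1])
            except (ValueError, IndexError) as err:
                raise ValueError(f"line {lineno}: malformed window header {line!r}") from err
            direction = "forward" if lam_from < lam_to else "reverse"
            current = {
                "lo": min(lam_from, lam_to),
                "hi": max(lam_from, lam_to),
                "dir": direction,
                "records": [],
            }
            last_step = None
        elif line.startswith(_DATA_PREFIX):
            if current is None:
                raise ValueError(f"line {lineno}: data line before any window header")
            fields = line.split()[1:]
            if len(fields) < 8:
                raise ValueError(f"line {lineno}: expected >= 8 numeric fields, got {len(fields)}")
            try:
                step = int(fields[0])
                dU = float(fields[5])
                T = float(fields[7])
            except ValueError as err:
                raise ValueError(f"line {lineno}: malformed numeric field in {line!r}") from err
            if last_step is not None and step <= last_step:
                raise ValueError(f"line {lineno}: non-increasing step index {step}")
            last_step = step
            current["records"].append((step, dU, T))
        # any other line is ignored (comments, equilibration banners, ...)
    if current is not None:
        _close(current)
    return windows


def write_fepout(
    windows: Sequence[WindowSamples],
    stream: TextIO,
    direction: Literal["forward", "reverse"] = "forward",
) -> None:
    """Write one direction of a transformation in the fepout dialect.

    The forward stream writes each window's forward_dU with the header
    running low -> high; the reverse stream writes reverse_dU with the
    header running high -> low.
    """
    p = PRECISION
    for w in windows:
        if direction == "forward":
            lam_from, lam_to, data = w.lambda_low, w.lambda_high, w.forward_dU
        else:
            lam_from, lam_to, data = w.lambda_high, w.lambda_low, w.reverse_dU
        stream.write(
            f"{_HEADER_PREFIX} LAMBDA SET TO {lam_from:.{p}f} LAMBDA2 {lam_to:.{p}f}\n"
        )
        running = 0.0
        for i, du in enumerate(data, start=1):
            running += du
            stream.write(
                f"{_DATA_PREFIX} {i:8d} {0:.{p}f} {0:.{p}f} {0:.{p}f} {0:.{p}f} "
                f"{du:.{p}f} {0:.{p}f} {w.temperature:.{p}f} {running:.{p}f}\n"
            )


def fepout_to_window_samples(
    forward: Sequence[FepoutWindow], reverse: Sequence[FepoutWindow]
) -> list[WindowSamples]:
    """Pair forward and reverse fepout windows into WindowSamples.

    Windows are matched on their (lambda_low, lambda_high) bounds,
    rounded at the serialization precision.
    """
    def key(w: FepoutWindow) -> tuple[float, float]:
        return (round(w.lambda_low, PRECISION), round(w.lambda_high, PRECISION))

    rev_by_key = {key(w): w for w in reverse}
    out = []
    for fw in forward:
        if fw.direction != "forward":
            raise ValueError(f"expected forward window, got reverse at {key(fw)}")
        rv = rev_by_key.get(key(fw))
        if rv is None:
            raise ValueError(f"no reverse window matching {key(fw)}")
        out.append(
            WindowSamples(
                lambda_low=fw.lambda_low,
                lambda_high=fw.lambda_high,
                forward_dU=fw.dU,
                reverse_dU=rv.dU,
                temperature=fw.temperature,
            )
        )
    return out


def write_samples_csv(
    windows: Sequence[WindowSamples],
    path: str | Path,
    direction: Literal["forward", "reverse"] = "forward",
) -> None:
    """Write one direction as headerless ``lambda_low,lambda_high,step,dU`` rows."""
    p = PRECISION
    with open(path, "w") as fh:
        for w in windows:
            data = w.forward_dU if direction == "forward" else w.reverse_dU
            for i, du in enumerate(data, start=1):
                fh.write(f"{w.lambda_low:.{p}f},{w.lambda_high:.{p}f},{i},{du:.{p}f}\n")


def read_samples_csv(
    forward_path: str | Path,
    reverse_path: str | Path,
    temperature: float,
) -> list[WindowSamples]:
    """Read a forward/reverse pair of headerless sample CSVs."""
    def _read(path) -> dict[tuple[float, float], list[float]]:
        df = pd.read_csv(path, header=None, names=["lo", "hi", "step", "dU"])
        out: dict[tuple[float, float], list[float]] = {}
        for (lo, hi), grp in df.groupby(["lo", "hi"], sort=True):
            out[(float(lo), float(hi))] = grp["dU"].tolist()
        return out

    fwd, rev = _read(forward_path), _read(reverse_path)
    out = []
    for bounds in sorted(fwd):
        if bounds not in rev:
            raise ValueError(f"no reverse data for window {bounds}")
        out.append(
            WindowSamples(
                lambda_low=bounds[0],
                lambda_high=bounds[1],
                forward_dU=np.array(fwd[bounds]),
                reverse_dU=np.array(rev[bounds]),
                temperature=temperature,
            )
        )
    return out


def read_experiment_table(path: str | Path) -> list[MutationRecord]:
    """Read an experimental reference table CSV into MutationRecords."""
    df = pd.read_csv(path)
    required = ["mutation", "ddg_expt_kcal_mol", "err_expt_kcal_mol"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"experiment table missing required column {col!r}")
    dup = df["mutation"][df["mutation"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicated mutation name(s): {sorted(set(dup))}")
    records = []
    for _, row in df.iterrows():
        for col in ("ddg_expt_kcal_mol", "err_expt_kcal_mol"):
            if not math.isfinite(float(row[col])):
                raise ValueError(f"non-numeric {col} for mutation {row['mutation']!r}")
        records.append(
            MutationRecord(
                mutation=str(row["mutation"]),
                ddg_expt=float(row["ddg_expt_kcal_mol"]),
                err_expt=float(row["err_expt_kcal_mol"]),
                direction=str(row.get("direction", "forward") or "forward"),
            )
        )
    return records


def _data_path(name: str):
    return resources.files("fepkit.data").joinpath(name)


def load_reference_table() -> pd.DataFrame:
    """The packaged Hv1/2GBI mutation table.

    Six mutations with experimental ddG +- error and the published
    computed ddG for both ligand tautomers (gbi1, gbi2), kcal/mol.
    """
    with resources.as_file(_data_path("hv1_2gbi_table1.csv")) as p:
        return pd.read_csv(p)


def load_reference_records() -> list[MutationRecord]:
    """Experimental records from the packaged reference table."""
    with resources.as_file(_data_path("hv1_2gbi_table1.csv")) as p:
        return read_experiment_table(p)


def load_reference_corrections() -> CorrectionSet:
    """Packaged finite-size charge corrections for the R211S mutation."""
    with resources.as_file(_data_path("r211s_charge_corrections.csv")) as p:
        return CorrectionSet.from_csv(p)


# ---------------------------------------------------------------------------
# Run manifest and pipeline
# ---------------------------------------------------------------------------


@dataclass
class RunManifest:
    """Declarative description of a full thermodynamic-cycle run.

    Each entry of ``mutations`` maps a mutation name to its two legs.
    A leg is either synthetic — ``{"harmonic": {"k_initial": ...,
    "k_final": ..., ...}}`` sampled at run time — or file-backed —
    ``{"fepout": {"forward": path, "reverse": path}}`` or
    ``{"csv": {"forward": path, "reverse": path}}``.
    """

    temperature: float
    seed: int
    n_windows: int = 40
    n_steps_per_window: int = 5000
    method: Method = "bar"
    decorrelate: bool = True
    tolerance: float = 1e-8
    mutations: dict = field(default_factory=dict)
    corrections_path: str | None = None
    experiment_table_path: str | None = None

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        self.seed = int(self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunManifest":
        raw = yaml.safe_load(Path(path).read_text())
        if "temperature" not in raw or "seed" not in raw:
            raise ValueError("manifest must state temperature and seed explicitly")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = {
            "temperature": self.temperature,
            "seed": self.seed,
            "n_windows": self.n_windows,
            "n_steps_per_window": self.n_steps_per_window,
            "method": self.method,
            "decorrelate": self.decorrelate,
            "tolerance": self.tolerance,
            "mutations": self.mutations,
            "corrections_path": self.corrections_path,
            "experiment_table_path": self.experiment_table_path,
        }
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def _leg_windows(
    manifest: RunManifest, mutation: str, leg_name: str, leg_cfg: Mapping, leg_seed: int
) -> list[WindowSamples]:
    if "harmonic" in leg_cfg:
        params = dict(leg_cfg["harmonic"])
        spec = ToyPotentialSpec(
            kind="harmonic",
            spring_constant_initial=float(params.get("k_initial", 1.0)),
            spring_constant_final=float(params.get("k_final", 2.0)),
            center_initial=float(params.get("center_initial", 0.0)),
            center_final=float(params.get("center_final", 0.0)),
            temperature=manifest.temperature,
        )
        return generate_transformation(
            spec,
            n_windows=manifest.n_windows,
            n_steps_per_window=manifest.n_steps_per_window,
            seed=leg_seed,
        )
    if "fepout" in leg_cfg:
        paths = leg_cfg["fepout"]
        for k in ("forward", "reverse"):
            if not Path(paths[k]).exists():
                raise FileNotFoundError(
                    f"{mutation}/{leg_name}: missing fepout file {paths[k]}"
                )
        fwd = parse_fepout(Path(paths["forward"]).read_text())
        rev = parse_fepout(Path(paths["reverse"]).read_text())
        return fepout_to_window_samples(fwd, rev)
    if "csv" in leg_cfg:
        paths = leg_cfg["csv"]
        for k in ("forward", "reverse"):
            if not Path(paths[k]).exists():
                raise FileNotFoundError(
                    f"{mutation}/{leg_name}: missing csv file {paths[k]}"
                )
        return read_samples_csv(paths["forward"], paths["reverse"], manifest.temperature)
    raise ValueError(f"{mutation}/{leg_name}: leg must define harmonic, fepout, or csv data")


@dataclass(frozen=True)
class CycleReport:
    """Pipeline output: per-mutation cycle table plus optional comparison."""

    per_mutation: pd.DataFrame
    comparison: ComparisonResult | None
    settings: dict

    def to_csv(self, path: str | Path) -> None:
        header = "".join(f"# {k} = {v}\n" for k, v in sorted(self.settings.items()))
        with open(path, "w") as fh:
            fh.write(header)
            self.per_mutation.to_csv(fh, index=False, float_format=f"%.{PRECISION}f")

    def summary(self) -> str:
        lines = [
            "thermodynamic cycle report",
            *(f"  {k} = {v}" for k, v in sorted(self.settings.items())),
            "",
            self.per_mutation.to_string(index=False, float_format=lambda v: f"{v:9.4f}"),
        ]
        if self.comparison is not None:
            lines += ["", str(self.comparison)]
        return "\n".join(lines)


def run_pipeline(manifest: RunManifest) -> CycleReport:
    """Execute the full cycle pipeline described by a manifest.

    For each mutation: obtain per-window samples for the apo and holo
    legs (simulated or parsed), subsample to independent data, estimate
    each window, accumulate the leg, apply additive corrections, orient
    into the wild-type -> mutant convention, and assemble ddG. If an
    experiment table is configured, deviations and the MAE are computed.
    Identical manifest and seed give an identical report.
    """
    corrections = (
        CorrectionSet.from_csv(manifest.corrections_path)
        if manifest.corrections_path
        else None
    )
    rows = []
    computed: list[DeltaDeltaG] = []
    for m_idx, (mutation, cfg) in enumerate(sorted(manifest.mutations.items())):
        direction = cfg.get("direction", "forward")
        legs = {}
        for leg_idx, leg_name in enumerate(("apo", "holo")):
            if leg_name not in cfg:
                raise ValueError(f"mutation {mutation!r}: missing {leg_name} leg")
            leg_seed = manifest.seed + 1000 * m_idx + 100 * leg_idx
            windows = _leg_windows(manifest, mutation, leg_name, cfg[leg_name], leg_seed)
            logger.info(
                "%s/%s: %d windows, %d samples/direction",
                mutation,
                leg_name,
                len(windows),
                windows[0].forward_dU.size if windows else 0,
            )
            try:
                estimates = [
                    estimate_window(
                        w,
                        method=manifest.method,
                        decorrelate=manifest.decorrelate,
                        tolerance=manifest.tolerance,
                    )
                    for w in windows
                ]
            except ValueError as err:
                raise ValueError(f"{mutation}/{leg_name}: {err}") from err
            total = accumulate(estimates)
            label = cfg.get(f"{leg_name}_label", f"{mutation}:{leg_name}")
            legs[leg_name] = LegResult(
                leg=leg_name, estimate=total, system_label=label, mutation=mutation
            )
        if corrections is not None:
            apo_leg, holo_leg = apply_corrections(
                [legs["apo"], legs["holo"]], corrections
            )
        else:
            apo_leg, holo_leg = legs["apo"], legs["holo"]
        result = orient(ddg(apo_leg, holo_leg), direction)
        computed.append(result)
        rows.append(
            {
                "mutation": mutation,
                "direction": direction,
                "dG3_apo": apo_leg.estimate.value,
                "dG3_stderr": apo_leg.estimate.stderr,
                "dG4_holo": holo_leg.estimate.value,
                "dG4_stderr": holo_leg.estimate.stderr,
                "ddG": result.value,
                "ddG_stderr": result.stderr,
            }
        )
    comparison = None
    if manifest.experiment_table_path:
        table = read_experiment_table(manifest.experiment_table_path)
        comparison = compare_to_experiment(computed, table)
    settings = {
        "temperature_K": manifest.temperature,
        "seed": manifest.seed,
        "method": manifest.method,
        "n_windows": manifest.n_windows,
        "n_steps_per_window": manifest.n_steps_per_window,
        "decorrelate": manifest.decorrelate,
    }
    return CycleReport(
        per_mutation=pd.DataFrame(rows), comparison=comparison, settings=settings
    )
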