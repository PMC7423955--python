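"""Convergence and pathology diagnostics for alchemical transformations.

Poor phase-space overlap between the forward and reverse directions of a
transformation — typical when flexible charged side chains decouple from
their salt-bridge partners — shows up as (i) low overlap between the
forward work distribution and the negated reverse work distribution,
(ii) hysteresis, i.e. a nonzero sum of the independently computed
forward and reverse transformation free energies, and (iii) dihedral
angle populations inconsistent with the fully interacting system. This
module quantifies all three, plus neighbor counting used for hydration
analysis (e.g. waters within 3 A of a mutating residue).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .estimators import FreeEnergyEstimate

__all__ = [
    "OverlapReport",
    "AngleSample",
    "HysteresisReport",
    "work_overlap",
    "hysteresis",
    "circular_mean",
    "count_within",
    "count_within_frames",
    "plot_overlap",
    "plot_polar_histogram",
]

#: Overlap coefficients below this value warrant a convergence warning.
LOW_OVERLAP_WARNING = 0.03


@dataclass(frozen=True)
class OverlapReport:
    """Shared-grid histograms of forward and negated-reverse work.

    ``overlap_coefficient`` is the integral of the pointwise minimum of
    the two normalized densities: 1 for identical distributions, 0 for
    disjoint supports.
    """

    bin_edges: np.ndarray
    density_forward: np.ndarray
    density_reverse_negated: np.ndarray
    overlap_coefficient: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap_coefficient <= 1.0 + 1e-12:
            raise ValueError("overlap coefficient must lie in [0, 1]")

    @property
    def is_poor(self) -> bool:
        return self.overlap_coefficient < LOW_OVERLAP_WARNING


@dataclass(frozen=True)
class AngleSample:
    """Dihedral angle observations in degrees, wrapped to (-180, 180]."""

    angles: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        wrapped = wrap_angles(np.asarray(self.angles, dtype=float))
        object.__setattr__(self, "angles", wrapped)


@dataclass(frozen=True)
class HysteresisReport:
    """Path-dependence check between opposite-direction transformations."""

    discrepancy: float
    stderr: float
    flagged: bool


def wrap_angles(angles: np.ndarray) -> np.ndarray:
    """Wrap angles in degrees to the principal interval (-180, 180]."""
    wrapped = np.mod(angles, 360.0)
    wrapped = np.where(wrapped > 180.0, wrapped - 360.0, wrapped)
    # map -180 -> 180 so the interval is half-open on the left
    return np.where(wrapped == -180.0, 180.0, wrapped)


def work_overlap(
    forward_w: Sequence[float] | np.ndarray,
    reverse_w: Sequence[float] | np.ndarray,
    n_bins: int = 50,
) -> OverlapReport:
    """Histogram overlap of forward and negated reverse work values.

    Both sample sets are binned on a common grid spanning the pooled
    range; the overlap coefficient sums the pointwise minimum density
    times the bin width. Forward work distributions P_F(w) and negated
    reverse distributions P_R(-w) coincide in the limit of perfect
    sampling, so low overlap signals inadequate phase-space overlap
    between the two directions.
    """
    w_f = np.asarray(forward_w, dtype=float).ravel()
    w_r = -np.asarray(reverse_w, dtype=float).ravel()
    if w_f.size == 0 or w_r.size == 0:
        raise ValueError("both work sample sets must be non-empty")
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    pooled_min = min(w_f.min(), w_r.min())
    pooled_max = max(w_f.max(), w_r.max())
    if pooled_min == pooled_max:
        # all mass in one point: identical degenerate distributions
        pooled_min -= 0.5
        pooled_max += 0.5
    edges = np.linspace(pooled_min, pooled_max, n_bins + 1)
    dens_f, _ = np.histogram(w_f, bins=edges, density=True)
    dens_r, _ = np.histogram(w_r, bins=edges, density=True)
    width = edges[1] - edges[0]
    coeff = float(np.minimum(dens_f, dens_r).sum() * width)
    return OverlapReport(
        bin_edges=edges,
        density_forward=dens_f,
        density_reverse_negated=dens_r,
        overlap_coefficient=min(coeff, 1.0),
    )


def hysteresis(
    forward_total: FreeEnergyEstimate, reverse_total: FreeEnergyEstimate
) -> HysteresisReport:
    """Discrepancy between independently computed opposite-direction legs.

    Free energy is a state function: the forward transformation total and
    the independently computed reverse transformation total must sum to
    zero. A discrepancy beyond twice its root-sum-square standard error
    is flagged.
    """
    disc = forward_total.value + reverse_total.value
    err = math.sqrt(forward_total.stderr**2 + reverse_total.stderr**2)
    return HysteresisReport(discrepancy=disc, stderr=err, flagged=abs(disc) > 2.0 * err)


def circular_mean(sample: AngleSample) -> tuple[float, float]:
    """Mean direction and resultant length of circular angle data.

    Returns ``(mean_degrees, resultant_length)`` with the mean in
    (-180, 180]. The resultant length in [0, 1] measures concentration;
    below 1e-9 the mean direction is undefined and a ValueError is
    raised.
    """
    a = np.radians(sample.angles)
    if a.size == 0:
        raise ValueError("angle sample must be non-empty")
    s, c = np.mean(np.sin(a)), np.mean(np.cos(a))
    r = math.hypot(s, c)
    if r < 1e-9:
        raise ValueError(
            f"resultant length {r:.2e} too small: circular mean undefined"
            + (f" for {sample.label}" if sample.label else "")
        )
    mean = math.degrees(math.atan2(s, c))
    if mean <= -180.0:
        mean += 360.0
    return mean, r


def plot_overlap(report: OverlapReport, path, title: str = "") -> None:
    """Render an overlap report as a forward/negated-reverse histogram pair."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    centers = 0.5 * (report.bin_edges[:-1] + report.bin_edges[1:])
    width = report.bin_edges[1] - report.bin_edges[0]
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.bar(centers, report.density_forward, width=width, alpha=0.5, label="forward")
    ax.bar(
        centers,
        report.density_reverse_negated,
        width=width,
        alpha=0.5,
        label="reverse (negated)",
    )
    ax.set_xlabel("work (kcal/mol)")
    ax.set_ylabel("density")
    label = f"overlap = {report.overlap_coefficient:.3f}"
    ax.set_title(f"{title}  {label}".strip())
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_polar_histogram(sample: AngleSample, path, n_bins: int = 36) -> None:
    """Polar histogram of dihedral angles (default 36 bins of 10 degrees)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    theta = np.radians(sample.angles)
    counts, edges = np.histogram(theta, bins=n_bins, range=(-math.pi, math.pi))
    fig = plt.figure(figsize=(4, 4))
    ax = fig.add_subplot(projection="polar")
    ax.bar(
        0.5 * (edges[:-1] + edges[1:]),
        counts,
        width=2 * math.pi / n_bins,
        alpha=0.7,
    )
    if sample.label:
        ax.set_title(sample.label)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def count_within(
    reference_points: np.ndarray, probe_points: np.ndarray, cutoff: float
) -> int:
    """Number of probe points strictly within ``cutoff`` of any reference point.

    The boundary is exclusive: a probe at exactly the cutoff distance is
    not counted. Used for hydration counts (waters within 3 A of a
    residue) and for pruning waters overlapping a docked ligand within
    2 A.
    """
    ref = np.atleast_2d(np.asarray(reference_points, dtype=float))
    probes = np.atleast_2d(np.asarray(probe_points, dtype=float))
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    if ref.size == 0:
        raise ValueError("reference point set must be non-empty")
    if probes.size == 0:
        return 0
    dmin = cdist(probes, ref).min(axis=1)
    return int(np.sum(dmin < cutoff))


def count_within_frames(
    reference_frames: Sequence[np.ndarray],
    probe_frames: Sequence[np.ndarray],
    cutoff: float,
) -> tuple[float, float, np.ndarray]:
    """Per-frame neighbor counts aggregated to mean and standard deviation.

    Mirrors reporting of average hydration numbers with standard
    deviation error bars over trajectory frames.
    """
    if len(reference_frames) != len(probe_frames):
        raise ValueError("reference and probe frame sequences must have equal length")
    counts = np.array(
        [count_within(r, p, cutoff) for r, p in zip(reference_frames, probe_frames)],
        dtype=float,
    )
    return float(counts.mean()), float(counts.std()), counts
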