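"""RMSD computation and reverse clustering of docked ligand poses.

Docking produces many near-duplicate poses. "Reverse clustering" winnows
them to a diverse set of representatives: poses are visited best score
first and a pose is retained only if its RMSD to every representative
already kept exceeds a cutoff (3.0 A by default); otherwise it joins the
nearest representative's cluster. The retained set is pairwise more than
a cutoff apart, giving broad coverage of candidate binding modes for
downstream refinement.

Docked poses share the receptor frame, so RMSD is computed without
superposition by default; optimal-rotation (Kabsch) RMSD is available
for poses from different frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = ["Pose", "ClusterResult", "rmsd", "reverse_cluster", "read_poses_xyz", "read_poses_pdb"]

DEFAULT_CUTOFF = 3.0


@dataclass(frozen=True)
class Pose:
    """A labeled ligand coordinate set over a fixed atom ordering.

    ``score`` orders clustering visits (higher is better, e.g. a docking
    score); poses without scores are visited in input order.
    """

    label: str
    coordinates: np.ndarray
    score: float | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"coordinates must be (n_atoms, 3), got {coords.shape}")
        object.__setattr__(self, "coordinates", coords)

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]


@dataclass(frozen=True)
class ClusterResult:
    """Representatives and pose-to-representative assignment."""

    representatives: tuple[str, ...]
    assignment: dict[str, str]

    def cluster_members(self, representative: str) -> list[str]:
        return [p for p, r in self.assignment.items() if r == representative]


def _check_compatible(a: Pose, b: Pose) -> None:
    if a.n_atoms != b.n_atoms:
        raise ValueError(
            f"atom-count mismatch: {a.label!r} has {a.n_atoms}, {b.label!r} has {b.n_atoms}"
        )


def _kabsch_rmsd(p: np.ndarray, q: np.ndarray) -> float:
    """Minimum RMSD over rigid rotations after centroid alignment."""
    p = p - p.mean(axis=0)
    q = q - q.mean(axis=0)
    h = p.T @ q
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    # proper rotation only: flip the smallest singular value if needed
    e = (p**2).sum() + (q**2).sum() - 2.0 * (s[0] + s[1] + d * s[2])
    return float(np.sqrt(max(e, 0.0) / p.shape[0]))


def rmsd(a: Pose, b: Pose, superpose: bool = False) -> float:
    """Root mean square deviation between two poses (Angstrom).

    Plain coordinate RMSD by default (docked poses share a frame);
    with ``superpose`` the poses are centroid-aligned and optimally
    rotated (Kabsch) first, which can only lower the value. Symmetric in
    its arguments.
    """
    _check_compatible(a, b)
    if superpose:
        return _kabsch_rmsd(a.coordinates, b.coordinates)
    diff = a.coordinates - b.coordinates
    return float(np.sqrt((diff**2).sum() / a.n_atoms))


def reverse_cluster(
    poses: Sequence[Pose],
    cutoff: float = DEFAULT_CUTOFF,
    superpose: bool = False,
) -> ClusterResult:
    """Greedy leader clustering retaining mutually distinct poses.

    Poses are visited in descending score (stable input order on ties or
    missing scores). A visited pose becomes a new representative iff its
    RMSD to every existing representative is strictly greater than
    ``cutoff``; otherwise it is assigned to its nearest representative.
    The representative set is therefore pairwise more than ``cutoff``
    apart, and the result is deterministic given pose order and scores.
    """
    if not poses:
        raise ValueError("pose set must be non-empty")
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    order = sorted(
        range(len(poses)),
        key=lambda i: (-(poses[i].score if poses[i].score is not None else -np.inf), i),
    )
    reps: list[Pose] = []
    assignment: dict[str, str] = {}
    for i in order:
        pose = poses[i]
        dists = [rmsd(pose, rep, superpose=superpose) for rep in reps]
        if not dists or min(dists) > cutoff:
            reps.append(pose)
            assignment[pose.label] = pose.label
        else:
            nearest = reps[int(np.argmin(dists))]
            assignment[pose.label] = nearest.label
    return ClusterResult(
        representatives=tuple(r.label for r in reps), assignment=assignment
    )


def read_poses_xyz(path: str | Path) -> list[Pose]:
    """Read poses from a concatenated XYZ file (one frame per pose).

    Each frame: an atom-count line, a comment line (used as the pose
    label; a trailing ``score=<x>`` token is parsed if present), then
    one ``element x y z`` line per atom.
    """
    lines = Path(path).read_text().splitlines()
    poses: list[Pose] = []
    i = 0
    frame = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as err:
            raise ValueError(f"{path}:{i + 1}: expected atom count, got {lines[i]!r}") from err
        comment = lines[i + 1].strip() if i + 1 < len(lines) else ""
        score = None
        label = comment or f"pose{frame}"
        for tok in comment.split():
            if tok.startswith("score="):
                score = float(tok[len("score="):])
                label = comment.replace(tok, "").strip() or f"pose{frame}"
        coords = []
        for j in range(n):
            parts = lines[i + 2 + j].split()
            coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
        poses.append(Pose(label=label, coordinates=np.array(coords), score=score))
        i += 2 + n
        frame += 1
    if not poses:
        raise ValueError(f"no poses found in {path}")
    return poses


def read_poses_pdb(path: str | Path) -> list[Pose]:
    """Read poses from a multi-model PDB file, one pose per MODEL."""
    import biotite.structure.io.pdb as pdb

    f = pdb.PDBFile.read(str(path))
    stack = f.get_structure(model=None)
    coords = np.atleast_3d(stack.coord)
    if coords.ndim == 2:
        coords = coords[None]
    return [
        Pose(label=f"model{m + 1}", coordinates=coords[m]) for m in range(coords.shape[0])
    ]


def write_representatives_csv(result: ClusterResult, poses: Sequence[Pose], path) -> None:
    """Write the clustering outcome as a pose-list CSV."""
    import pandas as pd

    by_label = {p.label: p for p in poses}
    rows = [
        {
            "pose": label,
            "representative": rep,
            "is_representative": label == rep,
            "score": by_label[label].score,
        }
        for label, rep in result.assignment.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
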