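"""Winnow docked ligand poses by reverse clustering.

Builds three tight families of synthetic 8-atom poses around distinct
binding modes, then retains one representative per family: poses are
visited best docking score first, and a pose survives only if it is more
than 3 A RMSD from every representative already kept.
"""

import numpy as np

from fepkit import Pose, reverse_cluster, rmsd

rng = np.random.default_rng(4)
template = rng.uniform(-2, 2, (8, 3))
modes = {"modeA": (0.0, 0.0, 0.0), "modeB": (6.0, 0.0, 0.0), "modeC": (0.0, 7.0, 0.0)}

poses = []
for mode, center in modes.items():
    for i in range(4):
        jitter = rng.normal(0.0, 0.3, (8, 3))
        poses.append(
            Pose(
                label=f"{mode}_{i}",
                coordinates=template + np.asarray(center) + jitter,
                score=float(rng.uniform(0, 10)),
            )
        )

result = reverse_cluster(poses, cutoff=3.0)
print(f"{len(poses)} docked poses -> {len(result.representatives)} representatives")
for rep in result.representatives:
    members = result.cluster_members(rep)
    print(f"  {rep}: cluster of {len(members)} ({', '.join(sorted(members))})")

by_label = {p.label: p for p in poses}
pairs = [
    (a, b, rmsd(by_label[a], by_label[b]))
    for i, a in enumerate(result.representatives)
    for b in result.representatives[i + 1:]
]
print("pairwise representative RMSDs (all must exceed 3.0 A):")
for a, b, d in pairs:
    print(f"  {a} vs {b}: {d:.2f} A")
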