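"""Calibrate flat-bottom restraints from equilibrium distance series.

Flexible charged side chains (Arg/Lys) wander unphysically once their
nonbonded interactions decouple mid-transformation. A flat-bottom wall
placed just beyond the equilibrium distance range costs zero energy on
every calibration frame yet penalizes excursions harmonically.
"""

import numpy as np

from fepkit import propose_upper_walls, restraint_energy

rng = np.random.default_rng(8)
series = {
    "R208:NH1-D119:CG": rng.normal(3.8, 0.25, 500),
    "R208:NH1-E192:CD": rng.normal(4.3, 0.30, 500),
}
walls = propose_upper_walls(series, margin=0.5, force_constant=10.0)

for w in walls:
    calib = series[w.pair_label]
    on_input = sum(restraint_energy(d, w) for d in calib)
    print(f"{w.pair_label}: wall at {w.upper_wall:.2f} A (k = {w.force_constant:g})")
    print(f"  energy on {calib.size} calibration frames : {on_input:.1f} kcal/mol")
    print(f"  energy 1 A beyond the wall               : "
          f"{restraint_energy(w.upper_wall + 1.0, w):.1f} kcal/mol")
# Zero on every calibration frame by construction; (k/2)*1^2 = 5 kcal/mol
# one Angstrom past the wall.
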