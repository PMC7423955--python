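# fepkit

Analysis machinery for **alchemical relative binding free energy (RBFE)
calculations** of receptor mutations, built around the workflow used to
study small-molecule blockers of the Hv1 proton channel: λ-window
scheduling with dual-topology coupling, Zwanzig and Bennett-acceptance-ratio
(BAR) free-energy estimation with autocorrelation-aware subsampling,
thermodynamic-cycle ΔΔG bookkeeping with additive charge corrections,
forward/reverse convergence diagnostics, flat-bottom restraint
energetics, and reverse clustering of docked ligand poses.

It is aimed at practitioners of alchemical free energy perturbation who
want the *analysis* layer — everything between the raw per-window energy
differences an MD engine emits and the final ΔΔG-vs-experiment table —
as a tested, reusable library. A built-in Monte Carlo toy simulator with
closed-form free-energy oracles lets every estimator be validated
end-to-end without any MD engine.

## The model

A receptor mutation's effect on ligand binding is the relative binding
free energy

    ΔΔG = ΔG₂ − ΔG₁ = ΔG₄ − ΔG₃

where ΔG₁/ΔG₂ are the (experimental) binding free energies of wild type
and mutant, and ΔG₃/ΔG₄ are the *alchemical* free energies of mutating
the residue in the ligand-free (apo) and ligand-bound (holo) receptor.
Each alchemical leg is split into equally spaced λ windows (40 in the
reference protocol, the first spanning λ = 0 to 0.025). Within a window,
forward work samples w_F = U(λ_hi) − U(λ_lo) collected at λ_lo and
reverse samples w_R = U(λ_lo) − U(λ_hi) collected at λ_hi are combined
by BAR, the minimum-variance solution of

    Σᵢ f(M + β(w_F,i − ΔG)) = Σⱼ f(−M + β(w_R,j + ΔG)),  f(x) = 1/(1+eˣ)

with M = ln(n_F/n_R). Samples are first thinned by the statistical
inefficiency g = 1 + 2·(integrated autocorrelation time). Window
estimates sum to the leg total; uncertainties combine as root sum
squares. Dual-topology coupling scales outgoing electrostatics linearly
to zero over λ ∈ [0, ½], incoming electrostatics from zero over [½, 1],
and van der Waals interactions across the full range through a
Beutler-style soft-core form that stays finite at zero separation.

## Worked example

`examples/01_toy_transformation.py` samples a harmonic toy system whose
spring constant morphs from 1 to 2 kcal/mol/Å² over 10 λ windows and
compares accumulated BAR with the exact answer (kT/2)·ln 2:

```
windows sampled : 10
BAR estimate    : +0.2067 +- 0.0012 kcal/mol
analytic result : +0.2066 kcal/mol
deviation       : 0.07 standard errors
```

The estimate agrees with the closed form well inside one standard
error. `examples/02_cycle_report.py` runs the worked-example arithmetic
on the packaged six-mutation Hv1/2GBI table (experimental ΔΔG plus the
published computed values for both ligand tautomers):

```
mutation  ddg_calc  stderr_calc  ddg_expt  err_expt  deviation  within_band
   D112E      2.30         0.70      1.01      0.05       1.29         True
   V178A      0.80         0.30     -0.56      0.05       1.36         True
   S181A      1.10         0.30      0.24      0.05       0.86         True
   V109A     -0.40         0.30     -0.26      0.06      -0.14         True
   R208K      1.70         0.80     -0.01      0.05       1.71        False
   R211S     -7.10         0.70      0.11      0.05      -7.21        False
MAE = 2.1 kcal/mol over 6 mutations
MAE excluding R211S = 1.1 kcal/mol
10-fold-change band = +-1.4 kcal/mol
```

The mean absolute error for the gbi2 tautomer is 2.1 kcal/mol over all
six mutations and 1.1 kcal/mol once the pathological charge-changing
R211S mutation is excluded; the band column flags mutations whose
deviation stays within k_BT·ln 10 ≈ 1.4 kcal/mol, i.e. a 10-fold change
in the binding constant. The remaining examples cover overlap/hysteresis
diagnostics (`03`), flat-bottom restraint calibration (`04`), and
reverse clustering of docked poses (`05`).

A thin CLI wraps the same library calls:

```bash
fepkit simulate --seed 1 --out run/          # toy fepout data
fepkit estimate --forward run/forward.fepout --reverse run/reverse.fepout --temperature 300
fepkit diagnose --forward run/forward.fepout --reverse run/reverse.fepout
fepkit cycle --config manifest.yaml --out report.csv
fepkit cluster-poses --poses poses.xyz --cutoff 3.0
```

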