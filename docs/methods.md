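# Methods

## Scope and model

fepkit implements the analysis layer of a relative binding free energy
(RBFE) workflow for receptor mutations. The physical content is the
standard thermodynamic cycle: the effect of a mutation on ligand binding,
ΔΔG = ΔG₄ − ΔG₃, is computed from two alchemical legs — mutating the
residue in the apo receptor (ΔG₃) and in the holo receptor (ΔG₄) — each
discretized into λ windows sampled in both directions. The package does
not run molecular dynamics; it consumes per-window energy-difference
samples (from its fepout/CSV readers or its own toy simulator) and owns
everything downstream: estimation, error propagation, cycle assembly,
corrections, diagnostics, and pose filtering.

## Estimators

**Zwanzig (exponential averaging).** ΔG = −kT ln⟨e^(−w/kT)⟩ evaluated
through a log-sum-exp shift so arbitrarily large work values cannot
overflow. The standard error propagates the sample variance of the
normalized exponential through the logarithm (first order): σ_ΔG =
kT·sd(x/mean x)/√n. Constant-work input short-circuits to the exact
answer with zero variance.

**BAR.** The self-consistent Bennett equation with the Fermi function
and M = ln(n_F/n_R) is solved by Brent's method on a bracket seeded from
the two one-sided Zwanzig estimates widened by 50 kT, to a tolerance of
10⁻⁸ kcal/mol. The objective is monotone in ΔG, so the root is unique.
The standard error is the maximum-likelihood asymptotic variance,

    var(ΔG) = (1/β²)·[(Σ_all 1/(2 + 2cosh(M + βw − βΔG)))⁻¹ − (1/n_F + 1/n_R)],

summed over forward works and negated reverse works. When every pooled
work sits so far from the crossover that this variance is numerically
unbounded (no statistical overlap between directions), the estimator
raises rather than returning a meaningless number; the window identity
is attached by the caller. Symmetric zero-variance inputs (w_F ≡ c,
w_R ≡ −c) return exactly c with zero error.

**Decorrelation.** The statistical inefficiency g = 1 + 2·Σ C(t) is
computed from the normalized autocorrelation function, truncating the
sum at its first non-positive value and clamping g to [1, n]. Retained
indices run from 0 with stride ⌈g⌉. Each direction of each window is
thinned independently before estimation (the two chains are independent
simulations); a constant series carries no information and is assigned
g = n with a warning. Subsampling is on by default.

**Accumulation.** Windows are treated as independent: leg value = Σ
window values, leg stderr = √Σ stderr². The same root-sum-square rule
combines the apo and holo legs into the ΔΔG uncertainty.

A finite-sample caveat: the textbook sandwich "BAR lies between the
forward-Zwanzig and negated reverse-Zwanzig estimates" is an asymptotic
property; on finite samples BAR can exceed a bound by a fraction of a
standard error, and the test suite allows exactly that slack.

## λ schedule and coupling

`make_windows(n)` builds the equally spaced grid (the reference protocol
uses n = 40, first window [0, 0.025]). Dual-topology coupling follows
the split-electrostatics convention: outgoing-atom charges scale as
max(0, 1−2λ), incoming charges as max(0, 2λ−1), van der Waals linearly
across the full range. The soft-core pair energy is the Beutler-style
form E = 4ελ[s² − s], s = σ⁶/(α(1−λ)σ⁶ + r⁶), with the shift applied to
the r⁶ term only and default α = 0.5: exactly Lennard-Jones at λ = 1,
finite at r = 0 for λ < 1, zero at λ = 0. The reference workflow names
but does not define its soft-core functional form, so this choice is a
documented stand-in, not a reproduction. Likewise the linear-in-λ vdW
scale is the plain reading of full-range scaling; whether
the original engine folded the scaling entirely into the soft-core
exponent is unknowable from the description.

`simulation_time_budget` is pure bookkeeping: windows × ns/window ×
directions per mutation (40 × 5 × 2 = 400 ns in the reference protocol)
and the grand total across mutations and systems (7 × 3 × 400 ns =
8.4 μs).

## Toy simulator and oracles

The synthetic module replaces per-window MD with Metropolis Monte Carlo
on one-dimensional λ-coupled potentials:

- **harmonic**: spring constant and center interpolate linearly in λ;
  the exact end-state free-energy difference is (kT/2)·ln(k₁/k₀),
  independent of the centers. This is the oracle used throughout the
  tests.
- **softcore_lj**: a single pair separation under the soft-core coupling,
  confined to a box by reflection; no closed form, used to exercise
  end-point behavior.

Each window runs two independent chains (one per endpoint), discards the
first 20% as burn-in (mirroring a 1 ns equilibration / 4 ns production
split), and records energy differences to the opposite endpoint. Moves
are symmetric uniform displacements; the default half-width of 3.0 Å
gives ≈40% acceptance on the default harmonic spec (k: 1→2 kcal/mol/Å²
at 300 K). Per-window, per-direction random streams derive from
`numpy.random.SeedSequence(master_seed, spawn_key=(window,))` spawned
per direction, so streams are mutually independent and runs are
bit-reproducible from the master seed. k_B is fixed at 0.0019872041
kcal/mol/K; energies are kcal/mol, distances Å, temperatures K
everywhere.

What the toy data do *not* emulate: multidimensional configuration
spaces, slow collective rearrangements (solvent reorganization, side
chain flips), and the resulting long correlation times and metastability
that make real alchemical legs hard. Passing tests therefore validate
the estimators, propagation rules, and plumbing — not the adequacy of
any MD sampling protocol.

## Diagnostics

**Work overlap.** Forward works and negated reverse works are histogrammed
on a shared [min, max] grid (default 50 bins; the reference workflow does
not state a binning) and the overlap coefficient is ∫min(p_F, p_R). A
warning threshold of 0.03 flags pathological windows; the threshold is
this package's choice, since the phenomenon is described qualitatively
(bimodal work histograms) in the reference workflow. For two unit-variance Gaussians
separated by δ the coefficient is 2Φ(−δ/2), which the tests use as a
closed form.

**Hysteresis.** Independently computed opposite-direction leg totals
must sum to zero (free energy is a state function); the discrepancy is
reported with its root-sum-square error and flagged beyond 2σ.

**Circular statistics.** Dihedral samples are wrapped to (−180°, 180°];
the circular mean is atan2 of the mean sine and cosine, with the
resultant length as a concentration measure. A resultant below 10⁻⁹
(e.g. antipodal pairs) leaves the mean undefined and raises. Polar
histograms default to 36 bins of 10°.

**Neighbor counts.** Hydration-style counts use a strict `<` cutoff (a
probe at exactly the cutoff is excluded — the boundary convention is left open
by the reference protocol and is fixed here); per-frame counts aggregate to
mean ± standard deviation.

## Restraints

Flat-bottom walls are one-sided upper walls: zero energy through the
wall, (k/2)(d − wall)² beyond, continuous and once-differentiable at the
wall. The reference protocol's printed force-constant unit (10 kcal/mol/Å) is
dimensionally ambiguous for a harmonic wall and is interpreted as k =
10 kcal/mol/Å². One-sidedness follows the restraint's purpose —
preventing excursions, not compressions. `propose_upper_walls` places
each wall at the maximum observed equilibrium distance plus a margin
(default 0.5 Å), which guarantees zero restraint energy on every
calibration frame.

## Cycle bookkeeping

`ddg` enforces matching mutation labels and apo/holo roles. `orient`
maps mutant→wild-type runs into the canonical direction by negation
(stderr unchanged, label prefixed "-1x"); it is an involution.
Additive finite-size corrections for charge-changing mutations are
applied per leg with unchanged errors; the packaged set carries the
R211S values (apo −3.1042, holo gbi1 −3.1030, holo gbi2 −3.1019
kcal/mol), whose net ΔΔG effect is the difference (+0.0012 kcal/mol for
gbi1) — individually sizable, negligible relatively. Legs without an
entry default to zero with a logged warning, because charge-conserving
mutations need no correction. MAE against the experimental table is
computed at full precision and reported rounded to one decimal; the
agreement band is k_BT·ln(fold) at a fixed 300 K (≈1.4 kcal/mol for
10-fold). Computed from the rounded published per-mutation values, the
gbi1 tautomer's MAE is 3.3 (2.6 excluding R211S); the gbi2 values give
2.1 and 1.1.

## Pose filtering

RMSD is computed without superposition by default — docked poses share
the receptor frame — with optional Kabsch (SVD) superposition after
centroid alignment, which can only lower the value. Reverse clustering
is greedy leader clustering: visit poses best score first (stable input
order on ties/missing scores); retain a pose iff its RMSD to every
retained representative exceeds the cutoff (strict >, default 3.0 Å),
else assign it to the nearest representative. Representatives are
pairwise farther than the cutoff by construction and the result is
deterministic. All atoms of the pose are used; no symmetry equivalence
(e.g. near-symmetric aromatic rings) is handled — a documented
limitation.

## File formats and pipeline

The fepout dialect mirrors engine-style output: window headers
`#NEW FEP WINDOW: LAMBDA SET TO x LAMBDA2 y` and `FepEnergy:` data lines
whose 6th numeric field is ΔU and 8th is T; unknown lines are ignored;
numeric fields serialize with 6 decimals, which is the round-trip
precision contract (the trailing cumulative-ΔG column is derived, not
contractual). A headerless CSV (`lambda_low,lambda_high,step,dU`) is
accepted as an interoperability format. Run manifests (YAML) must state
temperature and seed explicitly — neither is ever silently defaulted —
and both are echoed in every report, which is byte-reproducible for a
fixed manifest and seed.

## Problem sizes

Test and validation runs use deliberately small toy problems: 5–10
windows with 10³–5×10⁴ MC steps per window, 20-seed repetition for
coverage statements (≥95% within 3σ), 10⁵-sample closed-form checks for
the Gaussian Zwanzig and overlap formulas. These sizes give standard
errors of order 10⁻³–10⁻² kcal/mol on the toy systems, ample for
3σ-level oracle comparisons.

## Known limitations

- The toy simulator is one-dimensional; it cannot reproduce sampling
  pathologies (the very phenomena the diagnostics exist for) except by
  construction in tests.
- No MBAR across all windows; estimation is pairwise per window, as in
  the reference workflow.
- Finite-size charge corrections are applied, never computed; obtaining
  them requires a Poisson–Boltzmann continuum calculation outside this
  package's scope.
- Pose RMSD ignores atom-symmetry equivalence.
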