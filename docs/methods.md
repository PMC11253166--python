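# Methods

## Model

A functional in the family is a linear combination of seven energy
components per process:

```
E = a1·E_HF-x + a2·E_aux-x + a3·E_GGA-x + a4·E_aux-c + a5·E_GGA-c
    + a6·E_MP2-ss + a7·E_MP2-os
```

(exact exchange, auxiliary exchange, (meta-)GGA exchange, auxiliary
correlation, (meta-)GGA correlation, same-spin and opposite-spin
second-order perturbative correlation). Benchmark references and component
energies are stored per *species*; a *process* is a stoichiometric
combination of species with a reference energy in kcal/mol. Component
energies are stored in hartree and converted with 627.509474 kcal/mol per
hartree when the design matrix is built.

The family is nested by the number of free parameters p = 1…7. The
reduction rules tie the dependent coefficients:

| p | free            | tied                                          |
|---|-----------------|-----------------------------------------------|
| 1 | a1 = α          | a2 = a4 = 0, a3 = 1−α, a5 = 1−α², a6 = a7 = α² |
| 2 | α, β            | a2 = a4 = 0, a3 = 1−α, a5 = 1−β, a6 = a7 = β   |
| 3 | a1, a3, a6      | a2 = a4 = 0, a5 = 1−a6, a7 = a6               |
| 4 | a1, a2, a3, a6  | a4 = 0, a5 = 1−a6, a7 = a6                    |
| 5 | + a5            | a4 = 0, a7 = a6                               |
| 6 | + a4            | a7 = a6                                       |
| 7 | all             | —                                             |

Each level embeds in the next (p = 1 → 2 via β = α²), so the minimum
training MAD is non-increasing in p. For p ≥ 2 the full coefficient vector
is an *affine* function of the free parameters, `a = M·v + b`
(`affine_expansion`); for p = 1 it is quadratic in α.

## Fitting

The fit minimizes the mean absolute deviation (MAD) of predicted process
energies from the references.

- **p ≥ 2 (exact linear program).** With residuals affine in the free
  parameters, MAD minimization is the classical least-absolute-deviations
  problem. It is solved exactly with auxiliary slack variables
  (`|r_i| ≤ s_i`, minimize mean s) via `scipy.optimize.linprog` (HiGHS).
  Free parameters are box-constrained to (−3, 3) by default — wide enough
  to be inactive for physically sensible data; an active bound is reported
  as `status="bounded"` instead of `"global"`.
- **p = 1 (grid + scalar refinement).** The objective is piecewise smooth in
  α with quadratic inner structure, so a dense grid over (−0.5, 1.5) at
  step 1e−3 is followed by bounded scalar minimization
  (`minimize_scalar`, xatol = 1e−12) inside the winning cell.
- **Degeneracy.** If the design matrix in the free-parameter basis has rank
  < p the optimum is a face, not a point; a minimal-Euclidean-norm
  representative is then selected by a constrained quadratic refinement
  (SLSQP) so results are deterministic. At full rank the HiGHS solution is
  already unique and no refinement runs. Fits with more parameters than
  processes are reported as `status="underdetermined"`.

`grid_oracle` provides an independent exhaustive check (chunked evaluation,
capped at 1e7 grid points). Because the MAD is convex in the free parameters
for p ≥ 2, staged grid shrinking and local refinement around the grid
optimum cannot lose the global minimum; the acceptance tests additionally
refine exactly by enumerating residual-zero vertices (the LAD optimum of a
convex piecewise-linear objective interpolates p processes).

## Transferability metrics

For a functional trained on set A and evaluated on set B:

```
T_B@A    = (MAD_B@A + η) / (MAD_B@B + η)          η = 0.01 kcal/mol
ΔMAD_B@A = MAD_B@A − MAD_B@B
```

η regularizes the ratio when the self-fit MAD approaches zero (noise-free
or underdetermined fits) while perturbing realistic MADs of order 1 kcal/mol
by under 1%. `T_B@B = 1` identically. When all training optima are global,
`T ≥ 1` and `ΔMAD ≥ 0`; a negative ΔMAD therefore signals a non-global
training fit and raises `NonGlobalOptimumWarning` rather than being clamped.
Absolute per-process errors are classed as good (< 1), acceptable (1–7) and
bad (> 7 kcal/mol).

`tat_matrix` assembles the full matrix over a list of sets: columns are
training sets, rows are test sets; all diagonal MADs are computed first so
every ratio uses the self-fit denominator.

## Synthetic data generator

`generate_benchset` draws seeded species (1–4 elements from a 15-element
pool; component energies scaled per component at
(0.05, 0.015, 0.05, 0.015, 0.03, 0.008, 0.02) hartree), stoichiometric
processes of 2–5 species with coefficients in {−2, −1, 1, 2}, and reference
energies `y = D·a_planted + ε` with i.i.d. Gaussian noise ε (σ in kcal/mol).
All randomness flows from one `numpy.random.SeedSequence` spawned into
separate species/process/noise streams, so results are reproducible and
individual draws do not interact.

**What it emulates**

- the exact linear component structure of the functional family, so
  fitting, nesting monotonicity and the transferability algebra behave as
  in the real setting;
- chemical *regimes*: each regime has its own planted coefficient vector,
  and optional per-component *flatness* factors shrink chosen columns of
  the design matrix. The default two-regime fixture shrinks the three
  correlation columns of the "flat" regime by (0.05, 0.02, 0.02), making
  that regime nearly insensitive to the perturbative-correlation direction
  — its fits wander along that direction and transfer badly to the "sharp"
  regime, reproducing the qualitative train/test asymmetry;
- a known noise floor: with i.i.d. Gaussian noise the large-sample MAD of
  the true model is σ·√(2/π), giving a closed-form target for recovery
  tests;
- curation pools: three regimes with imbalanced weights (4:1:1), a planted
  subset whose processes are anchored to element-diverse species and spread
  evenly over regimes, so that a diversity-times-transferability score can
  identify it against random subsets.

**What it does not emulate**

- real quantum-chemistry component energies, basis-set or geometry effects;
- correlated or systematic reference errors (noise is i.i.d. Gaussian);
- element-specific physics — elements only label species for the coverage
  count used in curation;
- realistic benchmark sizes or subset taxonomies of thermochemistry
  databases.

Problem sizes in the defaults (40 species / 160–200 processes; 72-process
curation pools) are package choices made so the full test suite runs in
minutes on one CPU, not properties of any external dataset.

## Curation

`ga_breed` searches for size-k process subsets that transfer well: fitness
of a candidate is the reciprocal of the mean transferability of the
evaluation sets under the functional fitted (p = 7 by default) on the
candidate. The GA uses tournament selection (k = 2), uniform crossover with
size repair, per-slot mutation (rate 0.05), elitism of 2, population 32 and
200 generations; each run draws from `default_rng([seed, run])`. Candidate
quality is then scored as

```
score = N_elements / mean_p T̄_p,     p ∈ {1, 4, 7}
```

— element coverage divided by the mean transferability over small, medium
and saturated fits — and `select_best` picks the argmax (ties broken toward
higher coverage, then lexicographically). `exhaustive_best` enumerates all
subsets for small pools and serves as the oracle in tests.

## Numerical choices

- LP solver: HiGHS via `scipy.optimize.linprog`; deterministic for
  full-rank designs.
- Tolerances: fit optimality 1e−8; matrix diagonal law asserted at 1e−9;
  off-diagonal lower bound at 1 − 1e−6; oracle agreement at 1e−5 kcal/mol;
  nesting monotonicity at 1e−6.
- Energies are handled in kcal/mol throughout the fitting layer; CSV output
  keeps 12 significant digits so round-trips preserve fits to well below
  all tolerances.
- Seeds: every public generator takes an explicit seed; derived seeds stay
  below 2³¹.

## Limitations

- LAD fits on very small sets (≈ 12 processes against 7 parameters) are
  volatile: tiny reference perturbations can move the optimum to a
  different vertex. The curation fixtures use pools large enough for the
  planted subset to be identifiable, but individual random pool seeds can
  still produce landscapes where random subsets score close to the planted
  one.
- `T ≥ 1` is guaranteed only when the training fit is global; box-bounded
  or underdetermined fits can break the bound, which is why fit status is
  carried through the matrices.
- The η regularizer makes T insensitive to MADs below ~0.01 kcal/mol by
  design; comparisons between near-interpolating fits should use ΔMAD.
- The two-regime asymmetry direction is a statistical property of the
  generator: it holds for the default fixture and for the large majority of
  seeds, but not necessarily for every seed at every p.
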