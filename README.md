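# tatkit

A toolkit for assessing the **transferability** of empirically fitted
density-functional approximations across benchmark datasets.

## The problem

Modern double-hybrid density functionals are linear combinations of up to
seven energy components (exact exchange, semilocal exchange and correlation,
and spin-resolved second-order perturbation terms) whose mixing coefficients
are fitted to a training benchmark. A functional that reaches a low mean
absolute deviation (MAD) on its training set may still perform poorly on
chemistry it was not trained on — the fit can exploit idiosyncrasies of the
training data rather than capture transferable physics. This package
quantifies that effect:

- **Fit** a p-parameter functional (p = 1…7, nested families) to any
  benchmark set by minimizing the MAD exactly.
- **Cross-evaluate** the fitted functional on other sets and form the
  transferability ratio `T_B@A = (MAD_B@A + η) / (MAD_B@B + η)`: how much
  worse set B is described by the functional trained on A than by the
  functional trained on B itself. `T_B@B = 1` by construction, and `T ≥ 1`
  whenever the training optimum is global.
- **Diagnose** overfitting (T grows with p while the training MAD shrinks)
  and **curate** compact, transferable training sets with a genetic search.

Because real benchmark data require quantum-chemistry component energies,
the package ships a synthetic-data generator that emulates the *structure*
of the problem (linear component model, chemical regimes, stoichiometric
reactions, noisy references) and makes every statistical claim testable at
desk scale.

## Quickstart

Generate a two-regime synthetic benchmark (a "sharp" regime, sensitive to
the perturbative-correlation fraction, and a "flat" regime that barely is),
fit a 2-parameter functional, and compute the transferability matrix:

```python
import numpy as np
from tatkit import fit, generate_two_regime, tat_matrix

sharp, flat = generate_two_regime(seed=0)

res = fit(sharp, p=2)
print("fit on 'sharp':", "a =", np.round(res.a, 4),
      f"MAD = {res.mad:.3f} kcal/mol ({res.status})")

tm = tat_matrix([sharp, flat], p=2)
print(tm.to_frame().round(3))
```

Output:

```text
fit on 'sharp': a = [0.5555 0.     0.4445 0.     0.5938 0.4062 0.4062] MAD = 4.576 kcal/mol (global)
                                    sharp  flat
test_set (rows) \ train_set (cols)
sharp                               1.000  2.63
flat                                1.222  1.00
```

Read the matrix by columns: the functional trained on `flat` transfers badly
to `sharp` (T = 2.63) because the flat regime leaves the perturbative
fraction nearly unconstrained, while the `sharp`-trained functional
transfers comparatively well (T = 1.22). The diagonal is 1 by definition.

The same model is available as a scikit-learn estimator on raw design
matrices:

```python
from tatkit import XygRegressor, design_matrix, reference_energies

X, y = design_matrix(sharp), reference_energies(sharp)
est = XygRegressor(p=2).fit(X, y)
est.coef_      # full 7-vector of mixing coefficients
est.mad_       # training MAD in kcal/mol
```

## Command line

Every operation is also exposed through the `tatkit` CLI:

```bash
tatkit simulate --seed 3 --out data/            # write species.csv / processes.csv
tatkit validate --species data/species.csv --processes data/processes.csv
tatkit fit      --species ... --processes ... --set sharp --p 2
tatkit tat      --species ... --processes ... --sets sharp,flat --p 2 --out out/
tatkit curate   --species ... --processes ... --eval-sets r1,r2 --size 4 \
                --candidates 2 --seed 1 --out curated/
```

## Reproducing results

The whole analysis pipeline runs end-to-end from one script:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

It derives all randomness from `--seed`, exercises every major code path
(matrix laws, fit-vs-oracle agreement, MAD monotonicity over p, planted-model
recovery and the noise floor, the two-regime asymmetry, the overfitting
trend, and GA curation against an exhaustive oracle) and writes each summary
quantity as `{"name": {"value": ..., "n": ...}}`. The test suite
(`pytest -q`) asserts the corresponding tolerances; `tests/test_acceptance.py`
contains the end-to-end property checks and the unit modules cover each
subsystem. See `docs/methods.md` for the model, the numerical choices and
the generator's scope and limitations.

## Package layout

- `tatkit.chem_data` — species/process/benchmark-set data model and CSV I/O
- `tatkit.xyg_model` — the 7-component functional family, reduction rules,
  design matrices
- `tatkit.metrics` — MAD, transferability ratio, ΔMAD, error classes
- `tatkit.fitting` — exact MAD minimization (LP for p ≥ 2, grid + scalar
  refinement for p = 1), `XygRegressor`, grid oracle
- `tatkit.tat_analysis` — transferability matrices, accuracy limits, error
  summaries
- `tatkit.curation` — genetic subset search and diversity scoring
- `tatkit.synthetic_data` — seeded benchmark generators (single- and
  two-regime, curation pools)
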