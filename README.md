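# carslogit

Wrapper-based variable selection for binary classification, built for
risk-factor screening in epidemiology: which of many categorical
predictors (demographic, financial, health-related indicators of an
outcome such as perinatal mortality) belong in a logistic regression
model?

The package couples **competitive adaptive re-weighted sampling (CARS)**
with maximum-likelihood logistic regression, and ships a
forward-selection logistic baseline plus a five-criterion assessment
harness so the two strategies can be compared on synthetic or
user-supplied tabular data.

## The algorithm

For a binary response *Y* and an *s* × *v* predictor matrix *X*, the
logistic model is

    logit(P(Y=1)) = α + c·x

Selection proceeds over *N* Monte-Carlo sampling runs (default 50).
At run *i*:

1. **Monte-Carlo sampling** — fit the model on a random 80% row
   subsample using the currently surviving variables.
2. **Coefficient weights** — give each survivor the normalized weight
   *hᵢ = |cᵢ| / Σⱼ|cⱼ|*.
3. **Forced elimination** — an exponentially decreasing function (EDF)
   fixes the fraction kept at run *i*: *qᵢ = z·e^(−t·i)* with
   *z = (v/2)^(1/(N−1))* and *t = ln(v/2)/(N−1)*, so *q₁ = 1* (all
   variables enter run 1) and *q_N = 2/v* (two remain at run *N*); the
   lowest-weight variables are removed down to that count.
4. **Adaptive re-weighted sampling (ARS)** — the survivors are
   resampled with replacement with probability proportional to weight;
   the distinct drawn set is the competitive survivor pool.
5. **Scoring** — the pool is scored by 10-fold cross-validated deviance
   on the full data.

The subset with the lowest cross-validation score wins ("survival of
the fittest"), is refit on all rows, and is pruned to the variables
with Wald *p* < 0.05. Models are assessed by AIC, BIC, McFadden R²,
adjusted McFadden R², and Cox & Snell R², and reported as odds ratios
with Wald confidence intervals.

An assumption pipeline (near-zero-variance filter, outlier removal by
standardized Pearson residual, |r| > 0.7 pairwise-correlation filter,
binned-residual diagnostic) prepares raw tables for selection.

## Worked example

```python
from carslogit import SimConfig, generate, run_cars

config = SimConfig(n_samples=2000, n_variables=50,
                   informative_indices=(0, 1, 2, 3, 4),
                   effect_sizes=(1.0,) * 5, intercept=-2.5, seed=42)
dataset, truth = generate(config)
result = run_cars(dataset, N=50, k_folds=10, seed=42)
print(result.selected_names(dataset))
```

Running `python examples/01_simulate_and_select.py` prints:

```
data: 2000 x 50, event rate 0.522, planted columns [0, 1, 2, 3, 4]
CARS selected ['X1', 'X2', 'X3', 'X4', 'X5', 'X30', 'X47'] (best run 2)
cross-validated deviance of winner: 0.5828 nats/observation
  X1: OR 2.84 [2.29, 3.53], p = 3.87e-21
  ...
```

All five planted columns are recovered; their odds ratios sit near
e ≈ 2.72, the value implied by the planted unit log-odds effect, while
the two false inclusions hover just above OR 1.2.
`examples/02_compare_with_forward_selection.py` runs the comparison
harness (selection on a 70% training split, the five criteria computed
on the 30% test split) and prints, for the same kind of data:

```
CARS selected    [0, 1, 2, 3, 4]
forward selected [0, 1, 2, 3, 4, 10, 12, 22, 31, 35, 39]
subset overlap (Jaccard): 45.5%
metric                    CARS     forward
aic                   712.9383    733.6890
mcfadden_r2             0.1546      0.1440
```

— the parsimonious CARS subset generalises better than the forward
selection, which keeps several noise columns.

## Command line

```sh
carslogit simulate --n-samples 2000 --n-variables 50 --n-informative 5 \
    --intercept -2.5 --seed 1 --out sim.csv
carslogit run --input sim.csv --response Y --seed 1 --out-dir out/
carslogit compare --input sim.csv --response Y --seed 1 --out-dir cmp/
```

Each command writes `results.json` (full trace), `summary.tsv`
(odds-ratio table) and, where applicable, `preprocess.json` and
`comparison.tsv`.

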