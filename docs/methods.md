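# Methods

## Problem and data

The package models the yield (percent of plant dry mass) of polysaccharides
extracted from *Radix Actinidiae Chinensis* (PRAC) by microwave-assisted
extraction, as a function of four process factors:

| symbol | factor | unit | levels (−1 / 0 / +1) |
|---|---|---|---|
| A | liquid-to-solid ratio | mL/g | 14 / 18 / 22 |
| B | extraction temperature | °C | 60 / 80 / 100 |
| C | extraction time | min | 60 / 90 / 120 |
| D | microwave power | W | 300 / 400 / 500 |

The packaged dataset (`pracopt/data/prac_bbd29.csv`, mirrored in
`designs/`) is the published 29-run, three-level Box-Behnken design — 24
edge runs plus 5 center replicates — together with the per-run predictions
of the four models the original study compared.  A note on provenance: the
source table's second, third and fourth column headers are mutually
swapped (the values in the "power" column run 60–100, etc.); the packaged
CSV assigns each column the factor whose published level set matches its
values, which is also the only assignment under which the fitted surface
evaluated at the center reproduces the published center prediction
(≈ 3.01 %) and all published optima fall inside their factor ranges.
Yields are stored as percent, never fractions.

## Response-surface model

The surface is the full second-order polynomial in k = 4 factors
(15 terms: intercept, 4 linear, 6 two-way interactions, 4 pure quadratics),
fitted by ordinary least squares (statsmodels OLS behind
`rsm.fit_quadratic`).  A model can carry its coefficients in actual units
or on the coded (−1, 0, +1) scale; because coding is affine, the conversion
is exact (polynomial re-expansion, no refitting).

**ANOVA.** Per-term sums of squares are Type III (reduced-model refits) and
are always computed on the coded basis.  This is deliberate: Type-III SS of
lower-order terms is not invariant under affine reparameterization, and the
coded basis — under which a Box-Behnken design is near-orthogonal — is the
convention of standard DoE software and the one that reproduces the
published per-factor F statistics.  A consequence is that the reported
per-term SS are identical whichever unit system the model object uses.
F ratios use MS(term)/MS(Residual); p-values come from the one-sided F
distribution (stored exact; a display layer may floor at "< 0.0001").
Pure error is estimated from replicate groups (runs with identical
settings); with no replicates the lack-of-fit rows are omitted and the
table carries a `pure_error_undefined` flag.  When the replicates agree
exactly (noise-free data) the lack-of-fit F ratio is undefined and left as
`None`.  CV% = 100·√MS(Residual)/ȳ.

**PRESS / predicted R².** Leave-one-out PRESS uses the hat-matrix identity
eᵢ/(1−hᵢᵢ); predicted R² = 1 − PRESS/SS(total).  The hat matrix depends
only on the basis column space, so units are irrelevant.  Runs with
leverage 1 make PRESS undefined: `press_and_predicted_r2` raises, and
`anova` degrades to `pred_r2 = None`.

**Surface maximization.** A quadratic over a box can peak on the boundary,
so `optimize_surface` runs projected-gradient L-BFGS-B from all 2ᵏ corners
plus the center (analytic gradient, ftol 1e-12) and breaks value ties
toward lexicographically smallest settings.  On the packaged data the
box-constrained maximum of the refit surface is 4.65 % at
(22 mL/g, 100 °C, 120 min, 300 W) — the time boundary, not the published
"95 min" optimum (4.17 %), which evidently reflects an unreported
desirability setting in the original software.  Both results are left to
stand; the package reports the mathematical maximum of the polynomial it
fitted.  Evaluating the *published* coefficients is a separate code path
(`published_yield_model`), because their printed rounding shifts
predictions by about 0.01.

## Neural surrogates

The surrogate is a 4–h–1 feedforward regressor: tanh hidden layer, linear
output.  Inputs and response are min–max scaled to [−1, 1] on the training
data only (hand-rolled 15-line scaler so a trained network serializes to
JSON without extra dependencies; columns of zero range map to 0 and back).
Candidate hidden sizes follow round(√(n_in+n_out)) + a, a = 1…10, and
`select_hidden_size` picks the training-MSE minimizer (ties to the smaller
h); h = 4 — the published choice — is the default elsewhere.

**Backpropagation** is plain full-batch gradient descent with a fixed
learning rate (default 0.05), budget 1000 epochs, stopping when the
scaled-space training MSE drops below 1e-5 (the published stopping target).
Weights initialize uniform(−0.5, 0.5) from the seeded generator.  The
trainer returns the best parameters seen, so the final training MSE never
exceeds the initial one even if a late step overshoots.  Momentum,
adaptive rates and validation-based early stopping are deliberately out of
scope.  Note the optimizer's reach: 1000 full-batch steps at this rate do
*not* interpolate the training set (typical scaled training MSE ≈ 1e-2 on
the 29-run data, ≈ 3e-4 on an easy linear target) — this matters for how
the model comparison behaves, see below.

**GA** (`ga_minimize`): real-coded, population 30, 50 generations,
crossover probability 0.8 (arithmetic blend), per-gene Gaussian mutation
probability 0.2 (σ = 10 % of the bound width), tournament selection of
size 2, one-elite elitism — the published budget with standard operators
where the study is silent.  Non-finite objective values are penalized
(1e12), not fatal.

**ACO** (`aco_minimize`): the continuous weight space is discretized to a
per-parameter candidate grid (default 40 points over [−3, 3] in scaled
space; tanh saturates beyond ±3 once inputs are in [−1, 1]).  One
pheromone value per (parameter, candidate).  Ant choice: greedy argmax
with probability q0 = 0.2 ("transition probability constant"), otherwise
pheromone-proportional roulette; zero-pheromone rows fall back to uniform.
Update: τ ← 0.9·τ + deposit on the iteration-best path ("volatilization
coefficient" 0.9 read as retention; the opposite reading is one config
field away), with the deposit normalized so the initial total pheromone is
1 ("total amount of information").  Budget mirrors the GA (30 ants, 50
iterations) where the study is silent.

**Hybrids.** `train_ga_bp` runs the GA directly on the flattened 25-vector
of weights/thresholds (objective: scaled training MSE) and hands the best
individual to backpropagation.  `train_ga_aco_bp` is three-stage: (1) a GA
searches per-candidate pheromone-bias vectors (one gene per grid column,
shared across parameters), each scored by the best MSE a short fixed-seed
ACO probe (10 ants × 5 iterations) reaches from that field — one faithful
reading of "GA determines the optimal pheromones"; (2) a full ACO run with
the winning initial field searches the weight space; (3) backpropagation
refines the best ant.  Stage objectives are nonincreasing from stage 2 to
3 by the best-seen contract.

## Model comparison protocol

R² = 1 − RSS/TSS (the published formula's denominator is garbled in print;
the standard definition reproduces the published metric table), MAE and
RMSE are computed against the actual yields.  The published 12-cell
comparison is verified to be computed over **all 29 runs**, training rows
included, so `compare_models` defaults to `basis="all"` and the training
comparison in the acceptance tests likewise trains on the full design —
it is a goodness-of-fit comparison, not a held-out-generalization one.
With a seeded 21/8 split (the published protocol; row assignment was never
published and `evaluation.split` provides it) the full-29 R² of any
trainer is dominated by which 8 rows land in the test set, and medians
drop by roughly 0.1 with seed-to-seed ranges of ±0.5.

Under the defaults, the hybrid ordering of the published table emerges:
over seeds 0–4 the median full-29 R² is ≈ 0.90 for GA-ACO-BP, ≈ 0.88 for
GA-BP and ≈ 0.87 for plain BP.  The mechanism is worth stating plainly:
the fixed-rate batch optimizer is deliberately weak (see above), so a
metaheuristic warm start that places the weights in a good basin is what
backpropagation cannot achieve from a random start within its budget.  A
stronger optimizer (e.g. per-sample updates) erases the gap by making
plain BP near-perfect on this small, smooth dataset — at which point the
comparison degenerates.  Single published stochastic numbers (best fitness
0.022, stabilization at iteration 23, the per-model "optimal processes")
are seed- and implementation-dependent and are asserted only as
properties, never as values.

## Synthetic experiments

`synthetic_data` emulates the assumed data-generating process: a true
quadratic surface evaluated on a deterministic Box-Behnken design (edge
pairs in lexicographic order, then center replicates — the randomized run
order of real DoE software is not simulated) plus i.i.d. Gaussian noise.
The paper-like default uses the published coefficients with noise
sd = √0.058 ≈ 0.24 (the residual mean square of the published fit); the
center-replicate scatter alone would suggest √0.0131 ≈ 0.11.  An optional
smooth non-quadratic perturbation (amplitude·sin(1.5 zᵢ)·sin(1.5 zⱼ) in
coded units) lets tests probe lack-of-fit behaviour.  What passing tests
show: unbiased coefficient recovery, correct error scaling with noise, and
F-test power ≥ 80 % at the paper-like noise level.  What they do not show:
anything about non-Gaussian error, run-order effects, or factor ranges
beyond the design box.

## Release kinetics and assay formulas

Cumulative release follows M(t) = M∞(1 − e^(−kt)), fitted by
`scipy.optimize.curve_fit` with bounds M∞ ∈ (0, 100], k ∈ (0, 10] and
starting values M∞₀ = max(data), k₀ from the first informative point.
The published per-timepoint release data are not tabulated, so fitting is
validated by self-consistency (noiseless samples of the published curves
recover (93.47, 0.30) and (90.68, 0.24) to 1e-6) and by Monte-Carlo noise
robustness (median R² > 0.98 under unit-scale noise), not by reproducing
the published R² values.  Data that are not predominantly nondecreasing
are fitted anyway but flagged with a quality warning.  The assay formulas
(yield, purity, EE, LC, Ke) are direct mass-balance ratios with explicit
domain errors on zero denominators.

## Numerical choices and limitations

- OLS rank is checked before fitting; a rank-deficient basis raises an
  error naming the collinear terms (QR with column pivoting).
- Reported acceptance-style checks compare against published values at the
  precision those tables print.  Three ANOVA quantities and the published
  equation's intercept cannot be matched to one unit in the last printed
  digit from the packaged data, because the published response column is
  printed to 3 decimals while the original computations used unrounded
  laboratory data; the recomputed values (B-factor F 76.22 vs 76.26,
  residual SS 0.8121 vs 0.8119, predicted R² 0.3831 vs 0.3834, intercept
  −0.26471 vs −0.2634) are left to stand.
- All stochastic components draw from `numpy.random.default_rng` seeded
  through their configs; identical seeds give bitwise-identical results.
- Problem sizes in the test-suite Monte-Carlo checks (200 replicates for
  recovery/power, 100 per noise level for scaling, 5 seeds for the trainer
  comparison) were chosen to keep sampling error well below the asserted
  margins on a single CPU.
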