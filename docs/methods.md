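# Methods

This note records the models implemented in `gnetox`, the assumptions
behind them, the parameter choices that matter, and the known limits of
what the synthetic benchmark can show.

## The G-Network / RNN model

A Random Neural Network is a Markovian network of `n` spiking cells. Cell
`i` holds a non-negative integer potential; it receives exogenous
excitatory spikes (Poisson, rate `Λ(i)`) and inhibitory spikes (rate
`λ(i)`), and while excited (potential > 0) fires after exponential holding
times at total rate `r(i)`. A fired spike reaches cell `j` as excitatory
with probability `w⁺(i,j)/r(i)` (potential of `j` += 1), as inhibitory
with probability `w⁻(i,j)/r(i)` (potential −= 1, floored at 0), or leaves
the network with the residual probability `d(i)/r(i)`, where
`d(i) = r(i) − Σⱼ(w⁺(i,j)+w⁻(i,j)) ≥ 0` is the leak. The stationary joint
law of the potentials has product form, with the marginal excitation
probabilities solving

    q(i) = min(1, λ⁺(i) / (r(i) + λ⁻(i))),
    λ⁺(i) = Σⱼ q(j) w⁺(j,i) + Λ(i),
    λ⁻(i) = Σⱼ q(j) w⁻(j,i) + λ(i).

The solution exists and is unique while every unclamped ratio stays below
1 (the *stable* regime); `solve_fixed_point` iterates the map by damped
successive substitution (damping 1.0 by default, tolerance 1e-8 on the
max-abs update, cap 10,000 iterations) from `q = 0`, clamps to [0, 1] and
flags instability instead of aborting. `simulate_network` is the
independent oracle: a Gillespie simulation of the chain itself, reporting
time-averaged occupancy (fraction of time each potential exceeds 0) with
batch-means standard errors (50 batches after a 5% warm-up). The two
routes agree within Monte-Carlo error on random stable networks — this is
the package's central correctness check, since the fixed point and the
simulator share no code.

A note on monotonicity: on purely excitatory-coupled networks (`w⁻ ≡ 0`)
the fixed point is a monotone system — every `q` is non-decreasing in any
`Λ(i)` and non-increasing in any `λ(i)` — and the tests assert this.
With inhibitory synapses *componentwise* monotonicity genuinely fails
(raising one cell's excitation raises the inhibition it projects onward),
so in the general case only the own-cell response is asserted.

## RNN classifier and gradient learning

The classifier network has one input cell per descriptor, `n_hidden`
hidden cells (default 8; 4 in the benchmark harness) and one output cell,
fully recurrently connected without self-loops. Descriptors scaled to
[0, 1] enter as excitatory rates `Λ(input_i) = gain · x_i`. Two numerical
choices matter and were made once, on the small sanity tasks:

- **Auto gain** `gain = min(2.5, 10/d)` for `d` descriptors. The total
  exogenous drive then stays O(1) however wide the descriptor table is;
  with a fixed gain, hundreds of descriptors saturate every cell and
  gradients vanish.
- **Bias drive** `Λ = 0.2` on hidden and output cells. Without a baseline
  drive the output cell cannot cross mid-range scores when the weighted
  input is weak, and training stalls in the all-quiet state.

Training minimises the squared error of the output cell's `q` by
full-batch gradient descent. The gradient is exact: with
`D_i = r_i + λ⁻_i` and `Ω(j,i) = (w⁺(j,i) − q_i w⁻(j,i))/D_i`, the
sensitivity of `q` to any weight solves the linear system
`g(I − Ω) = γ`, where `γ` collects the direct dependence of `λ⁺`, `λ⁻`
and `r` on that weight (the firing rates are recomputed as weight row
sums plus a fixed leak, default 1.0, so `r > 0` always). One batched
`n×n` solve per sample per epoch gives all weight gradients as outer
products; the implementation is verified against finite differences to
1e-8. After each update the weights are projected to ≥ 0 and the
diagonal re-zeroed. Instability during training clamps scores at 1 and
continues; divergence (non-finite loss) raises, naming the epoch.
Defaults `lr = 0.5`, 200 epochs learn the 4-point AND table exactly and
separate Gaussian blobs at BA 1.0; the benchmark harness uses `lr = 2.0`,
25 epochs as its fixed budget-per-fit.

`cv_select_rnn` performs stratified K-fold selection over a
(hidden-count, learning-rate, epochs) grid by mean validation balanced
accuracy, ties resolved toward the smaller architecture and then fewer
epochs; the published description of the weight-determination procedure
is too terse to pin down, so cross-validation over the gradient-descent
hyperparameters is this package's documented reading, not a claim about
any other implementation.

## MLRNN

The MLRNN keeps the single-cell transfer `min(1, x⁺/(r + x⁻))` and uses
it feed-forward with a deliberately fixed structure: 20 inputs and 100
hidden cells. Since "20 inputs" must be produced from an arbitrary
number of descriptors while keeping rates non-negative, the package uses
a frozen random projection sampled uniform[0, 1] and column-normalised
(each input rate is a convex combination of descriptors). Each hidden
cell receives independent uniform[0, 1] excitatory and inhibitory
combinations of those 20 rates (`r_hidden = 1`). Only the readout is
trained — ridge least squares with an unpenalised intercept (fitted via
centring), the ridge strength chosen from {1e-4 … 1} by stratified CV on
balanced accuracy, ties toward the stronger ridge. Twenty independently
initialised trials are averaged: the ensemble's score is the mean score,
and the benchmark reports the mean of per-trial metrics. This ELM-style
readout is a design choice consistent with the fixed-structure,
low-training-cost character of the approach; it is not claimed to
replicate any specific prior code.

## SMOTE

`smote_augment` is a from-scratch implementation: each synthetic sample
is `p + u(n − p)` for a random minority point `p`, one of its `k = 5`
nearest minority neighbours `n` (Euclidean distance on the full
descriptor vector; distance ties broken by row index), and
`u ~ U[0, 1]`. The minority class is raised to an exact target ratio
(default 1:1, rounding the required count up); original rows are
preserved first and in order. Interpolated fingerprint coordinates stay
fractional — the synthetic cloud is continuous even on binary columns,
matching the behaviour of the standard SMOTE toolboxes. `k` is reduced
with a warning when the minority class is smaller than `k + 1`. Only
training partitions are ever augmented; the harness asserts the test
partitions are byte-identical between conditions.

## Curation

The pipeline order is fixed and logged: (1) greedy complete sub-matrix —
repeatedly delete the row or column with the largest missing fraction,
ties resolved by larger absolute count, then column before row, then
lowest index (finding the true maximum complete sub-matrix is NP-hard;
on random 7×7 masks the greedy result retains ≥ 60% of the exhaustive
optimum's cells); (2) binarisation — label 0 iff the AC50 equals the
1,000,000 inactive sentinel, compared with relative tolerance 1e-9 so
values survive CSV round-trips; (3) assays with an active fraction
strictly below 5% are dropped; (4) fingerprints present in strictly
fewer than 5% of compounds are dropped; (5) physico-chemical columns are
min-max scaled to [0, 1], constant columns mapping to 0, with the fitted
statistics returned for reuse (whole-dataset fitting is the default;
passing stored statistics gives train-only fitting).

## Benchmark harness

Per assay, R stratified random train/test partitions (default R = 50,
test fraction 0.25 — the split fraction is this package's choice, made
once) are drawn with per-cell seeds derived from the master seed through
a counter-based `SeedSequence` scheme, so any cell is reproducible in
isolation. Undefined metrics (a denominator of zero) propagate as
missing, are excluded from aggregation and counted — silently scoring
them as zero would bias BA. A failed fit is recorded with its error
message and the run continues. XGBoost runs through a thin adapter with
the library's defaults (`n_jobs = 1`, seeded).

## Synthetic data

The generator emulates the *structure* of a curated screening campaign,
with defaults shaped like the real panels this stack targets: 404
compounds × 37 assays, 74 continuous descriptors uniform on [0, 1], a
binary fingerprint block (per-fingerprint prevalence uniform on
[0.05, 0.5]; 160 columns by default — a full screening fingerprint
dictionary runs to thousands of columns, which adds bulk but no
qualitative structure at this scale), per-assay active fractions uniform
on [0.05, 0.30], and 15% missingness in the raw AC50 matrix (inactive
cells hold the sentinel; active AC50 magnitudes are log-uniform over
10⁻³–10², and are irrelevant downstream of binarisation). Labels come
from a logistic model on 10 randomly chosen informative descriptors with
coefficients ±2 (effect size chosen once so assays are learnable but far
from separable, i.e. a mid-60s test-BA regime), the intercept calibrated
by bisection so each assay's expected active fraction hits its target
exactly. Everything is a pure function of config + seed.

What the generator does *not* emulate: real descriptor correlation
structure, chemical series and scaffold clustering, assay-to-assay
correlation, and non-random missingness. Consequently the benchmark
shows that the estimators, the balancing contract and the harness behave
correctly and reproduce the expected *direction* of the
augmentation effect (sensitivity up, specificity down, for every
method); it does not certify accuracy levels on any real screening
panel.

## Problem sizes used in the shipped runs

The acceptance checks run the full pipeline at 400 compounds × 10 assays
× 48 descriptors with R = 10 repeats (script: R = 5), 20 random
2–4-cell networks at simulation horizon 1e5 (script: 10 networks at
1e4), sizes chosen as the smallest at which every qualitative effect is
stable across seeds.

## Known limitations

- The recurrent RNN trains by full-batch gradient descent with a fixed
  epoch budget; no early stopping, momentum or line search.
- The greedy sub-matrix heuristic carries no optimality guarantee beyond
  the measured ratio on small masks.
- Scores are thresholded at 0.5 (ties to the active class); no
  threshold calibration or ROC analysis is provided.
- Significance testing between methods is deliberately out of scope; the
  harness reports means, standard deviations and exclusion counts only.
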