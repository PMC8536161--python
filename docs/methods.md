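# Methods

## Models

All three ensembles operate on a common base-learner contract, the *core
learning unit* (CLU): a neural classifier (sigmoid output, binary
cross-entropy) or regressor (linear output, mean squared error) described
declaratively by a `CLUSpec` and trained by minibatch gradient descent.
Three CLU kinds are provided:

- `mlp` for tabular feature vectors — a dense stack whose widths are
  `layer_sizes`, ending in a width-1 output;
- `cnn` for single-channel images — conv(3×3)→ReLU→maxpool blocks with
  filter counts `conv_filters` (default 16/32/64), then a dense head;
- `rnn` for sequences — one GRU (or LSTM) layer with additive-attention
  pooling, then a dense head. GRU-with-attention is the default cell.

The conv/recurrent defaults are this package's own compact architectures,
chosen so that desk-scale CPU training is feasible; the framework treats
the architecture as a plug-in, and every piece is overridable through
`CLUSpec`.

**Training schedule.** The learning rate follows a step decay, λ ← λ − 0.1·λ
after every completed 50-epoch period, so after k periods λ = λ₀·0.9ᵏ.
After each epoch the validation loss is evaluated on the held-out
validation split and the weights of the epoch with the minimum validation
loss are checkpointed; training returns those weights, not the final
epoch's. A non-finite training loss aborts with a divergence error rather
than silently producing NaN predictions.

**DAL (bagging).** Member i is trained on a bootstrap resample (with
replacement, same size as the training set) drawn from a generator keyed
by `(seed, member)`; a disjoint-partition mode exists as an option. The
ensemble score is the running sum of member probabilities divided by n,
accumulated in member order, which makes the output bit-identical to an
explicit loop-and-average. A mode (majority-vote) aggregator is available;
vote ties break toward the positive class.

**GDLB (boosting).** The base prediction is the training-label mean. At
stage i the booster is fitted to the current residuals (labels minus the
running prediction); its output is added scaled by λᵢ. λᵢ is one
uniform(0,1) draw per booster from the run seed; a fixed λ or explicit
sequence can be supplied for analyses (λ = 1 is admitted so that an
exact-fit booster provably zeroes the training residual in one step). The
final raw score is clipped to [0,1] for reporting and thresholded at 0.5
for class labels — the regression-to-class conversion is otherwise
unspecified in gradient-boosted probability models, and a fixed symmetric
threshold is the least-surprising choice. The staged training MSE is
recorded at every boost, which is what the contraction tests assert on.

**DeSGEL (stacking).** Level-0 members are trained on the full training
split, differing only by their derived seeds. The level-1 classifier is
fitted on the metadata matrix (columns = member scores) computed on the
*validation* split — in-sample metadata would hand the meta-learner
memorised scores and leak. Default level-1 is scikit-learn logistic
regression; a column-mean meta-learner is provided as an analytic reference
point, since stacking with an averaging meta-learner is exactly bagging's
aggregation. If the validation split happens to contain a single class
(possible at very small sample sizes), the logistic meta-learner is
replaced by the column-mean one with a logged warning.

Member seeds are always `seed + i`, making ensembles reproducible as a
whole while keeping members distinct.

## Preprocessing

- *Tabular*: missing cells are imputed with the column mean of observed
  values (an all-missing column is an error naming the column), then
  standardised with x̂ = (x − μ)/σ, μ and σ (population form, ÷n) fitted on
  the training partition only. Zero-variance columns get σ = 1 so scaling
  degrades to centering, with a warning.
- *Splitting*: 80:4:16 train/validation/test by largest-remainder
  apportionment (ties toward train, then validation). The test partition
  is drawn once per seed and held fixed; each of the 10 folds re-permutes
  the remainder into train/validation, mirroring repeated experiments
  against one independent test set.
- *Feature ranking*: a 100-tree random forest (scikit-learn), shallow trees
  (`max_depth=2`, reflecting two-node stumps), importances normalised to
  sum to 1. Informational — features are not dropped.
- *Sequences*: each participant's minute-level series spans whole days
  (D×1440 values). A missing minute is imputed with that participant's mean
  at the same minute-of-day across days; a minute missing on every day
  falls back to the participant's overall mean, staying within-participant.
  The seven-day forward moving window then emits one 10,080-minute sample
  per start day (D − 6 samples for D ≥ 7), advancing one day per step, each
  inheriting the participant's label. A `downsample_to_daily_profile`
  option averages the seven values at each minute-of-day into a 1440-value
  daily profile; the workflow additionally bins profiles (default 15-minute
  bins) before feeding them to recurrent CLUs, since truncated
  backpropagation over 10,080 raw steps is neither necessary for the
  synthetic signal nor affordable on a CPU.
- *Images*: resized to 200×200×1 by bilinear interpolation (the workflow
  uses smaller targets at desk scale), intensities normalised to [0,1] by
  the input dtype's maximum; RGB inputs are reduced to luminance. For
  classical comparators, a convolutional autoencoder (two conv→pool blocks
  of 16/8 filters, a dense bottleneck, mirrored decoder with sigmoid
  output, MSE loss, Adam) is fitted on training images only; the frozen
  bottleneck activations are the fixed-length image features. The dense
  bottleneck makes the feature dimension an exact, freely chosen number.

No fitted transform ever sees validation or test rows; the workflow test
suite asserts this by corrupting the test partition and checking that every
fitted parameter hash is unchanged.

## Evaluation

Metrics come directly from the four confusion-matrix counts: accuracy,
precision, recall, F1, and MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
Degenerate denominators (e.g. no positive predictions) return 0 with a
warning. AUC is the Mann–Whitney rank statistic on scores — identical in
exact arithmetic to trapezoidal ROC integration and simpler to verify
against a brute-force all-pairs count. Repeated experiments are summarised
per metric as mean ± population standard deviation, formatted to two
decimals with round-half-even.

## Synthetic data

The generators pin the *shapes* of three public benchmarks: a 270×13 table
at class ratio 1.25 (150:120), an image cohort at ratio 0.37
normal:disease with heterogeneous sizes, and a 55-participant actigraphy
cohort (32 control : 23 depressed, 8–14 whole days each by default, class
amplitudes 5 vs 1 around a circadian sinusoid, noise sd 1). Class counts
use largest-remainder apportionment. Tabular class signal is a mean shift
of `effect_size` on the informative columns; image class signal is additive
bright Gaussian blobs; sequence class signal is the circadian amplitude
difference. Sequence missingness is inserted as contiguous blocks
(device-off episodes, Poisson count per day, 30–240 minutes each), not
i.i.d. points, which is what stresses the time-of-day imputer. The image
preset defaults to 200 samples: the pinned property is the class ratio and
size heterogeneity, not the original cohort size.

What passing tests on these data do **not** show: performance on the real
benchmarks. The generators have no clinical covariance structure, no
image texture, and no behavioural nonstationarity; planted-signal accuracy
is a correctness check of the pipeline, not a claim about real-world
discrimination.

## Numerical and design choices

- The neural backend is pure NumPy in float64 with explicit
  forward/backward passes; every backward pass is verified against central
  finite differences in the test suite. All randomness flows through
  `numpy.random.Generator` objects derived from (seed, purpose-key), which
  is what makes same-seed runs bitwise identical on a given platform.
- Checkpoint ties (equal validation losses) keep the earliest epoch.
- Grid selection (Phase 2) uses validation accuracy; ties prefer fewer
  sub-models, then fewer epochs. The full sweep is 5–50 sub-models ×
  50–500 epochs in steps of 50; the desk-scale default is the low corner
  (5 × 50).
- Default batch size is 32; default 10 repetitions in Phase 3, each with a
  re-drawn train/validation fold, a shifted seed, and the fixed test set.
- Ensemble calibration at null: when the planted effect is zero, the
  stacked model's held-out meta-learner recovers the base rate and its
  accuracy settles at the majority-class rate, while mean-aggregated
  sigmoid members (and clipped boosted regression) thresholded at 0.5
  hover near chance level, which on imbalanced null data lies *below* the
  majority rate. Both behaviours are label-independent — no ensemble beats
  the majority rate — and the acceptance tests assert exactly that,
  two-sidedly where base-rate calibration makes it attainable.

## Problem sizes

The test suite and the reproduction script run the tabular pipeline at
n = 500 (10 features, 4 informative, effect size 3), ensembles of 5
members/boosters with 16–8–1 MLPs for 30–50 epochs, 10 repetitions; image
and sequence paths run at reduced sizes (e.g. 32×32 images, 30-minute
sequence bins). These sizes were chosen so a full run completes in minutes
on a single CPU while leaving every contract observable.

## Known limitations

- Window samples from one participant may land in different partitions of
  the sample-level split; participant-grouped splitting is not implemented.
- Recurrent CLUs see binned daily profiles, not raw 10,080-minute windows.
- Binary classification only; no transfer learning or GPU-scale
  architectures; no calibration metrics or significance tests between
  models.
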