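# Methods

## The pipeline and its assumptions

`seqprobe` quantifies how a recurrent classifier's internal evidence about a
sequence's class develops along two axes: within an item (across timesteps)
and across training (epochs). The pipeline is: generate or load a sequence
dataset → split → balance → train the recurrent model → capture per-timestep
hidden states on the test split after every epoch → score each
(epoch, timestep) cell with a KNN probe → reduce each within-epoch curve to
descriptive metrics → compare metric tables with linear models.

The central assumption is that the LSTM hidden state `h_t` is an adequate
summary of what the network has extracted from inputs up to timestep `t`,
and that local class separability of `{(h_t, y)}` — as measured by a
distance-based classifier — is a meaningful proxy for "how much class
information the representation carries at this point". The probe is
deliberately non-parametric and training-free (lazy KNN), so the measured
curve reflects the representation, not a second model's fit.

## Model

Architecture, in order:

* **Per-timestep batch normalization.** Statistics and affine parameters are
  kept per (timestep, feature) pair and computed across the batch, so each
  timestep is normalized independently (mean 0, variance 1 per feature
  within a timestep during training). An alternative reading of
  "BatchNorm1d over a batch × T × d tensor" would pool statistics across
  features within a timestep; we normalize per feature because it preserves
  feature identity and is the behavior the shape contract describes. At
  evaluation time, running statistics (momentum 0.1) are used, so captured
  traces do not depend on how evaluation data is batched.
* **Single LSTM layer** with hidden dimension equal to the input dimension
  `d`, standard gates (input, forget, cell, output), zero initial state.
  The exposed per-timestep embedding is the hidden state `h_t`, not the cell
  state: `h_t` is the layer's output at `t` and lives in the same
  `d`-dimensional space at every timestep.
* **Linear head without activation** mapping `h_{T-1}` to class logits.

Training: Adam (lr 0.001 by default, β = 0.9/0.999, ε = 1e-8), mean
cross-entropy, seeded batch shuffling. Parameters are initialized uniformly
in `[-1/√h, 1/√h]`, the customary LSTM default; batch-norm affine parameters
start at identity. No gradient clipping — a non-finite loss raises
immediately rather than being silently handled.

The implementation is pure NumPy with analytic backpropagation through time.
At the scales this package targets (d up to a few hundred, T up to 150,
10³–10⁴ items) this is fast on a single CPU, bit-deterministic for a given
seed, and directly verifiable: the test suite checks every parameter's
gradient against central finite differences, and checks the causality
contract (`h_t` is bit-identical under any perturbation of inputs at
timesteps > t).

Traces are captured after each epoch completes (not mid-epoch), in
evaluation mode. Trailing training batches with fewer than two items are
skipped, because per-timestep batch statistics are undefined on a single
item.

## Synthetic tasks: what they emulate and what they do not

The generators produce the two input geometries the pipeline targets —
token sequences (default 66 timesteps × 300 features, the sentence-task
shape) and keypoint trajectories (default 150 timesteps × 274 features,
i.e. 137 coordinate pairs) — with controlled *information structure*:

* **Token tasks.** A fixed, seeded Gaussian token-embedding table stands in
  for pretrained word vectors: what matters structurally is that each token
  has one fixed dense vector reused across items, which a random table
  preserves; a hook accepts user-supplied token vectors. Each class owns
  `n_discriminative_tokens` private token types; each item carries that many
  informative occurrences at positions controlled by `position_profile`
  (`early` = first third, `late` = last third, `uniform` = anywhere).
  `neutral_first_token` forces timestep 0 to be byte-identical across
  classes, making the first slice provably class-uninformative.
* **Trajectory tasks.** Per item, `x_t = offset_c + drift_c · t/(T−1) + z_t`
  over its real frames, where `offset_c` and `drift_c` are fixed random
  class directions scaled by `class_offset_scale` and
  `class_dynamics_scale` (each scaled by √d so per-feature magnitudes are
  scale-free), and `z_t` is an AR(1) process with autocorrelation
  `ar_coefficient` (default 0.8 — high frame-to-frame correlation, as in
  motion data) and stationary standard deviation `noise_sd`. Items may have
  variable real lengths; frames beyond them are zero padding with a
  prefix-true mask.

These generators reproduce the *structural* features that drive the
learning-curve signatures — where in the item class information lives, how
autocorrelated the signal is, padding and class imbalance — but not the
content of real language or motion: no syntax, no token frequency spectrum,
no articulatory constraints. Tests passing on them show the pipeline
measures information placement correctly; they do not certify conclusions
about any particular real dataset.

Null constructions: `label_permutation` (default — the simplest way to
destroy the class-conditional signal while preserving both marginals),
`within_item_timestep_shuffle` (destroys temporal order, keeps item content
and labels), and `across_item_superimposition` (keeps each timestep's
marginal frame distribution, destroys within-item coherence). All preserve
the label marginal. The choice among them is an analysis decision; all
three are exposed because "reshuffled null" is not a single construction.

Splits are 64/16/20 train/val/test, computed as test = round(0.2·n) first,
then val = round(0.2·remaining), rounding half away from zero, seeded
shuffle — documented so counts are exactly reproducible. Minority classes
are up-sampled with replacement to the majority count on the training and
validation splits only (the test split keeps its natural composition).
The run planner enumerates (dataset × pair × rep × condition) with
deterministic per-run seeds derived via SHA-256 from a base seed, so a
full design (e.g. 25 reps × 15 pairs × 2 datasets = 750 ordered runs) is
reproducible from one integer.

## Probe

KNN with k = 5 by default (odd, to minimize vote ties), Euclidean distance
on raw embeddings — embeddings are treated as a location-wise projection,
so distances are meaningful without standardization; accuracy is invariant
to any global positive rescaling (tested). Evaluation protocol default is
stratified 5-fold cross-validation on the test-split embeddings: in-sample
1-NN accuracy is degenerately 1.0, so a held-out protocol is needed for the
surface to be informative. `loocv` and `insample` are selectable for
sensitivity analysis. Vote ties break by the tied classes' summed inverse
neighbor distance, then by the lower class index, making every cell of the
surface bit-reproducible given the seed.

Degenerate cells are measured honestly: if all embeddings at a timestep are
identical (e.g. timestep 0 under `neutral_first_token`, where batch
normalization maps a constant slice to a constant), the probe's accuracy
equals the realized class share behind the arbitrary-but-deterministic
constant vote — at chance in expectation, with sampling spread set by the
test-split size. This is why chance-level checks in this package use test
splits of ≥ 120 items.

## Curve metrics

For a within-epoch curve `c[0..T−1]`: `start = c[0]`, `end = c[T−1]`,
`max = max(c)`, `t_max = argmax(c)/(T−1)` with ties resolved to the first
(earliest) attaining index, `end_minus_start = end − start`. `t_max` is
normalized so 0 is the first slice and 1 the last. `end` and `max` are
taken over all T slices including any padding region, matching curves drawn
across the full padded item; callers who want real-frame-only metrics can
slice the surface by the dataset mask before reduction.

## Statistics

The long metric table has one row per (dataset, condition, class pair, rep,
epoch, metric). Rep-level records are analyzed un-averaged — pooling is
what gives the suite its statistical resolution, and small-but-significant
adjusted R² values are meaningful at that n. Epoch enters as a continuous
1-based covariate; categorical predictors are treatment-coded with the
lexicographically first level as reference.

Four families, all ordinary least squares via statsmodels:

1. *Data-source difference*: metric ~ dataset, on ordered-condition rows.
2. *Baseline null*: metric ~ condition, within one dataset.
3. *Epoch and class*: metric ~ class pair; metric ~ epoch; and
   metric ~ epoch + class pair + epoch:class pair.
4. *Class contribution*: adjusted-R² gain of the interaction model over the
   epoch-only model with the extra-sum-of-squares F test
   (`anova_lm` on the nested pair).

Adjusted R² = 1 − (1 − R²)(n − 1)/(n − p − 1). Raw p-values are always
reported next to star thresholds (0.05, 0.01, 0.001, 0.0001). No
multiple-testing correction is applied; the report counts tests run so
users can apply their own. Rank-deficient designs (e.g. class pairs nested
within dataset) raise an error naming the collinear terms rather than
silently dropping columns.

## Numerical and design choices

* Seeds: every stochastic step (generation, splitting, up-sampling, batch
  order, fold assignment) takes an explicit seed; sub-seeds derive via
  SHA-256 (stable across processes, < 2³¹).
* Batch-norm ε = 1e-5; probe tie-break ε = 1e-12 on inverse distances.
* KNN neighbor search uses scikit-learn's `NearestNeighbors`; the vote and
  tie-break are implemented here so the documented rule is exactly what
  runs. On exactly tied distances the neighbor *set* follows scikit-learn's
  deterministic index order.
* CSV I/O writes full-precision floats and reads with round-trip float
  parsing, so write→read is bit-exact. `time_slice` is 0-based in files,
  `epoch` 1-based; a dialect flag rebases 1-based time slices on read.
* Degenerate inputs fail loudly: empty splits, single-class probe labels,
  curves outside [0, 1], non-finite losses, lengths exceeding T.

## Problem sizes used in the shipped checks

The package's own verification runs scaled-down task geometries chosen so
the full suite runs in well under a minute of training time on one CPU:
d = 16, T = 12, 150–300 items per class, 10–15 epochs for token tasks;
d = 20, T = 20, 100 items per class for trajectory tasks. Full-scale
geometries (66 × 300, 150 × 274) are exercised for shape and causality
contracts via forward passes. The statistical suite's calibration check
runs 2,000 zero-effect replicates at n = 24 rows each. These sizes are
large enough for every qualitative signature the pipeline is designed to
expose (chance start under an uninformative first slice, perfect asymptotic
max on separable tasks, the offset-vs-late-information modality signature)
while keeping the default test run fast.

## Known limitations

* Single-layer unidirectional LSTM only; no attention, bidirectionality or
  deep stacks. The probing logic would extend, but the shipped model is the
  minimal architecture the method needs.
* The probe measures *local* (neighborhood) separability; a representation
  that is linearly separable but locally interleaved would be under-scored
  relative to a linear probe.
* Batch-norm trace capture uses running statistics; with very few training
  batches those statistics lag the batch statistics early in training.
* The NumPy trainer is single-threaded and not intended for GPU-scale
  replication of full designs at full dimensionality; the planner
  enumerates such designs, but executing them is a compute decision left to
  the user.
* Surfaces are probed per timestep independently; no smoothing or
  change-point analysis is applied to the curves.
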