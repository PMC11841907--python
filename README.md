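# seqprobe

Learning-curve interpretability for recurrent sequence classifiers.

When a recurrent network classifies a sequence, two timescales of "learning"
unfold at once: within a single item, the hidden state accumulates evidence
timestep by timestep (the *information-processing trajectory*), and across
training, that whole within-item curve reshapes as the network improves (the
*developmental trajectory*). `seqprobe` makes both visible and quantifiable.
It is written for computational cognitive scientists and deep-learning
researchers who want to audit *when* a sequence model extracts class
information — from the first frame of a gesture, or only after the telling
words of a sentence have arrived — rather than just whether its final
accuracy is high.

## Method

1. **Model.** A per-timestep batch-normalization layer, a single LSTM whose
   hidden dimension equals the input dimension, and a linear head (no
   activation) on the final timestep's hidden state, trained with Adam
   (lr 0.001) on cross-entropy. Under the recurrence `h_t = f(x_t, h_{t-1})`,
   the hidden state at timestep `t` summarizes inputs up to `t` only.
   Implemented in NumPy with analytic backpropagation through time, so runs
   are bit-deterministic on CPU and gradients are verified against finite
   differences in the test suite.
2. **Probing.** After every training epoch, all `T` hidden-state arrays are
   captured on the held-out test split, and a k-nearest-neighbor classifier
   (Euclidean distance, stratified cross-validation by default) scores how
   separable the classes are at each (epoch, timestep). The result is an
   `E × T` *learning-curve surface*.
3. **Metrics.** Each epoch's within-item curve is reduced to `start`, `end`,
   `max`, `t_max` (fractional position of the first maximum) and
   `end − start` (the information gain across the item).
4. **Statistics.** Metric tables are compared across data sources, class
   pairs, epochs, and reshuffled-null baselines with OLS linear models
   (adjusted R² as effect size) and nested-model ANOVA for the contribution
   of class differences beyond epoch alone.

Synthetic task generators with controlled information structure are
first-class: token-sequence tasks (class-private tokens at early/late/uniform
positions, mapped through a fixed seeded embedding table; user token vectors
accepted) and autoregressive keypoint-trajectory tasks (class signal split
between a spatial offset present from frame 0 and dynamics that accrue over
time), plus label-permutation and frame-reshuffling nulls, minority
up-sampling, 64/16/20 splits, pairwise `C(C,2)` task decomposition, and an
experiment planner.

## Worked example

A binary token task whose first token is identical across classes and whose
class-revealing tokens sit in the last third of each item:

```python
from seqprobe import (
    TokenTaskConfig, TrainConfig, ProbeConfig,
    generate_token_task, split_dataset, upsample_minority,
    train_and_trace, map_learning_surface, surface_metrics,
)

cfg = TokenTaskConfig(
    n_per_class=150, C=2, T=12, d=16, vocab_size=60,
    n_discriminative_tokens=4, position_profile="late",
    neutral_first_token=True, seed=1,
)
dataset = generate_token_task(cfg)

train, val, test = split_dataset(dataset, seed=1)
train = upsample_minority(train, seed=2)
val = upsample_minority(val, seed=3)

traces, log = train_and_trace(
    train, val, test, TrainConfig(epochs=10, batch_size=64, seed=1)
)
print(f"final validation accuracy: {log.val_accuracy[-1]:.3f}")

surface = map_learning_surface(traces, ProbeConfig(k=5, seed=1))
print(f"surface shape (epochs x time slices): {surface.performance.shape}")

last = surface_metrics(surface)[-1]
print(f"epoch 10: start={last.start:.3f}  max={last.max:.3f}  "
      f"t_max={last.t_max:.3f}  end-start={last.end_minus_start:.3f}")
```

Output:

```
final validation accuracy: 1.000
surface shape (epochs x time slices): (10, 12)
epoch 10: start=0.567  max=1.000  t_max=0.818  end-start=0.433
```

Read: the model solves the task (validation accuracy 1.0). The probe's
accuracy at the first time slice stays near chance (`start ≈ 0.5`) because
the first token carries no class signal; by the last epoch the curve climbs
to perfect separability (`max = 1.0`) late in the item (`t_max ≈ 0.82`), and
the item yields a large information gain (`end − start ≈ 0.43`) — the
signature of a task whose evidence arrives late. A trajectory task with a
class-dependent spatial offset shows the opposite signature: `start > 0.75`
and `end − start ≈ 0`.

## Command line

```bash
seqprobe run-all --demo --out runs/demo          # full scaled-down pipeline
seqprobe stats --in runs/demo/curves.csv --out stats.json
```

`run-all` writes dataset sidecars, the curve and metric CSVs (long format:
`dataset,condition,label_pair,rep,epoch,time_slice,performance`), the
statistics JSON/text report, six figures, a manifest and a log. Subcommands
`simulate`, `train`, `map`, `metrics`, `stats` and `plot` run the stages
individually.

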