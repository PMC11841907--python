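import numpy as np
import pytest

from seqprobe import (
    ProbeConfig,
    TokenTaskConfig,
    TrainConfig,
    generate_token_task,
    map_learning_surface,
    split_dataset,
    train_and_trace,
    upsample_minority,
)


@pytest.fixture(scope="session")
def small_token_dataset():
    """Late-information binary token task at unit-test scale."""
    cfg = TokenTaskConfig(
        n_per_class=60, C=2, T=8, d=8, vocab_size=40,
        n_discriminative_tokens=3, position_profile="late",
        neutral_first_token=True, seed=7,
    )
    return generate_token_task(cfg)


@pytest.fixture(scope="session")
def trained_run(small_token_dataset):
    """One trained run: (train, val, test, traces, epoch log)."""
    train, val, test = split_dataset(small_token_dataset, 7)
    train = upsample_minority(train, 8)
    val = upsample_minority(val, 9)
    cfg = TrainConfig(epochs=5, batch_size=32, learning_rate=0.001, seed=7)
    traces, log = train_and_trace(train, val, test, cfg)
    return train, val, test, traces, log


@pytest.fixture(scope="session")
def small_surface(trained_run):
    _, _, _, traces, _ = trained_run
    cfg = ProbeConfig(k=3, eval_protocol="stratified_cv", folds=4, seed=7)
    return map_learning_surface(
        traces, cfg,
        provenance={"dataset": "tok", "condition": "ordered",
                    "label_pair": "class_0/class_1", "rep": 0},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
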