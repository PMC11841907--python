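"""Recurrent sequence classifier with per-timestep embedding traces.

Architecture: per-timestep batch normalization of the inputs, a single LSTM
layer whose hidden dimension equals the input dimension (so the per-timestep
embedding lives in the same space as the input), and a linear head without
activation applied to the final timestep's hidden state.  Trained with Adam
on cross-entropy loss.

The implementation is pure NumPy with analytic backpropagation through time,
which keeps runs bit-deterministic on CPU for a given seed and makes the
gradient computation directly verifiable against finite differences.  The
quantity exposed for probing is the LSTM hidden state ``h_t`` after each
timestep: under the recurrence ``h_t = f(x_t, h_{t-1})`` it summarizes the
inputs up to and including timestep ``t`` and nothing later.

Batch normalization treats each (timestep, feature) pair independently across
the batch: batch statistics during training, running statistics in
evaluation mode, so traces captured in evaluation mode do not depend on how
the evaluation data is batched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data import SequenceDataset

__all__ = [
    "ModelSpec",
    "TrainConfig",
    "EmbeddingTrace",
    "EpochLog",
    "LSTMClassifier",
    "build_model",
    "forward_with_trace",
    "train_and_trace",
    "save_traces",
    "load_traces",
]

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


@dataclass(frozen=True)
class ModelSpec:
    """Shape contract: hidden dimension equals input dimension."""

    input_dim: int
    n_classes: int
    seq_len: int

    @property
    def hidden_dim(self) -> int:
        return self.input_dim


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 50
    batch_size: int = 64
    learning_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class EmbeddingTrace:
    """Per-timestep hidden states captured on an evaluation split.

    ``hidden`` has shape (T, n_eval, hidden_dim): one array per timestep, all
    sharing the same items and hence one label array.
    """

    epoch: int
    hidden: np.ndarray
    labels: np.ndarray
    eval_split: str = "test"

    def __post_init__(self) -> None:
        if self.hidden.ndim != 3:
            raise ValueError("hidden must be (T, n_eval, hidden_dim)")
        if self.labels.shape != (self.hidden.shape[1],):
            raise ValueError("labels must match n_eval")

    @property
    def T(self) -> int:
        return self.hidden.shape[0]

    @property
    def n_eval(self) -> int:
        return self.hidden.shape[1]


@dataclass
class EpochLog:
    """Per-epoch training diagnostics plus final held-out test metrics."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    test_metrics: dict = field(default_factory=dict)

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)


# ---------------------------------------------------------------------------
# The classifier
# ---------------------------------------------------------------------------

class LSTMClassifier:
    """Batch-norm + LSTM + linear head, NumPy, analytically differentiated.

    Gate layout in the stacked weight matrices follows the (input, forget,
    cell, output) order.  Parameters are initialized uniformly in
    ``[-1/sqrt(h), 1/sqrt(h)]`` (the customary LSTM default), batch-norm
    affine parameters at identity.
    """

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        d, h, C, T = spec.input_dim, spec.hidden_dim, spec.n_classes, spec.seq_len
        rng = np.random.default_rng(seed)
        bound = 1.0 / np.sqrt(h)

        def u(*shape):
            return rng.uniform(-bound, bound, size=shape)

        self.params: dict[str, np.ndarray] = {
            "bn_gamma": np.ones((T, d)),
            "bn_beta": np.zeros((T, d)),
            "W_x": u(4 * h, d),
            "W_h": u(4 * h, h),
            "b": u(4 * h),
            "W_out": u(C, h),
            "b_out": u(C),
        }
        self.running_mean = np.zeros((T, d))
        self.running_var = np.ones((T, d))
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # -- forward -----------------------------------------------------------

    def _batchnorm_forward(self, x: np.ndarray, training: bool, update_running: bool):
        """x: (n, T, d) -> normalized (n, T, d); caches for backward."""
        gamma = self.params["bn_gamma"]
        beta = self.params["bn_beta"]
        if training:
            mu = x.mean(axis=0)                      # (T, d)
            var = x.var(axis=0)                      # biased, used to normalize
            if update_running:
                n = x.shape[0]
                unbiased = var * n / max(n - 1, 1)
                self.running_mean = (1 - _BN_MOMENTUM) * self.running_mean + _BN_MOMENTUM * mu
                self.running_var = (1 - _BN_MOMENTUM) * self.running_var + _BN_MOMENTUM * unbiased
        else:
            mu = self.running_mean
            var = self.running_var
        inv_std = 1.0 / np.sqrt(var + _BN_EPS)
        xhat = (x - mu) * inv_std
        out = gamma * xhat + beta
        cache = (xhat, inv_std, training)
        return out, cache

    def _lstm_forward(self, x: np.ndarray):
        """x: (n, T, d) -> hidden (T, n, h); caches per-step activations."""
        n, T, _ = x.shape
        h_dim = self.spec.hidden_dim
        W_x, W_h, b = self.params["W_x"], self.params["W_h"], self.params["b"]
        h = np.zeros((n, h_dim))
        c = np.zeros((n, h_dim))
        hidden = np.empty((T, n, h_dim))
        caches = []
        for t in range(T):
            a = x[:, t] @ W_x.T + h @ W_h.T + b
            ai, af, ag, ao = np.split(a, 4, axis=1)
            i = _sigmoid(ai)
            f = _sigmoid(af)
            g = np.tanh(ag)
            o = _sigmoid(ao)
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            caches.append((x[:, t], h, c, i, f, g, o, tanh_c))
            h, c = h_new, c_new
            hidden[t] = h
        return hidden, caches

    def forward(self, x: np.ndarray, training: bool = False, update_running: bool = False):
        """Full forward pass.

        Returns (logits, hidden, caches) where hidden is (T, n, h) and logits
        are computed from the final timestep's hidden state only.
        """
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 3 or x.shape[2] != self.spec.input_dim:
            raise ValueError(
                f"expected input (n, T, {self.spec.input_dim}); got {x.shape}"
            )
        xn, bn_cache = self._batchnorm_forward(x, training, update_running)
        hidden, lstm_caches = self._lstm_forward(xn)
        logits = hidden[-1] @ self.params["W_out"].T + self.params["b_out"]
        return logits, hidden, (bn_cache, lstm_caches)

    # -- loss and gradients --------------------------------------------------

    def loss(self, x: np.ndarray, y: np.ndarray, training: bool = True) -> float:
        logits, _, _ = self.forward(x, training=training, update_running=False)
        return float(_cross_entropy(logits, y))

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray, update_running: bool = True):
        """Mean cross-entropy and analytic gradients for every parameter."""
        x = np.asarray(x, dtype=np.float64)
        y = np.asarray(y, dtype=np.int64)
        n = x.shape[0]
        logits, hidden, (bn_cache, lstm_caches) = self.forward(
            x, training=True, update_running=update_running
        )
        loss = _cross_entropy(logits, y)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite training loss ({loss}); training aborted"
            )

        p = _softmax(logits)
        dlogits = p
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n

        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        grads["W_out"] = dlogits.T @ hidden[-1]
        grads["b_out"] = dlogits.sum(axis=0)

        T = self.spec.seq_len
        W_x, W_h = self.params["W_x"], self.params["W_h"]
        h_dim = self.spec.hidden_dim
        dh_next = dlogits @ self.params["W_out"]
        dc_next = np.zeros((n, h_dim))
        dxn = np.empty((n, T, x.shape[2]))
        for t in range(T - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, g, o, tanh_c = lstm_caches[t]
            do = dh_next * tanh_c
            dc = dc_next + dh_next * o * (1.0 - tanh_c**2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            da = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)],
                axis=1,
            )
            grads["W_x"] += da.T @ x_t
            grads["W_h"] += da.T @ h_prev
            grads["b"] += da.sum(axis=0)
            dxn[:, t] = da @ W_x
            dh_next = da @ W_h
            dc_next = dc * f

        # batch-norm backward; the input gradient itself is not needed
        xhat, inv_std, _ = bn_cache
        grads["bn_gamma"] = (dxn * xhat).sum(axis=0)
        grads["bn_beta"] = dxn.sum(axis=0)
        return float(loss), grads

    # -- optimizer -----------------------------------------------------------

    def adam_step(self, grads: dict[str, np.ndarray], lr: float,
                  beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self._adam_t += 1
        t = self._adam_t
        for k, g in grads.items():
            m = self._adam_m[k] = beta1 * self._adam_m[k] + (1 - beta1) * g
            v = self._adam_v[k] = beta2 * self._adam_v[k] + (1 - beta2) * g * g
            m_hat = m / (1 - beta1**t)
            v_hat = v / (1 - beta2**t)
            self.params[k] -= lr * m_hat / (np.sqrt(v_hat) + eps)

    # -- evaluation ----------------------------------------------------------

    def predict_logits(self, x: np.ndarray) -> np.ndarray:
        logits, _, _ = self.forward(x, training=False)
        return logits

    def evaluate(self, x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
        """(mean cross-entropy, accuracy) in evaluation mode."""
        logits = self.predict_logits(x)
        loss = float(_cross_entropy(logits, y))
        acc = float((logits.argmax(axis=1) == y).mean())
        return loss, acc


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _cross_entropy(logits: np.ndarray, y: np.ndarray) -> float:
    z = logits - logits.max(axis=1, keepdims=True)
    log_p = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    return -log_p[np.arange(len(y)), y].mean()


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def build_model(d: int, n_classes: int, seed: int, seq_len: int) -> LSTMClassifier:
    """Construct the batch-norm + LSTM + linear-head classifier.

    The hidden dimension equals ``d`` so per-timestep embeddings can be
    tracked in a fixed-width space; normalization statistics are kept per
    (timestep, feature), which is why the sequence length is part of the
    model shape.
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if seq_len < 1:
        raise ValueError("seq_len must be >= 1")
    return LSTMClassifier(ModelSpec(input_dim=d, n_classes=n_classes, seq_len=seq_len), seed=seed)


def forward_with_trace(model: LSTMClassifier, x: np.ndarray,
                       training: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Run a batch through the model, returning (logits, hidden (T, n, h)).

    ``h_t`` depends only on inputs at timesteps <= t; the logits depend only
    on ``h_{T-1}``.
    """
    logits, hidden, _ = model.forward(x, training=training, update_running=False)
    return logits, hidden


def train_and_trace(
    train: SequenceDataset,
    val: SequenceDataset,
    test: SequenceDataset,
    cfg: TrainConfig,
    model: LSTMClassifier | None = None,
) -> tuple[list[EmbeddingTrace], EpochLog]:
    """Train the classifier and capture a test-split embedding trace per epoch.

    After each epoch's parameter updates the model is switched to evaluation
    mode (running normalization statistics) and the full test split is pushed
    through once, recording all T hidden-state arrays plus validation
    loss/accuracy.  The caller is expected to have balanced the training
    split (see :func:`seqprobe.data.upsample_minority`).
    """
    for part, tag in ((train, "train"), (val, "val"), (test, "test")):
        if part.n_items == 0:
            raise ValueError(f"{tag} split is empty")
    if model is None:
        model = build_model(train.d, train.n_classes, cfg.seed, train.T)
    rng = np.random.default_rng(cfg.seed)

    traces: list[EmbeddingTrace] = []
    log = EpochLog()
    n = train.n_items
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(n)
        batch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            if len(idx) < 2:
                continue  # batch statistics need >= 2 items
            loss, grads = model.loss_and_grads(train.x[idx], train.y[idx])
            model.adam_step(grads, cfg.learning_rate)
            batch_losses.append(loss)
        log.train_loss.append(float(np.mean(batch_losses)))
        v_loss, v_acc = model.evaluate(val.x, val.y)
        log.val_loss.append(v_loss)
        log.val_accuracy.append(v_acc)

        _, hidden = forward_with_trace(model, test.x, training=False)
        traces.append(EmbeddingTrace(
            epoch=epoch, hidden=hidden, labels=test.y.copy(), eval_split="test",
        ))

    log.test_metrics = _final_test_metrics(model, test)
    return traces, log


def _final_test_metrics(model: LSTMClassifier, test: SequenceDataset) -> dict:
    from sklearn.metrics import precision_recall_fscore_support

    logits = model.predict_logits(test.x)
    pred = logits.argmax(axis=1)
    loss = float(_cross_entropy(logits, test.y))
    acc = float((pred == test.y).mean())
    prec, rec, f1, _ = precision_recall_fscore_support(
        test.y, pred, average="macro", zero_division=0
    )
    return {
        "test_loss": loss, "test_accuracy": acc,
        "precision": float(prec), "recall": float(rec), "f1": float(f1),
    }


# ---------------------------------------------------------------------------
# Trace persistence: array files + JSON manifest
# ---------------------------------------------------------------------------

def save_traces(traces: list[EmbeddingTrace], directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"epochs": [], "eval_split": traces[0].eval_split if traces else None}
    for tr in traces:
        np.save(directory / f"hidden_epoch{tr.epoch:04d}.npy", tr.hidden)
        manifest["epochs"].append(
            {"epoch": tr.epoch, "shape": list(tr.hidden.shape)}
        )
    if traces:
        np.save(directory / "labels.npy", traces[0].labels)
    (directory / "traces.json").write_text(json.dumps(manifest, indent=2))
    return directory


def load_traces(directory: str | Path) -> list[EmbeddingTrace]:
    directory = Path(directory)
    manifest = json.loads((directory / "traces.json").read_text())
    labels = np.load(directory / "labels.npy")
    out = []
    for rec in manifest["epochs"]:
        hidden = np.load(directory / f"hidden_epoch{rec['epoch']:04d}.npy")
        out.append(EmbeddingTrace(
            epoch=rec["epoch"], hidden=hidden, labels=labels,
            eval_split=manifest.get("eval_split") or "test",
        ))
    return out
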