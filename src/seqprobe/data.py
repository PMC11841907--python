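"""Synthetic sequence-classification tasks with controlled information structure.

Two generators emulate the two modalities the learning-curve pipeline targets:

* **Token tasks** — discrete token sequences mapped through a fixed, seeded
  random embedding table to dense vectors (the stand-in for pretrained word
  vectors such as GloVe; user-supplied token vectors are accepted through the
  ``token_vectors`` hook).  Class identity is carried by small sets of
  class-private "discriminative" tokens whose positions are controlled, so the
  moment at which class information becomes available within an item is a
  design parameter.
* **Trajectory tasks** — continuous keypoint-like trajectories built from an
  order-1 autoregressive process around a class-dependent spatial offset
  (present from the very first frame) plus a class-dependent drift that
  accrues over time, zero-padded beyond each item's true length.

The module also provides the null constructions (label permutation, frame
reshuffling), minority up-sampling, the 64/16/20 train/val/test split,
pairwise binary task enumeration (C choose 2), the experiment-design planner,
and plain-file persistence.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "SequenceDataset",
    "TokenTaskConfig",
    "TrajectoryTaskConfig",
    "RunSpec",
    "RunPlan",
    "generate_token_task",
    "generate_trajectory_task",
    "reshuffle_null",
    "upsample_minority",
    "split_dataset",
    "pairwise_binary",
    "plan_experiment",
    "save_dataset",
    "load_dataset",
    "derive_seed",
]

NULL_STRATEGIES = (
    "label_permutation",
    "within_item_timestep_shuffle",
    "across_item_superimposition",
)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class SequenceDataset:
    """Dense per-item sequences with labels and a padding mask.

    Attributes
    ----------
    x : ndarray, shape (n_items, T, d)
        Feature vectors per timestep.  Padding timesteps are exactly zero.
    y : ndarray, shape (n_items,)
        Integer class labels covering a contiguous range ``{0..C-1}``.
    mask : ndarray of bool, shape (n_items, T)
        True where the timestep is a real (non-padding) frame.  Real frames
        always precede padding (prefix-true).
    class_names : list of str
        One name per class.
    meta : dict
        Free-form provenance (generator name, seed, config).
    """

    x: np.ndarray
    y: np.ndarray
    mask: np.ndarray
    class_names: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.int64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.x.ndim != 3:
            raise ValueError(f"x must be 3-d (n, T, d); got shape {self.x.shape}")
        n, T, _ = self.x.shape
        if self.y.shape != (n,):
            raise ValueError("y must have one label per item")
        if self.mask.shape != (n, T):
            raise ValueError("mask must be n_items x T")
        C = len(self.class_names)
        if C < 2:
            raise ValueError("need at least 2 classes")
        if n > 0:
            labels = np.unique(self.y)
            if labels.min() < 0 or labels.max() >= C:
                raise ValueError("labels must lie in {0..C-1}")
        # prefix-true mask: once padding starts it never stops
        if np.any(np.diff(self.mask.astype(np.int8), axis=1) > 0):
            raise ValueError("mask must be prefix-true (real frames precede padding)")
        if np.any(self.x[~self.mask] != 0.0):
            raise ValueError("padding timesteps must be exactly zero")

    @property
    def n_items(self) -> int:
        return self.x.shape[0]

    @property
    def T(self) -> int:
        return self.x.shape[1]

    @property
    def d(self) -> int:
        return self.x.shape[2]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def subset(self, idx: np.ndarray) -> "SequenceDataset":
        """Row subset preserving metadata."""
        return SequenceDataset(
            x=self.x[idx], y=self.y[idx], mask=self.mask[idx],
            class_names=list(self.class_names), meta=dict(self.meta),
        )


@dataclass(frozen=True)
class TokenTaskConfig:
    """Configuration for the token-sequence (sentence-like) generator.

    ``T`` and ``d`` default to the sentence-task geometry (66 timesteps of
    300-dimensional token vectors).  ``n_discriminative_tokens`` is the size
    of each class's private informative-token vocabulary; each item carries
    that many informative occurrences at positions governed by
    ``position_profile`` (early = first third, late = last third, uniform =
    anywhere, always excluding timestep 0 when ``neutral_first_token`` holds).
    """

    n_per_class: int
    C: int = 2
    T: int = 66
    d: int = 300
    vocab_size: int = 200
    n_discriminative_tokens: int = 4
    position_profile: str = "uniform"
    neutral_first_token: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T < 2:
            raise ValueError("T must be >= 2")
        if self.d < 1:
            raise ValueError("d must be >= 1")
        if self.C < 2:
            raise ValueError("C must be >= 2")
        if self.position_profile not in ("early", "late", "uniform"):
            raise ValueError(
                f"position_profile must be early/late/uniform, got {self.position_profile!r}"
            )
        if self.vocab_size < self.C * self.n_discriminative_tokens + 2:
            raise ValueError(
                "vocab_size too small for the requested discriminative tokens "
                f"({self.C} classes x {self.n_discriminative_tokens} tokens "
                "+ neutral + filler)"
            )


@dataclass(frozen=True)
class TrajectoryTaskConfig:
    """Configuration for the keypoint-trajectory (gesture-like) generator.

    ``d`` defaults to 274, read as 137 (x, y) coordinate pairs; ``T`` to 150
    frames.  ``class_offset_scale`` controls a spatial offset present from
    frame 0 (why a probe can beat chance before any movement has unfolded);
    ``class_dynamics_scale`` controls a class-specific drift that accrues
    linearly over real frames; ``ar_coefficient`` sets the frame-to-frame
    autocorrelation of the residual motion.
    """

    n_per_class: int
    C: int = 2
    T: int = 150
    d: int = 274
    ar_coefficient: float = 0.8
    class_offset_scale: float = 1.0
    class_dynamics_scale: float = 1.0
    noise_sd: float = 0.5
    real_length_distribution: Callable[[np.random.Generator, int], np.ndarray] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.ar_coefficient < 1.0):
            raise ValueError("ar_coefficient must lie in [0, 1)")
        if self.class_offset_scale < 0 or self.class_dynamics_scale < 0:
            raise ValueError("scales must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.T < 2 or self.d < 1 or self.C < 2:
            raise ValueError("invalid geometry")


@dataclass(frozen=True)
class RunSpec:
    """One simulation run in an experiment design."""

    dataset_id: str
    class_pair: tuple[int, int]
    rep_index: int
    condition: str
    seed: int


@dataclass
class RunPlan:
    """Full enumeration of an experiment design."""

    runs: list[RunSpec]

    def __len__(self) -> int:
        return len(self.runs)

    def __iter__(self):
        return iter(self.runs)


# ---------------------------------------------------------------------------
# Seeding
# ---------------------------------------------------------------------------

def derive_seed(base_seed: int, *parts) -> int:
    """Stable sub-seed derived from a base seed and identifying parts.

    Uses SHA-256 over the repr of the parts so the mapping is stable across
    processes and Python versions (unlike ``hash``).  Result is < 2**31.
    """
    key = repr((int(base_seed),) + tuple(parts)).encode()
    digest = hashlib.sha256(key).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


# ---------------------------------------------------------------------------
# Token tasks
# ---------------------------------------------------------------------------

def _token_embedding_table(vocab_size: int, d: int, seed: int) -> np.ndarray:
    """Fixed random Gaussian token-vector table, unit-ish scale."""
    rng = np.random.default_rng(derive_seed(seed, "token-table"))
    return rng.standard_normal((vocab_size, d))


def _informative_positions(rng: np.random.Generator, cfg: TokenTaskConfig) -> np.ndarray:
    lo = 1 if cfg.neutral_first_token else 0
    third = max(1, cfg.T // 3)
    if cfg.position_profile == "early":
        lo_p, hi_p = lo, max(lo + 1, third)
    elif cfg.position_profile == "late":
        lo_p, hi_p = max(lo, cfg.T - third), cfg.T
    else:  # uniform
        lo_p, hi_p = lo, cfg.T
    k = min(cfg.n_discriminative_tokens, hi_p - lo_p)
    return rng.choice(np.arange(lo_p, hi_p), size=k, replace=False)


def generate_token_task(
    cfg: TokenTaskConfig,
    token_vectors: np.ndarray | None = None,
) -> SequenceDataset:
    """Generate a token-sequence classification task.

    Token ids are laid out as: id 0 = the neutral sentence-initial token,
    ids ``1 .. C*n_disc`` = class-private discriminative tokens, the rest =
    shared filler.  Each item is a full-length sequence of filler tokens with
    ``n_discriminative_tokens`` occurrences drawn from its class's private
    set placed at profile-controlled positions, then mapped through the
    embedding table.

    Parameters
    ----------
    cfg : TokenTaskConfig
    token_vectors : ndarray (vocab_size, d), optional
        User-supplied token vectors replacing the fixed random table.
    """
    if token_vectors is None:
        table = _token_embedding_table(cfg.vocab_size, cfg.d, cfg.seed)
    else:
        table = np.asarray(token_vectors, dtype=np.float64)
        if table.shape != (cfg.vocab_size, cfg.d):
            raise ValueError(
                f"token_vectors must have shape ({cfg.vocab_size}, {cfg.d})"
            )

    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_per_class * cfg.C
    neutral_id = 0
    disc_ids = 1 + np.arange(cfg.C * cfg.n_discriminative_tokens).reshape(
        cfg.C, cfg.n_discriminative_tokens
    )
    filler_lo = 1 + cfg.C * cfg.n_discriminative_tokens

    tokens = np.empty((n, cfg.T), dtype=np.int64)
    y = np.repeat(np.arange(cfg.C), cfg.n_per_class)
    for i in range(n):
        seq = rng.integers(filler_lo, cfg.vocab_size, size=cfg.T)
        if cfg.neutral_first_token:
            seq[0] = neutral_id
        pos = _informative_positions(rng, cfg)
        seq[pos] = rng.choice(disc_ids[y[i]], size=len(pos), replace=True)
        tokens[i] = seq

    x = table[tokens]  # (n, T, d)
    mask = np.ones((n, cfg.T), dtype=bool)
    meta = {
        "generator": "token_task",
        "seed": cfg.seed,
        "config": {
            "n_per_class": cfg.n_per_class, "C": cfg.C, "T": cfg.T, "d": cfg.d,
            "vocab_size": cfg.vocab_size,
            "n_discriminative_tokens": cfg.n_discriminative_tokens,
            "position_profile": cfg.position_profile,
            "neutral_first_token": cfg.neutral_first_token,
        },
    }
    names = [f"class_{c}" for c in range(cfg.C)]
    return SequenceDataset(x=x, y=y, mask=mask, class_names=names, meta=meta)


# ---------------------------------------------------------------------------
# Trajectory tasks
# ---------------------------------------------------------------------------

def generate_trajectory_task(cfg: TrajectoryTaskConfig) -> SequenceDataset:
    """Generate a keypoint-trajectory classification task.

    Each item follows ``x_t = offset_c + drift_c * t/(T-1) + z_t`` over its
    real frames, where ``z_t`` is an AR(1) process with the configured
    autocorrelation and innovation scale, ``offset_c`` is a fixed random unit
    direction per class scaled by ``class_offset_scale`` and ``drift_c``
    likewise by ``class_dynamics_scale``.  Frames beyond the item's real
    length are zero padding.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_per_class * cfg.C
    y = np.repeat(np.arange(cfg.C), cfg.n_per_class)

    # class-specific unit directions, scaled
    def _unit_rows(k: int) -> np.ndarray:
        v = rng.standard_normal((k, cfg.d))
        return v / np.linalg.norm(v, axis=1, keepdims=True)

    offsets = _unit_rows(cfg.C) * cfg.class_offset_scale * math.sqrt(cfg.d)
    drifts = _unit_rows(cfg.C) * cfg.class_dynamics_scale * math.sqrt(cfg.d)

    if cfg.real_length_distribution is None:
        lengths = np.full(n, cfg.T, dtype=np.int64)
    else:
        lengths = np.asarray(cfg.real_length_distribution(rng, n), dtype=np.int64)
        if lengths.shape != (n,):
            raise ValueError("real_length_distribution must return n lengths")
        if np.any(lengths > cfg.T):
            raise ValueError("real lengths exceed padded length T")
        if np.any(lengths < 1):
            raise ValueError("real lengths must be >= 1")

    x = np.zeros((n, cfg.T, cfg.d))
    mask = np.zeros((n, cfg.T), dtype=bool)
    innovation_sd = cfg.noise_sd * math.sqrt(max(1.0 - cfg.ar_coefficient**2, 0.0))
    for i in range(n):
        L = lengths[i]
        mask[i, :L] = True
        z = np.zeros((L, cfg.d))
        if cfg.noise_sd > 0:
            z[0] = rng.normal(0.0, cfg.noise_sd, size=cfg.d)
            eps = rng.normal(0.0, innovation_sd, size=(L - 1, cfg.d)) if L > 1 else None
            for t in range(1, L):
                z[t] = cfg.ar_coefficient * z[t - 1] + eps[t - 1]
        frac = np.arange(L) / max(cfg.T - 1, 1)
        x[i, :L] = offsets[y[i]] + np.outer(frac, drifts[y[i]]) + z

    meta = {
        "generator": "trajectory_task",
        "seed": cfg.seed,
        "config": {
            "n_per_class": cfg.n_per_class, "C": cfg.C, "T": cfg.T, "d": cfg.d,
            "ar_coefficient": cfg.ar_coefficient,
            "class_offset_scale": cfg.class_offset_scale,
            "class_dynamics_scale": cfg.class_dynamics_scale,
            "noise_sd": cfg.noise_sd,
        },
    }
    names = [f"gesture_{c}" for c in range(cfg.C)]
    return SequenceDataset(x=x, y=y, mask=mask, class_names=names, meta=meta)


# ---------------------------------------------------------------------------
# Null constructions
# ---------------------------------------------------------------------------

def reshuffle_null(ds: SequenceDataset, strategy: str, seed: int) -> SequenceDataset:
    """Destroy class-conditional signal while preserving marginals.

    ``label_permutation`` permutes labels across items; ``within_item_timestep_shuffle``
    permutes the order of each item's real frames (labels intact);
    ``across_item_superimposition`` replaces each item's frame at t with a
    frame drawn from a random item's same timestep t (labels intact; only
    items with a real frame at t are donor candidates).
    """
    if strategy not in NULL_STRATEGIES:
        raise ValueError(f"unknown null strategy {strategy!r}; choose from {NULL_STRATEGIES}")
    rng = np.random.default_rng(seed)
    out = ds.subset(np.arange(ds.n_items))
    out.meta = dict(ds.meta)
    out.meta["null_strategy"] = strategy
    out.meta["null_seed"] = seed

    if strategy == "label_permutation":
        out.y = ds.y[rng.permutation(ds.n_items)]
        return out

    if strategy == "within_item_timestep_shuffle":
        for i in range(ds.n_items):
            L = int(ds.mask[i].sum())
            perm = rng.permutation(L)
            out.x[i, :L] = ds.x[i, :L][perm]
        return out

    # across_item_superimposition
    x_new = out.x
    for t in range(ds.T):
        donors = np.flatnonzero(ds.mask[:, t])
        if len(donors) == 0:
            continue
        recipients = np.flatnonzero(ds.mask[:, t])
        pick = rng.choice(donors, size=len(recipients), replace=True)
        x_new[recipients, t] = ds.x[pick, t]
    return out


# ---------------------------------------------------------------------------
# Balancing, splitting, pairing, planning
# ---------------------------------------------------------------------------

def upsample_minority(ds: SequenceDataset, seed: int) -> SequenceDataset:
    """Up-sample every class to the majority-class count (with replacement)."""
    counts = np.bincount(ds.y, minlength=ds.n_classes)
    if np.any(counts == 0):
        raise ValueError("cannot up-sample a class with zero items")
    rng = np.random.default_rng(seed)
    target = counts.max()
    idx_parts = []
    for c in range(ds.n_classes):
        members = np.flatnonzero(ds.y == c)
        idx_parts.append(members)
        deficit = target - len(members)
        if deficit > 0:
            idx_parts.append(rng.choice(members, size=deficit, replace=True))
    idx = np.concatenate(idx_parts)
    idx = idx[rng.permutation(len(idx))]
    out = ds.subset(idx)
    out.meta["upsampled"] = True
    return out


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def split_dataset(
    ds: SequenceDataset, seed: int
) -> tuple[SequenceDataset, SequenceDataset, SequenceDataset]:
    """Shuffled 64/16/20 train/val/test split of the items.

    Test size is ``round(0.2 n)`` first, then validation is ``round(0.2 *
    remaining)`` (round half away from zero), the rest is training.
    """
    n = ds.n_items
    if n < 5:
        raise ValueError("need at least 5 items to split")
    n_test = _round_half_away(0.2 * n)
    n_val = _round_half_away(0.2 * (n - n_test))
    n_train = n - n_test - n_val
    if min(n_train, n_val, n_test) < 1:
        raise ValueError("split produced an empty subset")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test = ds.subset(perm[:n_test])
    val = ds.subset(perm[n_test:n_test + n_val])
    train = ds.subset(perm[n_test + n_val:])
    for part, tag in ((train, "train"), (val, "val"), (test, "test")):
        part.meta["split"] = tag
        part.meta["split_seed"] = seed
    return train, val, test


def pairwise_binary(ds: SequenceDataset) -> list[SequenceDataset]:
    """Decompose a C-class dataset into C(C,2) binary tasks.

    Pairs are ordered lexicographically by class index; within each task the
    lower class index is re-encoded as 0 and the higher as 1.
    """
    out = []
    C = ds.n_classes
    for a in range(C):
        for b in range(a + 1, C):
            idx = np.flatnonzero((ds.y == a) | (ds.y == b))
            sub = ds.subset(idx)
            sub.y = (sub.y == b).astype(np.int64)
            sub.class_names = [ds.class_names[a], ds.class_names[b]]
            sub.meta["class_pair"] = (a, b)
            sub.meta["pair_label"] = f"{ds.class_names[a]}/{ds.class_names[b]}"
            out.append(sub)
    return out


def plan_experiment(
    reps: int,
    dataset_ids: Sequence[str],
    C: int,
    conditions: Sequence[str] = ("ordered",),
    base_seed: int = 0,
) -> RunPlan:
    """Enumerate every (dataset, class pair, rep, condition) run.

    The ordered-condition run count is ``reps * C(C,2) * n_datasets``; each
    run carries a deterministic seed derived from the base seed and its
    coordinates.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    runs = []
    for did in dataset_ids:
        for a in range(C):
            for b in range(a + 1, C):
                for r in range(reps):
                    for cond in conditions:
                        runs.append(RunSpec(
                            dataset_id=str(did),
                            class_pair=(a, b),
                            rep_index=r,
                            condition=cond,
                            seed=derive_seed(base_seed, did, (a, b), r, cond),
                        ))
    return RunPlan(runs=runs)


# ---------------------------------------------------------------------------
# Persistence (dense array files + JSON sidecar)
# ---------------------------------------------------------------------------

def save_dataset(ds: SequenceDataset, directory: str | Path) -> Path:
    """Save a dataset as a directory of .npy files plus a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.save(directory / "x.npy", ds.x)
    np.save(directory / "y.npy", ds.y)
    np.save(directory / "mask.npy", ds.mask)
    sidecar = {
        "shape": list(ds.x.shape),
        "class_names": ds.class_names,
        "meta": _jsonable(ds.meta),
    }
    (directory / "dataset.json").write_text(json.dumps(sidecar, indent=2))
    return directory


def load_dataset(directory: str | Path) -> SequenceDataset:
    directory = Path(directory)
    sidecar = json.loads((directory / "dataset.json").read_text())
    return SequenceDataset(
        x=np.load(directory / "x.npy"),
        y=np.load(directory / "y.npy"),
        mask=np.load(directory / "mask.npy"),
        class_names=list(sidecar["class_names"]),
        meta=dict(sidecar.get("meta", {})),
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
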