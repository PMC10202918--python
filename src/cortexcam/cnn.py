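"""Convolutional classifiers and the leave-one-subject-out training protocol.

The classifier is a C3D-style stack: three blocks of convolution ->
batchnorm -> ReLU -> max-pool, then two fully connected ReLU layers and a
single sigmoid output unit.  The 3d variant convolves 3x3x3 over
space x time volumes with pooling 2x2x1 then 2x2x2 twice; the 2d variant
convolves 3x3 over single images with 2x2 pooling throughout.

Training follows a two-stage transfer protocol per held-out patient
("specific patient", SP): pretrain on all other subjects (classes
undersampled to 1:1, 90/10 train/validation split, Adam + binary
cross-entropy, Kaiming init, learning rate from a range test, early
stopping on validation accuracy), then fine-tune only the fully connected
head — convolutional parameters frozen — on the SP's trials plus reserved
control subjects never seen in pretraining, with learning rate and weight
decay divided by 10, evaluating on a held-out 20% split.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit
from scipy.stats import rankdata

from . import nn
from .volumize import InputVolume

__all__ = [
    "ArchConfig",
    "TrainConfig",
    "Metrics",
    "VolumeDataset",
    "build_model",
    "stack_volumes",
    "lr_range_test",
    "pretrain",
    "fine_tune",
    "evaluate",
    "predict_proba",
    "rank_auroc",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class ArchConfig:
    """Network topology.  ``input_shape`` is (H, W, D) for 3d or (H, W) for
    2d; the full-scale defaults mirror the reference architecture
    (channels 64/128/256, FC width 512 on 120x120x16 inputs), while
    ``scaled()`` gives the desk-scale variant used by the tests."""

    mode: str = "3d"
    input_shape: tuple[int, ...] = (120, 120, 16)
    conv_channels: tuple[int, int, int] = (64, 128, 256)
    kernel: int = 3
    fc_width: int = 512

    def __post_init__(self):
        if self.mode not in ("2d", "3d"):
            raise ValueError(f"mode must be '2d' or '3d', got {self.mode!r}")
        want = 3 if self.mode == "3d" else 2
        if len(self.input_shape) != want:
            raise ValueError(
                f"{self.mode} input_shape needs {want} dims, got {self.input_shape}"
            )

    @property
    def pool_kernels(self) -> tuple[tuple[int, ...], ...]:
        if self.mode == "3d":
            return ((2, 2, 1), (2, 2, 2), (2, 2, 2))
        return ((2, 2), (2, 2), (2, 2))

    @staticmethod
    def scaled(mode: str = "3d", grid: int = 40) -> "ArchConfig":
        shape = (grid, grid, 16) if mode == "3d" else (grid, grid)
        return ArchConfig(
            mode=mode, input_shape=shape, conv_channels=(8, 16, 32), fc_width=32
        )


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings; ``lr = None`` triggers the range test."""

    batch_size: int = 128
    max_epochs: int = 100
    patience: int = 10
    lr: float | None = None
    weight_decay: float = 1e-5
    undersample: bool = True
    val_fraction: float = 0.10
    eval_fraction: float = 0.20  # fine-tuning evaluation split
    seed: int = 0

    def __post_init__(self):
        if self.patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")
        if min(self.batch_size, self.max_epochs, self.patience) <= 0:
            raise ValueError("batch_size, max_epochs and patience must be positive")

    @staticmethod
    def scaled(**overrides) -> "TrainConfig":
        cfg = TrainConfig(batch_size=16, max_epochs=30, patience=5)
        return replace(cfg, **overrides) if overrides else cfg


@dataclass
class Metrics:
    """Threshold metrics plus rank-based AUROC.

    Precision is NaN when nothing is predicted positive, recall is NaN
    when there are no positives, and AUROC is NaN when only one class is
    present (undefined rather than defaulted).
    """

    accuracy: float
    precision: float
    recall: float
    auroc: float
    tp: int
    fp: int
    tn: int
    fn: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("accuracy", "precision", "recall", "auroc", "tp", "fp", "tn", "fn")}


@dataclass
class VolumeDataset:
    """Stacked classifier inputs with provenance for subject-level audits."""

    X: np.ndarray  # (N, H, W[, D], 1) float32
    y: np.ndarray  # (N,) 0 = control, 1 = patient
    subject_ids: np.ndarray  # (N,) str
    trial_ids: np.ndarray  # (N,) int

    def __len__(self) -> int:
        return self.X.shape[0]

    def subset(self, idx) -> "VolumeDataset":
        return VolumeDataset(
            self.X[idx], self.y[idx], self.subject_ids[idx], self.trial_ids[idx]
        )

    def subjects(self) -> set[str]:
        return set(self.subject_ids.tolist())

    @staticmethod
    def concat(parts: list["VolumeDataset"]) -> "VolumeDataset":
        return VolumeDataset(
            np.concatenate([p.X for p in parts]),
            np.concatenate([p.y for p in parts]),
            np.concatenate([p.subject_ids for p in parts]),
            np.concatenate([p.trial_ids for p in parts]),
        )


def stack_volumes(volumes: list[InputVolume]) -> VolumeDataset:
    """Stack InputVolumes into a dataset; adds the trailing channel axis.
    3d volumes keep their (H, W, D) shape; 2d volumes drop the singleton
    window axis so inputs are (H, W)."""
    arrs, ys, sids, tids = [], [], [], []
    for v in volumes:
        a = v.values
        if a.shape[-1] == 1:
            a = a[..., 0]
        arrs.append(a[..., None])
        ys.append(1 if v.label == "patient" else 0)
        sids.append(v.subject_id)
        tids.append(v.trial_id)
    return VolumeDataset(
        np.stack(arrs).astype(np.float32),
        np.array(ys, dtype=np.int8),
        np.array(sids, dtype=object),
        np.array(tids, dtype=np.int64),
    )


def build_model(arch: ArchConfig, seed: int = 0) -> nn.Sequential:
    """Instantiate the classifier with Kaiming-initialized weights.

    Raises a ValueError when the input shape cannot survive the pooling
    depth (a spatial extent not divisible by its pool kernel, or zero).
    """
    rng = np.random.default_rng(seed)
    ndim = 3 if arch.mode == "3d" else 2
    layers: list[nn.Layer] = []
    shape = list(arch.input_shape)
    in_ch = 1
    for out_ch, pool in zip(arch.conv_channels, arch.pool_kernels):
        layers.append(nn.Conv(ndim, in_ch, out_ch, arch.kernel, rng=rng))
        layers.append(nn.BatchNorm(out_ch))
        layers.append(nn.ReLU())
        layers.append(nn.MaxPool(pool))
        for i, k in enumerate(pool):
            if shape[i] % k or shape[i] // k == 0:
                raise ValueError(
                    f"input shape {arch.input_shape} too small or not divisible "
                    f"for pooling depth (failing extent {shape[i]} / kernel {k})"
                )
            shape[i] //= k
        in_ch = out_ch
    layers.append(nn.Flatten())
    flat = int(np.prod(shape)) * in_ch
    layers.append(nn.Dense(flat, arch.fc_width, rng=rng))
    layers.append(nn.ReLU())
    layers.append(nn.Dense(arch.fc_width, arch.fc_width, rng=rng))
    layers.append(nn.ReLU())
    layers.append(nn.Dense(arch.fc_width, 1, rng=rng))
    return nn.Sequential(layers)


def head_start_index(model: nn.Sequential) -> int:
    """Index of the first fully connected layer (right after Flatten)."""
    for i, layer in enumerate(model.layers):
        if isinstance(layer, nn.Flatten):
            return i + 1
    raise ValueError("model has no Flatten layer")


def predict_logits(model: nn.Sequential, X: np.ndarray, batch_size: int = 64) -> np.ndarray:
    out = np.empty(X.shape[0], dtype=np.float64)
    for i in range(0, X.shape[0], batch_size):
        out[i : i + batch_size] = model.forward(X[i : i + batch_size]).ravel()
    return out


def predict_proba(model: nn.Sequential, X: np.ndarray, batch_size: int = 64) -> np.ndarray:
    return expit(predict_logits(model, X, batch_size))


def rank_auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUROC as the Mann-Whitney rank statistic (ties share rank)."""
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def evaluate(
    model: nn.Sequential,
    X: np.ndarray,
    y: np.ndarray,
    threshold: float = 0.5,
    batch_size: int = 64,
) -> Metrics:
    """Threshold metrics and AUROC of the sigmoid scores against labels."""
    y = np.asarray(y).astype(int)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    p = predict_proba(model, X, batch_size)
    pred = (p >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    total = tp + fp + tn + fn
    precision = tp / (tp + fp) if tp + fp else float("nan")
    recall = tp / (tp + fn) if tp + fn else float("nan")
    return Metrics(
        accuracy=(tp + tn) / total,
        precision=precision,
        recall=recall,
        auroc=rank_auroc(p, y),
        tp=tp, fp=fp, tn=tn, fn=fn,
    )


def lr_range_test(
    model: nn.Sequential,
    X: np.ndarray,
    y: np.ndarray,
    lr_min: float = 1e-8,
    lr_max: float = 1.0,
    n_candidates: int = 13,
    steps_per_candidate: int = 15,
    batch_size: int = 16,
    seed: int = 0,
    fallback_lr: float = 1e-3,
) -> float:
    """Exponential learning-rate sweep over [lr_min, lr_max].

    Each candidate rate is probed from the *same* initial weights on the
    same mini-batch sequence (restarting per candidate de-confounds the
    sweep from weight drift, which otherwise makes single-pass sweeps
    favor transiently large, unstable rates).  A candidate diverges when
    its loss exceeds 4x the common initial loss or becomes non-finite.
    Among the survivors the probe returns the *largest* rate whose tail
    loss is within 10% of the best tail loss: early training sits on a
    long loss plateau where many rates tie, and the largest statistically
    tied rate descends steepest per unit time.  Model weights are
    restored afterwards.  Falls back to ``fallback_lr`` with a warning
    when no candidate decreases the loss.
    """
    if X.shape[0] < 1:
        raise ValueError("need at least one batch of data")
    state = model.state_dict()
    rng = np.random.default_rng(seed)
    order = rng.permutation(X.shape[0])
    batches = [
        order[(i * batch_size) % X.shape[0] :][:batch_size]
        for i in range(steps_per_candidate)
    ]
    batches = [b if b.size else order[:batch_size] for b in batches]

    lrs = np.geomspace(lr_min, lr_max, n_candidates)
    tail_losses = np.full(n_candidates, np.inf)
    first_loss = None
    for c, lr in enumerate(lrs):
        model.load_state_dict(state)
        opt = nn.Adam(model.params(), lr=lr)
        losses = []
        diverged = False
        for sel in batches:
            logits = model.forward(X[sel], train=True)
            loss, dz = nn.bce_with_logits(logits, y[sel])
            if first_loss is None:
                first_loss = loss
            if not np.isfinite(loss) or loss > 4.0 * first_loss:
                diverged = True
                break
            losses.append(loss)
            model.backward(dz)
            opt.step()
        if not diverged and losses:
            tail_losses[c] = np.mean(losses[-max(1, len(losses) // 3) :])
    model.load_state_dict(state)

    finite = np.isfinite(tail_losses)
    if not finite.any() or tail_losses[finite].min() >= first_loss:
        warnings.warn(
            "learning-rate range test: loss never decreased; "
            f"falling back to lr={fallback_lr}"
        )
        return fallback_lr
    best = tail_losses[finite].min()
    ok = finite & (tail_losses <= 1.1 * best)
    chosen = float(lrs[np.flatnonzero(ok)[-1]])
    return float(np.clip(chosen, lr_min, lr_max))


@dataclass
class TrainLog:
    """What happened during one training stage."""

    lr: float
    epochs_run: int
    best_val_accuracy: float
    val_accuracy_history: list[float] = field(default_factory=list)
    train_subjects: list[str] = field(default_factory=list)
    n_train: int = 0
    n_val: int = 0


def _undersample(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Indices balancing the two classes 1:1 (uniform, without replacement)."""
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    n = min(pos.size, neg.size)
    keep = np.concatenate(
        [rng.choice(pos, n, replace=False), rng.choice(neg, n, replace=False)]
    )
    return np.sort(keep)


def _epoch_pass(model, opt, X, y, batch_size, rng):
    order = rng.permutation(X.shape[0])
    total = 0.0
    for i in range(0, order.size, batch_size):
        sel = order[i : i + batch_size]
        logits = model.forward(X[sel], train=True)
        loss, dz = nn.bce_with_logits(logits, y[sel])
        model.backward(dz)
        opt.step()
        total += loss * sel.size
    return total / order.size


def pretrain(
    model: nn.Sequential,
    dataset: VolumeDataset,
    held_out_subject_id: str,
    cfg: TrainConfig,
    exclude_subjects: tuple[str, ...] = (),
) -> tuple[nn.Sequential, TrainLog]:
    """Pretraining stage of the transfer protocol.

    All volumes of the held-out subject (and of any reserved subjects) are
    removed, classes are undersampled to 1:1, the remainder split 90/10
    into train/validation, and the model trained with early stopping on
    validation accuracy; the best-validation weights are restored.
    """
    if held_out_subject_id not in dataset.subjects():
        raise ValueError(f"held-out subject {held_out_subject_id!r} not in dataset")
    rng = np.random.default_rng(cfg.seed)
    banned = {held_out_subject_id, *exclude_subjects}
    keep = ~np.isin(dataset.subject_ids.astype(str), sorted(banned))
    ds = dataset.subset(np.flatnonzero(keep))
    if cfg.undersample:
        ds = ds.subset(_undersample(ds.y, rng))

    order = rng.permutation(len(ds))
    n_val = max(1, int(round(cfg.val_fraction * len(ds))))
    val = ds.subset(order[:n_val])
    train = ds.subset(order[n_val:])
    assert held_out_subject_id not in train.subjects() | val.subjects()

    lr = cfg.lr
    if lr is None:
        lr = lr_range_test(
            model, train.X, train.y, batch_size=cfg.batch_size, seed=cfg.seed
        )
    opt = nn.Adam(model.params(), lr=lr, weight_decay=cfg.weight_decay)

    best_acc = -np.inf
    best_state = model.state_dict()
    history = []
    since_best = 0
    epochs_run = 0
    for epoch in range(cfg.max_epochs):
        _epoch_pass(model, opt, train.X, train.y, cfg.batch_size, rng)
        acc = evaluate(model, val.X, val.y).accuracy
        history.append(acc)
        epochs_run = epoch + 1
        if acc > best_acc:
            best_acc = acc
            best_state = model.state_dict()
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
    model.load_state_dict(best_state)
    log = TrainLog(
        lr=lr,
        epochs_run=epochs_run,
        best_val_accuracy=float(best_acc),
        val_accuracy_history=history,
        train_subjects=sorted(train.subjects() | val.subjects()),
        n_train=len(train),
        n_val=len(val),
    )
    return model, log


def fine_tune(
    model: nn.Sequential,
    sp_volumes: VolumeDataset,
    reserve_control_volumes: VolumeDataset,
    cfg: TrainConfig,
    pretrain_subjects: tuple[str, ...] = (),
) -> tuple[nn.Sequential, VolumeDataset, TrainLog]:
    """Fine-tuning/evaluation stage for one specific patient.

    Convolutional blocks are frozen (their outputs are computed once in
    evaluation mode and cached), only the fully connected head is trained,
    with learning rate and weight decay at 1/10 of the pretraining values.
    Returns the model, the held-out 20% evaluation split, and a log.
    """
    overlap = reserve_control_volumes.subjects() & set(pretrain_subjects)
    if overlap:
        raise ValueError(
            f"reserve controls {sorted(overlap)} were used during pretraining"
        )
    if cfg.lr is None:
        raise ValueError("fine-tuning needs the pretraining lr (cfg.lr)")
    rng = np.random.default_rng(cfg.seed + 1)
    ds = VolumeDataset.concat([sp_volumes, reserve_control_volumes])
    order = rng.permutation(len(ds))
    n_eval = max(1, int(round(cfg.eval_fraction * len(ds))))
    eval_ds = ds.subset(order[:n_eval])
    train_ds = ds.subset(order[n_eval:])

    split = head_start_index(model)
    feats = _cached_features(model, train_ds.X, split, cfg.batch_size)
    head = nn.Sequential(model.layers[split:])
    opt = nn.Adam(
        head.params(), lr=cfg.lr / 10.0, weight_decay=cfg.weight_decay / 10.0
    )
    best_loss = np.inf
    since_best = 0
    epochs_run = 0
    for epoch in range(cfg.max_epochs):
        loss = _epoch_pass(head, opt, feats, train_ds.y, cfg.batch_size, rng)
        epochs_run = epoch + 1
        if loss < best_loss - 1e-6:
            best_loss = loss
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
    log = TrainLog(
        lr=cfg.lr / 10.0,
        epochs_run=epochs_run,
        best_val_accuracy=float("nan"),
        train_subjects=sorted(train_ds.subjects()),
        n_train=len(train_ds),
        n_val=len(eval_ds),
    )
    return model, eval_ds, log


def _cached_features(model, X, split, batch_size):
    feature_net = nn.Sequential(model.layers[:split])
    out = []
    for i in range(0, X.shape[0], batch_size):
        out.append(feature_net.forward(X[i : i + batch_size]))
    return np.concatenate(out)


def save_checkpoint(model: nn.Sequential, path_prefix: str, meta: dict) -> None:
    """Weights as .npz plus a JSON sidecar with config/seed/metrics."""
    np.savez(path_prefix + ".npz", **model.state_dict())
    with open(path_prefix + ".json", "w") as fh:
        json.dump(meta, fh, indent=2, default=str)


def load_checkpoint(model: nn.Sequential, path_prefix: str) -> dict:
    state = dict(np.load(path_prefix + ".npz"))
    model.load_state_dict(state)
    with open(path_prefix + ".json") as fh:
        return json.load(fh)
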