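"""Dataset splitting, class-imbalance undersampling and the training loop.

Training minimizes per-position categorical cross-entropy between the
softmax outputs and the label vectors, averaged over non-masked positions
(positions whose input code is the padding code 0 are excluded by
default), with the Adam optimizer. All shuffling, initialization and
dropout derive from a single master seed so single-threaded runs are
bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .encoding import EncodedSequence, LabelSequence, WindowSet, one_hot_encode
from .errors import (ConfigError, InvalidInputError, StratificationError,
                     TrainingFailureError)
from .tcn import DTYPE, TCN, softmax

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    learning_rate: float = 0.0005
    batch_size: int = 256
    epochs: int = 100
    seed: int = 0
    split_fraction: float = 0.9
    rus_enabled: bool = True
    rus_ratio: float = 1.0       # all-normal : mutation-containing after RUS
    mask_padding: bool = True
    val_fraction: float = 0.1    # carved from train, reporting only

    def validate(self) -> "TrainConfig":
        if not 0.0 < self.split_fraction < 1.0:
            raise ConfigError("split_fraction must be in (0,1)")
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 0:
            raise ConfigError("learning_rate > 0, batch_size >= 1, epochs >= 0 required")
        if not 0.0 <= self.val_fraction < 1.0:
            raise ConfigError("val_fraction must be in [0,1)")
        return self


def _has_mutation(item) -> bool:
    return bool((item[1] != 0).any())


def train_test_split(windows: WindowSet, cfg: TrainConfig):
    """Seeded 90:10 (by default) partition, stratified by whether a window
    contains any nonzero label. Per-stratum train counts are
    round(split_fraction * stratum size)."""
    cfg.validate()
    if len(windows) < 10:
        raise StratificationError(
            f"need at least 10 windows to split, got {len(windows)}"
        )
    rng = np.random.default_rng(cfg.seed)
    flags = np.array([_has_mutation(it) for it in windows.items])
    train = WindowSet(windows.window_len, windows.overlap)
    test = WindowSet(windows.window_len, windows.overlap)
    for stratum in (False, True):
        idx = np.flatnonzero(flags == stratum)
        if idx.size == 0:
            continue
        perm = rng.permutation(idx)
        n_train = int(round(cfg.split_fraction * idx.size))
        for j in perm[:n_train]:
            train.items.append(windows.items[j])
        for j in perm[n_train:]:
            test.items.append(windows.items[j])
    return train, test


def random_under_sample(train: WindowSet, cfg: TrainConfig) -> WindowSet:
    """Balance the train set: keep every mutation-containing window, and
    randomly keep at most rus_ratio x that many all-normal windows."""
    rng = np.random.default_rng(cfg.seed + 1)
    mutated = [it for it in train.items if _has_mutation(it)]
    normal = [it for it in train.items if not _has_mutation(it)]
    cap = int(cfg.rus_ratio * len(mutated))
    if len(normal) > cap:
        keep = rng.choice(len(normal), size=cap, replace=False)
        normal = [normal[i] for i in sorted(keep)]
    out = WindowSet(train.window_len, train.overlap)
    out.items = mutated + normal
    return out


class Adam:
    """Adam with bias correction, one slot pair per parameter array."""

    def __init__(self, params_and_grads, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params_and_grads]
        self.v = [np.zeros_like(p) for p, _ in params_and_grads]
        self.t = 0

    def step(self, params_and_grads):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for (p, g), m, v in zip(params_and_grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _assemble(items, in_dim):
    """Stack windows into one-hot X (B, in_dim, W), labels y and pad mask."""
    codes = np.stack([it[0] for it in items])
    y = np.stack([it[1] for it in items])
    B, W = codes.shape
    X = np.zeros((B, in_dim, W), dtype=DTYPE)
    b_idx = np.repeat(np.arange(B), W)
    X[b_idx, codes.ravel(), np.tile(np.arange(W), B)] = 1.0
    return X, y, codes != 0


def _batch_loss_and_grad(model: TCN, X, y, mask, rng):
    """Masked softmax cross-entropy; returns (loss, dlogits)."""
    logits = model.forward(X, training=True, rng=rng)
    p = softmax(logits, axis=1)
    B, _, W = logits.shape
    w = mask.astype(DTYPE)
    denom = max(w.sum(), 1.0)
    b_idx = np.repeat(np.arange(B), W)
    t_idx = np.tile(np.arange(W), B)
    picked = p[b_idx, y.ravel(), t_idx].reshape(B, W)
    loss = -(np.log(np.maximum(picked, 1e-12)) * w).sum() / denom
    dlogits = p.copy()
    dlogits[b_idx, y.ravel(), t_idx] -= 1.0
    dlogits *= (w / denom)[:, None, :]
    return float(loss), dlogits


def train_model(model: TCN, train: WindowSet, cfg: TrainConfig,
                start_epoch: int = 0, checkpoint_every: int = 0,
                checkpoint_dir=None):
    """Adam training loop over shuffled mini-batches.

    Returns (model, history) where history has one dict per epoch with the
    mean training loss and, when a validation fraction is configured, the
    macro-F1 over supported mutation classes on the held-out slice.
    ``start_epoch`` offsets the epoch numbering for resumed runs;
    ``checkpoint_every`` > 0 saves the model every that many epochs.
    """
    cfg.validate()
    if len(train) == 0:
        raise InvalidInputError("empty training set")
    rng = np.random.default_rng(cfg.seed + 2)
    items = list(train.items)
    n_val = int(cfg.val_fraction * len(items))
    if n_val:
        perm = rng.permutation(len(items))
        val_items = [items[i] for i in perm[:n_val]]
        items = [items[i] for i in perm[n_val:]]
    else:
        val_items = []
    in_dim = model.cfg.in_dim
    opt = Adam(model.params_and_grads(), cfg.learning_rate)
    history = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(items))
        losses = []
        for start in range(0, len(items), cfg.batch_size):
            batch = [items[i] for i in order[start : start + cfg.batch_size]]
            X, y, mask = _assemble(batch, in_dim)
            if not cfg.mask_padding:
                mask = np.ones_like(mask)
            model.zero_grads()
            loss, dlogits = _batch_loss_and_grad(model, X, y, mask, rng)
            if not np.isfinite(loss):
                raise TrainingFailureError(
                    f"non-finite loss at epoch {epoch}", epoch=epoch)
            model.backward(dlogits)
            opt.step(model.params_and_grads())
            losses.append(loss)
        rec = {"epoch": start_epoch + epoch, "loss": float(np.mean(losses))}
        if val_items:
            rec["val_macro_f1"] = _quick_macro_f1(model, val_items, in_dim,
                                                  cfg.mask_padding)
        history.append(rec)
        logger.info("epoch %d: %s", start_epoch + epoch, rec)
        if checkpoint_every and checkpoint_dir is not None \
                and (epoch + 1) % checkpoint_every == 0:
            model.save(checkpoint_dir)
    return model, history


def _quick_macro_f1(model, items, in_dim, mask_padding, chunk=256):
    from .evaluation import confusion_matrix_counts, precision_recall_f1
    cm = np.zeros((4, 4), dtype=np.int64)
    for start in range(0, len(items), chunk):
        batch = items[start : start + chunk]
        X, y, mask = _assemble(batch, in_dim)
        pred = model.predict_proba(X).argmax(axis=1)
        keep = mask if mask_padding else np.ones_like(mask)
        np.add.at(cm, (y[keep], pred[keep]), 1)
    f1s = [precision_recall_f1(cm, c)[2] for c in (1, 2, 3) if cm[c].sum() > 0]
    return float(np.mean(f1s)) if f1s else 0.0


def predict_labels(model: TCN, sequences: list[EncodedSequence]):
    """Run the model on full encoded sequences.

    Returns, per sequence, the n x 4 per-position probability matrix and
    the argmax LabelSequence (ties break toward the lower class index,
    which is what argmax does).
    """
    out = []
    for seq in sequences:
        if seq.codes.size and seq.codes.max() >= model.cfg.in_dim:
            raise InvalidInputError(
                f"sequence {seq.source_id} encoded with m >= model in_dim "
                f"{model.cfg.in_dim}; wrong k-mer table?"
            )
        X = one_hot_encode(seq, model.cfg.in_dim - 1)[None]
        probs = model.predict_proba(X)[0].T           # n x 4
        labels = probs.argmax(axis=1)
        out.append((probs, LabelSequence(source_id=seq.source_id,
                                         labels=labels.astype(np.int64))))
    return out
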