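"""Training protocol for the fusion family.

The protocol mirrors a standard volumetric-segmentation recipe: soft-Dice
loss, Adam, a one-cycle learning-rate schedule, periodic validation and
early stopping on the average validation Dice loss, with the weights of the
best validation step retained.  Full-scale defaults (16,000 batches of two
volumes, max learning rate 1e-3, validation every 20 batches, patience of
500 batches) are kept in :class:`TrainProtocol`; the ``desk`` preset scales
the schedule down for CPU-sized experiments on 2D slices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np

from .nn import autodiff as ad
from .nn.optim import Adam, one_cycle_lr

__all__ = [
    "TrainProtocol",
    "TrainRecord",
    "dice_loss",
    "fit",
    "train_model",
    "SliceSampler",
    "validation_loss",
    "evaluate_pairs",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class TrainProtocol:
    """Hyperparameters of the training loop."""

    total_batches: int = 16_000
    batch_size: int = 2
    max_lr: float = 1e-3
    val_every: int = 20
    patience_batches: int = 500
    loss: str = "dice"
    optimizer: str = "adam"
    scheduler: str = "one_cycle"
    warmup_frac: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.patience_batches < self.val_every:
            raise ValueError("patience_batches must be >= val_every")
        if self.total_batches < self.val_every:
            raise ValueError("total_batches must be >= val_every")

    @classmethod
    def desk(cls, seed: int = 0, total_batches: int = 600,
             max_lr: float = 3e-3) -> "TrainProtocol":
        """CPU-sized schedule for 2D desk-scale experiments.

        The warm-up is shortened to 10% of the horizon so that early
        stopping (patience 200 batches) cannot fire while the learning rate
        is still ramping up.
        """
        return cls(total_batches=total_batches, batch_size=2, max_lr=max_lr,
                   val_every=20, patience_batches=200, warmup_frac=0.1,
                   seed=seed)


@dataclass
class TrainRecord:
    """What happened during one training run."""

    history: list[tuple[int, float]] = field(default_factory=list)
    best_batch: int = 0
    best_val_loss: float = float("inf")
    stopped_early: bool = False
    final_weights_ref: Optional[str] = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, s: str) -> "TrainRecord":
        d = json.loads(s)
        d["history"] = [tuple(h) for h in d["history"]]
        return cls(**d)


# ---------------------------------------------------------------------------
# loss


def _soft_dice_loss_graph(logits: ad.Tensor, target: np.ndarray,
                          eps: float = 1e-5) -> ad.Tensor:
    """Soft-Dice training loss as an autodiff graph node.

    ``logits``: (N, C, *spatial) class scores; ``target``: (N, *spatial)
    binary foreground.  The loss is one minus the mean soft Dice over both
    class channels (softmax probabilities, overlap statistics pooled over
    the batch).  Including the background channel keeps gradients alive
    when a batch is foreground-poor: a foreground-only objective has a
    zero-gradient attractor at the all-background prediction.
    """
    prob = ad.channel_softmax(logits)
    t = np.asarray(target, dtype=logits.value.dtype)
    dice_terms = []
    for ch, t_ch in ((0, 1.0 - t), (1, t)):
        p = ad.take_channel(prob, ch)
        inter = ad.sum_all(ad.scale(p, t_ch))
        denom = ad.sum_all(p) + float(t_ch.sum()) + eps
        dice_terms.append((2.0 * inter + eps) / denom)
    return 1.0 - (dice_terms[0] + dice_terms[1]) * 0.5


def dice_loss(prob_foreground: np.ndarray, target: np.ndarray,
              eps: float = 1e-5) -> float:
    """1 minus the soft Dice of a foreground-probability map vs a binary
    target, with smoothing ``eps`` in numerator and denominator; range
    [0, 1] up to eps-order effects."""
    p = np.asarray(prob_foreground, dtype=float)
    t = np.asarray(target, dtype=float)
    if p.shape != t.shape:
        raise ValueError("probability map and target shapes disagree")
    inter = float((p * t).sum())
    return 1.0 - (2.0 * inter + eps) / (p.sum() + t.sum() + eps)


# ---------------------------------------------------------------------------
# data sampling over modality pairs


class SliceSampler:
    """Seeded sampler of 2D training slices from a set of modality pairs.

    Uses every axial slice containing foreground, plus an equal number of
    randomly chosen background slices (when available), so the network sees
    both kinds.  Volumes must already be preprocessed.
    """

    def __init__(self, pairs: Sequence, seed: int = 0):
        fg, bg = [], []
        for pair in pairs:
            for z in range(pair.label.shape[2]):
                (fg if pair.label[:, :, z].any() else bg).append((pair, z))
        rng = np.random.default_rng(seed)
        if bg:
            take = min(len(bg), max(1, len(fg)))
            idx = rng.choice(len(bg), size=take, replace=False)
            bg = [bg[i] for i in idx]
        self._slices = fg + bg
        if not self._slices:
            raise ValueError("no slices to sample from")
        self._rng = rng

    def batch(self, size: int):
        idx = self._rng.integers(0, len(self._slices), size=size)
        xr = np.stack([self._slices[i][0].image_ref[:, :, self._slices[i][1]]
                       for i in idx])
        xs = np.stack([self._slices[i][0].image_sec[:, :, self._slices[i][1]]
                       for i in idx])
        t = np.stack([self._slices[i][0].label[:, :, self._slices[i][1]]
                      for i in idx])
        return xr, xs, t


def validation_loss(model, pairs: Sequence, max_slices: int = 64) -> float:
    """Average soft-Dice loss over a fixed set of validation slices
    (all foreground-bearing slices, capped deterministically)."""
    slices = [(p, z) for p in pairs for z in range(p.label.shape[2])
              if p.label[:, :, z].any()]
    if not slices:
        raise ValueError("validation pairs contain no foreground slices")
    slices = slices[:max_slices]
    xr = np.stack([p.image_ref[:, :, z] for p, z in slices])
    xs = np.stack([p.image_sec[:, :, z] for p, z in slices])
    t = np.stack([p.label[:, :, z] for p, z in slices]).astype(float)
    prob = _softmax_np(model.logits(xr, xs))[:, 1]
    eps = 1e-5
    inter = (prob * t).sum(axis=(1, 2))
    losses = 1.0 - (2.0 * inter + eps) / (prob.sum(axis=(1, 2))
                                          + t.sum(axis=(1, 2)) + eps)
    return float(losses.mean())


def _softmax_np(x: np.ndarray) -> np.ndarray:
    m = x.max(axis=1, keepdims=True)
    e = np.exp(x - m)
    return e / e.sum(axis=1, keepdims=True)


def evaluate_pairs(model, pairs: Sequence) -> list[float]:
    """Volume-level Dice of the model's predicted mask on each pair."""
    from .fusion import predict_mask
    from .stats import dice_score

    return [dice_score(predict_mask(model, p.image_ref, p.image_sec),
                       p.label) for p in pairs]


# ---------------------------------------------------------------------------
# the loop


def fit(model, sample_batch: Callable[[int], tuple],
        protocol: TrainProtocol,
        validate_fn: Callable[[object], float],
        log_fn: Callable[[str], None] | None = None) -> TrainRecord:
    """Run the training loop on any model exposing ``loss_and_grads``,
    ``params``, ``get_params`` and ``set_params``.

    Validation runs every ``val_every`` batches; the best (lowest, earliest
    on ties) validation loss is tracked and training stops early once
    ``batch - best_batch >= patience_batches``.  The model is left holding
    the best-validation weights.
    """
    record = TrainRecord()
    opt = Adam(model.params, lr=protocol.max_lr)
    best_params = model.get_params()
    for batch_idx in range(1, protocol.total_batches + 1):
        opt.lr = one_cycle_lr(batch_idx - 1, protocol.total_batches,
                              protocol.max_lr,
                              warmup_frac=protocol.warmup_frac)
        xr, xs, t = sample_batch(protocol.batch_size)
        loss, grads = model.loss_and_grads(xr, xs, t)
        if not np.isfinite(loss):
            raise RuntimeError(
                f"non-finite training loss {loss!r} at batch {batch_idx}")
        opt.step(grads)
        if batch_idx % protocol.val_every == 0:
            val = float(validate_fn(model))
            if not np.isfinite(val):
                raise RuntimeError(
                    f"non-finite validation loss at batch {batch_idx}")
            record.history.append((batch_idx, val))
            if val < record.best_val_loss:
                record.best_val_loss = val
                record.best_batch = batch_idx
                best_params = model.get_params()
            if log_fn is not None:
                log_fn(f"batch={batch_idx} lr={opt.lr:.2e} "
                       f"train_loss={loss:.4f} val_loss={val:.4f} "
                       f"best={record.best_val_loss:.4f}@{record.best_batch}")
            if batch_idx - record.best_batch >= protocol.patience_batches:
                record.stopped_early = True
                break
    model.set_params(best_params)
    return record


def train_model(config, protocol: TrainProtocol, train_pairs: Sequence,
                val_pairs: Sequence, seed: int = 0,
                log_fn: Callable[[str], None] | None = None):
    """Build and train one family member on preprocessed modality pairs.

    Returns ``(model, TrainRecord)``; the model holds the weights of the
    validation step with the lowest validation loss.
    """
    from .fusion import build_model

    if not train_pairs or not val_pairs:
        raise ValueError("training and validation sets must be non-empty")
    model = build_model(config, seed=seed)
    sampler = SliceSampler(train_pairs, seed=seed + 1)
    record = fit(model, sampler.batch, protocol,
                 lambda m: validation_loss(m, val_pairs), log_fn=log_fn)
    return model, record


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(path, model, record: TrainRecord | None = None) -> None:
    """Weights + embedded config (+ train record) in one .npz archive."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"config": model.config.to_dict()}
    if record is not None:
        meta["record"] = json.loads(record.to_json())
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **model.params)


def load_checkpoint(path):
    """Rebuild a model (and its record, if stored) from an archive."""
    from .fusion import FusionConfig, build_model

    with np.load(Path(path)) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        params = {k: z[k] for k in z.files if k != "__meta__"}
    model = build_model(FusionConfig.from_dict(meta["config"]))
    model.set_params(params)
    record = None
    if "record" in meta:
        record = TrainRecord.from_json(json.dumps(meta["record"]))
    return model, record
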