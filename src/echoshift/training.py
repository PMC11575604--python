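"""Training: mean-absolute-error loss, Adam, checkpointing, reproducibility.

The loss is the plain mean absolute error between the confidence vector and
the 0/1 label vector, averaged over every point of the batch; labels are
extremely sparse (tens of ones against thousands of zeros), and the plain
unweighted mean is the default.  An optional positive weighting exists for
small-budget training but is off by default.

Training runs on random fixed-width crops of the full-width samples: the
network is fully convolutional along the frequency axis, so weights learned
on crops apply unchanged at full width.  All randomness (shuffling, crop
offsets) derives from the config seed, and NumPy arithmetic is
deterministic, so two runs with the same data, config and seed produce
bit-identical parameter trajectories.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .dataset import SpectraDataset
from .network import DTYPE, ModelState, NetworkConfig, build_model, forward

__all__ = [
    "TrainConfig",
    "mae_loss",
    "train",
    "save_checkpoint",
    "load_checkpoint",
    "Adam",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings; the seed fully determines the run."""

    epochs: int = 20
    batch_size: int = 16
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    seed: int = 0
    val_interval: int = 1  # epochs between validation passes
    plateau_patience: int = 3  # validations without improvement before lr ×0.5
    early_stop_patience: int = 8  # validations without improvement before stop
    crop_width: int | None = 1024  # None → train at full width
    pos_weight: float = 1.0  # >1 upweights label-1 points (off by default)
    pos_weight_final: float | None = None  # geometric anneal target over epochs
    lr_decay: float | None = None  # per-epoch multiplicative lr factor
    average_tail: float = 0.0  # Polyak-average weights over this final
    # fraction of epochs (0 → off); damps the end-of-run dither of the
    # sign-based L1 gradient
    device: str = "cpu"

    def __post_init__(self) -> None:
        if self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("epochs and batch_size must be positive")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is implemented")
        if self.device != "cpu":
            raise ValueError("only cpu execution is supported")


def mae_loss(y: np.ndarray, y_label: np.ndarray, pos_weight: float = 1.0):
    """Mean |y − ŷ| over all points; returns (loss, dL/dy).

    With pos_weight w ≠ 1, points whose label is 1 contribute w·|y − ŷ| and
    the mean is taken over the weighted total.
    """
    y = np.asarray(y, dtype=DTYPE)
    t = np.asarray(y_label, dtype=DTYPE)
    if y.shape != t.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {t.shape}")
    diff = y - t
    if pos_weight == 1.0:
        loss = float(np.abs(diff).mean())
        grad = np.sign(diff, dtype=DTYPE) / diff.size
    else:
        w = np.where(t > 0.5, DTYPE(pos_weight), DTYPE(1.0))
        total = w.sum()
        loss = float((w * np.abs(diff)).sum() / total)
        grad = (w * np.sign(diff)).astype(DTYPE) / DTYPE(total)
    return loss, grad.astype(DTYPE)


class Adam:
    """Standard Adam on the model's parameter list."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1**self.t
        bias2 = 1 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= (self.lr * (m / bias1)
                        / (np.sqrt(v / bias2) + self.eps)).astype(DTYPE)

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0


def _crop_batch(inputs, labels, idx, crop_width, rng):
    """Gather a batch, optionally taking a random crop per sample."""
    x = inputs[idx]
    t = labels[idx]
    full_w = x.shape[-1]
    if crop_width is None or crop_width >= full_w:
        return x, t
    xs = np.empty((len(idx), x.shape[1], crop_width), dtype=DTYPE)
    ts = np.empty((len(idx), crop_width), dtype=DTYPE)
    for b in range(len(idx)):
        off = int(rng.integers(0, full_w - crop_width + 1))
        xs[b] = x[b, :, off : off + crop_width]
        ts[b] = t[b, off : off + crop_width]
    return xs, ts


def _validate(model, val_inputs, val_labels, batch_size, tol_points=3):
    """Val MAE plus pooled precision/recall/F1 at threshold 0.5."""
    from .evaluation import detection_metrics, match_peaks
    from .inference import threshold_peaks

    n = len(val_inputs)
    losses = []
    tp = fp = fn = 0
    for start in range(0, n, batch_size):
        x = val_inputs[start : start + batch_size]
        t = val_labels[start : start + batch_size]
        y = forward(model, x, train=False)
        loss, _ = mae_loss(y, t)
        losses.append(loss * y.size)
        for b in range(len(x)):
            peaks = threshold_peaks(y[b])
            m = match_peaks(t[b], peaks, tol_points=tol_points)
            tp, fp, fn = tp + m.tp, fp + m.fp, fn + m.fn
    metrics = detection_metrics(tp=tp, fp=fp, fn=fn)
    mae = float(np.sum(losses) / (n * val_inputs.shape[-1]))
    return mae, metrics


def _snapshot(model: ModelState) -> list[np.ndarray]:
    return [p.value.copy() for p in model.params()]


def _restore(model: ModelState, values: list[np.ndarray]) -> None:
    for p, v in zip(model.params(), values):
        p.value = v.copy()


def train(
    model: ModelState,
    dataset: SpectraDataset,
    cfg: TrainConfig,
    val_dataset: SpectraDataset | None = None,
    log_path=None,
):
    """Optimize the model in place; returns (model at best validation, log).

    The log is a list of per-epoch dicts (train MAE, and on validation
    epochs the val MAE and pooled precision/recall/F1 at threshold 0.5).
    The returned model carries the parameters of the best validation epoch
    (best F1, ties broken by val MAE); with no validation set, the final
    parameters are kept.  NaN loss aborts with a diagnostic.
    """
    if len(dataset) == 0:
        raise ValueError("training dataset is empty")
    inputs = np.ascontiguousarray(dataset.inputs, dtype=DTYPE)
    labels = dataset.labels.astype(DTYPE)
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.params(), lr=cfg.learning_rate)
    log: list[dict] = []
    best = (-np.inf, np.inf)  # (f1, -mae) maximized
    best_params = _snapshot(model)
    stale = 0

    n = len(inputs)
    plateau_factor = 1.0
    avg_params: list[np.ndarray] | None = None
    avg_count = 0
    avg_start = (int(np.ceil(cfg.epochs * (1 - cfg.average_tail)))
                 if cfg.average_tail > 0 else cfg.epochs)
    for epoch in range(cfg.epochs):
        if cfg.lr_decay is not None:
            opt.lr = cfg.learning_rate * cfg.lr_decay**epoch * plateau_factor
        pos_weight = cfg.pos_weight
        if cfg.pos_weight_final is not None and cfg.epochs > 1:
            # geometric anneal: high early (lift-off), low late (precision)
            pos_weight = cfg.pos_weight * (
                cfg.pos_weight_final / cfg.pos_weight
            ) ** (epoch / (cfg.epochs - 1))
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_points = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            x, t = _crop_batch(inputs, labels, idx, cfg.crop_width, rng)
            y = forward(model, x, train=True)
            loss, dy = mae_loss(y, t, pos_weight=pos_weight)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged: loss={loss} at epoch {epoch}, "
                    f"step {model.step} (lr={opt.lr:g})"
                )
            opt.zero_grad()
            model.net.backward(dy[:, None, None, :])
            opt.step()
            model.step += 1
            epoch_loss += loss * y.size
            n_points += y.size
        entry = {"epoch": epoch, "train_mae": epoch_loss / n_points, "lr": opt.lr}

        if epoch >= avg_start:
            if avg_params is None:
                avg_params = [p.value.astype(np.float64) for p in model.params()]
            else:
                for acc, p in zip(avg_params, model.params()):
                    acc += p.value
            avg_count += 1

        if val_dataset is not None and len(val_dataset) and (
            (epoch + 1) % cfg.val_interval == 0 or epoch == cfg.epochs - 1
        ):
            val_mae, metrics = _validate(
                model, val_dataset.inputs, val_dataset.labels.astype(DTYPE),
                cfg.batch_size,
            )
            entry.update(
                val_mae=val_mae,
                val_precision=metrics.precision,
                val_recall=metrics.recall,
                val_f1=metrics.f1,
            )
            f1 = metrics.f1 if np.isfinite(metrics.f1) else 0.0
            score = (f1, -val_mae)
            if score > best:
                best = score
                best_params = _snapshot(model)
                stale = 0
            else:
                stale += 1
                if stale % cfg.plateau_patience == 0:
                    plateau_factor *= 0.5
                    opt.lr *= 0.5
                if stale >= cfg.early_stop_patience:
                    log.append(entry)
                    break
        log.append(entry)

    if avg_params is not None and avg_count > 0:
        for p, acc in zip(model.params(), avg_params):
            p.value = (acc / avg_count).astype(p.value.dtype)
    elif val_dataset is not None and len(val_dataset):
        _restore(model, best_params)
    if log_path is not None:
        with open(str(log_path), "w") as f:
            for entry in log:
                f.write(json.dumps(entry) + "\n")
    return model, log


# ----------------------------------------------------------------------------
# Checkpoints
# ----------------------------------------------------------------------------

def save_checkpoint(model: ModelState, path) -> None:
    """Write config + parameters + batch-norm statistics to an .npz file."""
    arrays = {}
    for i, p in enumerate(model.params()):
        arrays[f"param_{i}"] = p.value
    for i, bn in enumerate(_batchnorms(model)):
        arrays[f"bn_{i}_mean"] = bn.running_mean
        arrays[f"bn_{i}_var"] = bn.running_var
    meta = {
        "config": model.config.to_dict(),
        "config_hash": model.config_hash,
        "seed": model.seed,
        "step": model.step,
    }
    np.savez(str(path), meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path) -> ModelState:
    with np.load(str(path)) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        cfg = NetworkConfig.from_dict(meta["config"])
        model = build_model(cfg, seed=meta["seed"])
        if model.config_hash != meta["config_hash"]:
            raise ValueError("checkpoint config hash mismatch")
        for i, p in enumerate(model.params()):
            p.value = data[f"param_{i}"].astype(DTYPE)
        for i, bn in enumerate(_batchnorms(model)):
            bn.running_mean = data[f"bn_{i}_mean"].astype(DTYPE)
            bn.running_var = data[f"bn_{i}_var"].astype(DTYPE)
        model.step = meta["step"]
    return model


def _batchnorms(model: ModelState):
    from .network import BatchNorm2d, Residual, Sequential

    out = []

    def walk(layer):
        if isinstance(layer, BatchNorm2d):
            out.append(layer)
        elif isinstance(layer, Sequential):
            for l in layer.layers:
                walk(l)
        elif isinstance(layer, Residual):
            walk(layer.body)

    walk(model.net)
    return out
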