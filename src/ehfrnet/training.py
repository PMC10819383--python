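"""Training recipe, top-1 evaluation and Grad-CAM introspection.

The published recipe: 256x256 inputs, batch 32, AdamW, learning rate warmed
up linearly from 1e-6 over the first 20k iterations to the cosine maximum
0.002, then annealed by a cosine schedule down to 0.0002.  The epoch/
iteration budget is a free parameter (the source recipe does not state it);
short seed-pinned runs at reduced resolution are used for desk-scale sanity
checks.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .network import EHFRNet, save_checkpoint
from .nn.autograd import Tensor, log_softmax
from .nn.optim import AdamW
from .synthetic import ImageFolder

__all__ = ["TrainConfig", "MetricLog", "lr_at_step", "train", "evaluate",
           "gradcam", "save_heatmap_overlay"]


@dataclass
class TrainConfig:
    batch_size: int = 32
    resolution: int = 256
    warmup_start_lr: float = 1e-6
    warmup_iterations: int = 20_000
    cosine_lr_max: float = 0.002
    cosine_lr_min: float = 0.0002
    total_iterations: int = 100_000
    weight_decay: float = 0.01
    label_smoothing: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if not (self.warmup_start_lr < self.cosine_lr_min < self.cosine_lr_max):
            raise ValueError(
                "require warmup_start_lr < cosine_lr_min < cosine_lr_max")
        if self.total_iterations and self.warmup_iterations >= self.total_iterations:
            raise ValueError("warmup_iterations must be below total_iterations")


@dataclass
class MetricLog:
    iterations: list[int] = field(default_factory=list)
    losses: list[float] = field(default_factory=list)
    lrs: list[float] = field(default_factory=list)
    epoch_accuracy: list[tuple[int, float]] = field(default_factory=list)

    def append(self, iteration: int, loss: float, lr: float) -> None:
        if self.iterations and iteration <= self.iterations[-1]:
            raise ValueError("iteration indices must be strictly increasing")
        self.iterations.append(iteration)
        self.losses.append(loss)
        self.lrs.append(lr)

    def to_csv(self) -> str:
        buf = io.StringIO()
        writer = csv.writer(buf, lineterminator="\n")
        writer.writerow(["iteration", "loss", "lr"])
        for row in zip(self.iterations, self.losses, self.lrs):
            writer.writerow(row)
        return buf.getvalue()


def lr_at_step(step: int, cfg: TrainConfig) -> float:
    """Linear warmup to the cosine maximum, then cosine anneal to the minimum.

    Continuous at the junction: both pieces equal ``cosine_lr_max`` at
    ``warmup_iterations``.
    """
    if step < 0 or step > cfg.total_iterations:
        raise ValueError(
            f"step {step} outside [0, {cfg.total_iterations}]")
    if step < cfg.warmup_iterations:
        frac = step / cfg.warmup_iterations
        return cfg.warmup_start_lr + frac * (cfg.cosine_lr_max - cfg.warmup_start_lr)
    span = cfg.total_iterations - cfg.warmup_iterations
    t = (step - cfg.warmup_iterations) / span if span else 1.0
    return cfg.cosine_lr_min + 0.5 * (cfg.cosine_lr_max - cfg.cosine_lr_min) * (
        1.0 + math.cos(math.pi * t))


def cross_entropy(logits: Tensor, labels: np.ndarray,
                  label_smoothing: float = 0.0) -> Tensor:
    B, K = logits.shape
    target = np.full((B, K), label_smoothing / K, dtype=logits.data.dtype)
    target[np.arange(B), labels] += 1.0 - label_smoothing
    return -(Tensor(target) * log_softmax(logits, axis=1)).sum() * (1.0 / B)


def train(model: EHFRNet, data: ImageFolder, cfg: TrainConfig,
          out_dir=None, val_data: ImageFolder | None = None,
          log_every: int = 1) -> MetricLog:
    """Minimize smoothed cross-entropy under the warmup+cosine schedule.

    Checkpoints (initial, per epoch, best-by-validation) are written when
    ``out_dir`` is given.  Fully reproducible for a fixed seed: the data
    loader order and all weight noise flow from ``cfg.seed``.
    """
    if data.num_classes != model.cfg.num_classes:
        raise ValueError(
            f"model expects {model.cfg.num_classes} classes, "
            f"data has {data.num_classes}")
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        save_checkpoint(model, out / "initial.npz", iteration=0)
    log = MetricLog()
    if cfg.total_iterations == 0:
        return log
    model.train()
    optimizer = AdamW(model.parameters(), lr=cfg.warmup_start_lr,
                      weight_decay=cfg.weight_decay)
    data.rng = np.random.default_rng(cfg.seed)
    iters_per_epoch = max(1, math.ceil(len(data) / cfg.batch_size))
    best_acc = -1.0
    step = 0
    for x, y in data.epoch_batches(cfg.batch_size, cfg.total_iterations):
        lr = lr_at_step(step, cfg)
        optimizer.lr = lr
        logits = model(Tensor(x))
        loss = cross_entropy(logits, y, cfg.label_smoothing)
        loss_val = float(loss.data)
        if not np.isfinite(loss_val):
            raise RuntimeError(
                f"non-finite loss {loss_val} at iteration {step} (lr={lr:g})")
        optimizer.zero_grad()
        loss.backward()
        optimizer.step()
        step += 1
        if step % log_every == 0 or step == cfg.total_iterations:
            log.append(step, loss_val, lr)
        if step % iters_per_epoch == 0 or step == cfg.total_iterations:
            if val_data is not None:
                acc = evaluate(model, val_data)
                model.train()
                log.epoch_accuracy.append((step, acc))
                if out is not None and acc > best_acc:
                    best_acc = acc
                    save_checkpoint(model, out / "best.npz", iteration=step,
                                    extra={"val_top1": acc})
            if out is not None:
                save_checkpoint(model, out / "last.npz", iteration=step)
    if out is not None:
        (out / "metrics.csv").write_text(log.to_csv())
    return log


def evaluate(model: EHFRNet, data: ImageFolder,
             batch_size: int = 32) -> float:
    """Top-1 accuracy in percent; argmax ties resolve to the lowest index."""
    if len(data) == 0:
        raise ValueError("empty dataset")
    model.eval()
    correct = 0
    for x, y in data.batches(batch_size):
        logits = model(Tensor(x)).data
        correct += int((logits.argmax(axis=1) == y).sum())
    return 100.0 * correct / len(data)


# ---------------------------------------------------------------- Grad-CAM --

def _bilinear_resize(arr: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    im = Image.fromarray(arr.astype(np.float32), mode="F")
    return np.asarray(im.resize((size[1], size[0]), Image.BILINEAR))


def gradcam(model: EHFRNet, image: np.ndarray, target_class: int,
            layer_name: str = "group5") -> np.ndarray:
    """Class-gradient-weighted activation heatmap in [0, 1] at input size.

    ``image``: (3, H, W) or (1, 3, H, W), on the loader's [-1, 1] scale.
    """
    names = model.layer_names()
    if layer_name not in names:
        raise ValueError(
            f"unknown layer {layer_name!r}; available layers: {names}")
    x = np.asarray(image, dtype=np.float32)
    if x.ndim == 3:
        x = x[None]
    model.eval()
    capture: dict[str, Tensor] = {}
    logits = model(Tensor(x), capture=capture)
    onehot = np.zeros_like(logits.data)
    onehot[0, target_class] = 1.0
    (logits * Tensor(onehot)).sum().backward()
    act = capture[layer_name]
    weights = act.grad.mean(axis=(2, 3), keepdims=True)      # (1, C, 1, 1)
    cam = np.maximum((weights * act.data).sum(axis=1)[0], 0.0)
    cam = _bilinear_resize(cam, x.shape[-2:])
    peak = cam.max()
    return cam / peak if peak > 0 else cam


def save_heatmap_overlay(image: np.ndarray, cam: np.ndarray, path,
                         alpha: float = 0.5) -> None:
    """Blend a [0,1] heatmap (red channel) over the image and save as PNG."""
    x = np.asarray(image, dtype=np.float32)
    if x.ndim == 4:
        x = x[0]
    rgb = np.clip((x.transpose(1, 2, 0) + 1.0) / 2.0, 0, 1)
    heat = np.zeros_like(rgb)
    heat[:, :, 0] = cam
    heat[:, :, 2] = 1.0 - cam
    blended = (1 - alpha) * rgb + alpha * heat
    Image.fromarray((blended * 255).round().astype(np.uint8)).save(path)
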