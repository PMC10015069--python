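"""Training: Euclidean density loss + SGD with momentum and weight decay.

The loss is L(theta) = (1/2N) * sum_i || P(X_i; theta) - P_i^GT ||_2^2 over
a batch of N images, comparing predicted and ground-truth density maps
pixel-wise on the network's output grid.  The reference schedule is SGD
with batch size 2, learning rate 1e-7, momentum 0.95 and weight decay 5e-7
(sized for fine-tuning pretrained features; random-init desk-scale runs
need a larger learning rate, which is configurable).

Variable-size images cannot be stacked into a batch, so training draws
fixed-size random crops (ground truth is rebuilt from the points that fall
inside each crop, preserving count consistency); evaluation always runs on
the full image.
"""

from __future__ import annotations

import copy
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .annotations_io import AnnotatedImage, DatasetManifest, load_annotated, \
    PointAnnotation
from .density import DensityMap, assign_sigma, downsample_mass_preserving, \
    generate_density_map
from .evaluation import evaluate
from .model import ModelConfig, MosquitoCounter
from .nn import SGD

__all__ = ["TrainConfig", "TrainState", "density_loss",
           "density_loss_and_grad", "train"]


@dataclass
class TrainConfig:
    """Optimization hyper-parameters (defaults follow the reference
    schedule; see module docstring)."""

    learning_rate: float = 1e-7
    momentum: float = 0.95
    weight_decay: float = 5e-7
    batch_size: int = 2
    epochs: int = 100
    seed: int = 0
    crop_size: tuple[int, int] | None = (384, 384)
    eval_every: int = 1
    init: str = "he"  # weight init for non-pretrained runs

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.momentum < 0 or self.weight_decay < 0:
            raise ValueError("rates must be positive (momentum/decay >= 0)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class TrainState:
    """Trajectory of one training run."""

    seed: int
    loss_history: list[float] = field(default_factory=list)  # per-step
    epoch_loss: list[float] = field(default_factory=list)  # mean per epoch
    metrics: list[tuple[int, float, float]] = field(default_factory=list)
    best_mae: float = float("inf")
    best_epoch: int = -1
    best_weights: dict[str, np.ndarray] | None = None
    checkpoint_path: Path | None = None

    @property
    def epoch(self) -> int:
        return len(self.epoch_loss)


def _stack(maps) -> np.ndarray:
    """Density map(s) in any accepted form -> (N, H, W) float array.

    Accepts a single DensityMap or 2-D array (N=1), a pre-batched (N, H, W)
    or (N, 1, H, W) array, or a sequence of maps/2-D arrays.
    """
    if isinstance(maps, DensityMap):
        return maps.values[None]
    if isinstance(maps, np.ndarray):
        a = np.asarray(maps, dtype=np.float64)
        if a.ndim == 2:
            return a[None]
        if a.ndim == 3:
            return a
        if a.ndim == 4 and a.shape[1] == 1:
            return a[:, 0]
        raise ValueError(f"cannot interpret array of shape {a.shape} as maps")
    arrs = []
    for m in maps:
        a = m.values if isinstance(m, DensityMap) else np.asarray(m, dtype=np.float64)
        if a.ndim != 2:
            raise ValueError(f"each map must be 2-D, got shape {a.shape}")
        arrs.append(a)
    return np.stack(arrs)


def density_loss(pred, gt) -> float:
    """Half mean (over the batch) of the summed squared pixel differences."""
    p, g = _stack(pred), _stack(gt)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs gt {g.shape}")
    n = p.shape[0]
    return float(((p - g) ** 2).sum() / (2 * n))


def density_loss_and_grad(pred, gt) -> tuple[float, np.ndarray]:
    """Loss plus its gradient with respect to the predicted batch."""
    p, g = _stack(pred), _stack(gt)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs gt {g.shape}")
    n = p.shape[0]
    diff = p - g
    return float((diff ** 2).sum() / (2 * n)), diff / n


def _trim_to_multiple(img: AnnotatedImage, scale: int) -> AnnotatedImage:
    """Crop at most scale-1 edge pixels so dims divide the output grid;
    points in the trimmed margin are dropped."""
    h, w = img.shape
    th, tw = (h // scale) * scale, (w // scale) * scale
    if (th, tw) == (h, w):
        return img
    pts = [p for p in img.points if p.row < th and p.col < tw]
    return AnnotatedImage(image=img.image[:th, :tw], points=pts,
                          size_class=img.size_class, image_id=img.image_id)


def _random_crop(img: AnnotatedImage, size: tuple[int, int],
                 rng: np.random.Generator) -> AnnotatedImage:
    ch, cw = size
    h, w = img.shape
    if ch > h or cw > w:
        raise ValueError(f"crop {size} larger than image {h}x{w}")
    r0 = int(rng.integers(0, h - ch + 1))
    c0 = int(rng.integers(0, w - cw + 1))
    pts = [PointAnnotation(p.row - r0, p.col - c0) for p in img.points
           if r0 <= p.row < r0 + ch and c0 <= p.col < c0 + cw]
    return AnnotatedImage(image=img.image[r0:r0 + ch, c0:c0 + cw], points=pts,
                          size_class=img.size_class, image_id=img.image_id)


def _gt_map(img: AnnotatedImage, scale: int) -> DensityMap:
    full = generate_density_map(img.points, img.shape,
                                assign_sigma(img.size_class),
                                renormalize_boundary=True)
    return downsample_mass_preserving(full, scale)


def _resolve_images(data) -> tuple[list[AnnotatedImage], list[AnnotatedImage]]:
    if isinstance(data, DatasetManifest):
        train = [load_annotated(e) for e in data.split("train")]
        test = [load_annotated(e) for e in data.split("test")]
    else:
        train, test = list(data), []
    if not train:
        raise ValueError("empty training set")
    return train, test or train


def train(data: DatasetManifest | Sequence[AnnotatedImage],
          model_config: ModelConfig | None = None,
          train_config: TrainConfig | None = None,
          model: MosquitoCounter | None = None,
          out_dir: str | Path | None = None,
          log=None) -> tuple[TrainState, MosquitoCounter]:
    """Optimize the counting network on a dataset.

    ``data`` is a manifest (train split optimized, test split used for the
    per-epoch MAE/RMSE curve) or a plain list of annotated images (then
    also used for evaluation).  Fully deterministic given
    ``train_config.seed``: weight init, data order and crop positions all
    derive from it.  Returns the training state (with the best-MAE weights)
    and the model, whose final parameters are the best-MAE ones.
    """
    mcfg = model_config if model_config is not None else ModelConfig()
    tcfg = train_config if train_config is not None else TrainConfig()
    train_imgs, eval_imgs = _resolve_images(data)

    if model is None:
        model = MosquitoCounter(mcfg, seed=tcfg.seed, init=tcfg.init)
    scale = model.scale
    if tcfg.crop_size is not None:
        ch, cw = tcfg.crop_size
        if ch % scale or cw % scale:
            raise ValueError(
                f"crop_size {tcfg.crop_size} must be a multiple of the model "
                f"scale {scale}")

    rng = np.random.default_rng(tcfg.seed)
    opt = SGD(model.params(), lr=tcfg.learning_rate, momentum=tcfg.momentum,
              weight_decay=tcfg.weight_decay)
    state = TrainState(seed=tcfg.seed)
    log = log if log is not None else (lambda msg: print(msg, file=sys.stderr))

    # precompute full-image GT only when training without crops
    if tcfg.crop_size is None:
        train_imgs = [_trim_to_multiple(im, scale) for im in train_imgs]
        gt_cache = [_gt_map(im, scale) for im in train_imgs]

    for epoch in range(1, tcfg.epochs + 1):
        order = rng.permutation(len(train_imgs))
        losses = []
        for start in range(0, len(order), tcfg.batch_size):
            idx = order[start:start + tcfg.batch_size]
            xs, gts = [], []
            for i in idx:
                if tcfg.crop_size is not None:
                    item = _random_crop(train_imgs[i], tcfg.crop_size, rng)
                    gt = _gt_map(item, scale)
                else:
                    item, gt = train_imgs[i], gt_cache[i]
                xs.append(model.preprocess(item.image)[0])
                gts.append(gt.values)
            x = np.stack(xs)
            pred = model.forward_tensor(x, raw=True)[:, 0]
            loss, dpred = density_loss_and_grad(pred, np.stack(gts))
            opt.zero_grad()
            model.backward_tensor(dpred[:, None])
            opt.step()
            losses.append(loss)
            state.loss_history.append(loss)
        state.epoch_loss.append(float(np.mean(losses)))

        if epoch % tcfg.eval_every == 0 or epoch == tcfg.epochs:
            res = evaluate(model, eval_imgs)
            state.metrics.append((epoch, res.mae, res.rmse))
            log(f"epoch {epoch}: loss {state.epoch_loss[-1]:.6g} "
                f"MAE {res.mae:.4f} RMSE {res.rmse:.4f}")
            if res.mae < state.best_mae:
                state.best_mae = res.mae
                state.best_epoch = epoch
                state.best_weights = {p.name: p.value.copy()
                                      for p in model.params()}

    if state.best_weights is not None:
        for p in model.params():
            p.value = state.best_weights[p.name].copy()
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        state.checkpoint_path = model.save_weights(out_dir / "best.npz")
        _write_logs(state, out_dir)
    return state, model


def _write_logs(state: TrainState, out_dir: Path) -> None:
    import pandas as pd
    pd.DataFrame({"epoch": range(1, len(state.epoch_loss) + 1),
                  "loss": state.epoch_loss}).to_csv(
        out_dir / "loss.csv", index=False)
    pd.DataFrame(state.metrics, columns=["epoch", "mae", "rmse"]).to_csv(
        out_dir / "metrics.csv", index=False)
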