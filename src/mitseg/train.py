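"""Training loop, temperature-scaling calibration and uncertainty maps.

Training follows the published recipe for this segmenter: Adam at learning
rate 6e-4, batches of 8, 50 epochs, dropout 0.1, layer-norm epsilon 1e-6,
plain (unweighted) pixelwise cross-entropy.  Logits are produced at 1/4
resolution and bilinearly upsampled to the mask resolution before the loss;
padded tile pixels are excluded via the validity mask.  Runs are fully
seeded: given a seed and single-threaded BLAS the loop is bitwise
reproducible.

Calibration is post-hoc temperature scaling: a single scalar T > 0 divides
the logits before the softmax, fitted by minimizing the validation negative
log-likelihood.  Dividing by a positive scalar is monotone per pixel, so
calibration never changes the argmax prediction — accuracy and mIoU are
invariant under it.  The per-pixel uncertainty is 1 - max_c p_c of the
calibrated posterior, which is 0 for a one-hot pixel and (K-1)/K for a
uniform one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .autodiff import Tensor, softmax_cross_entropy
from .decoder import _resize_bilinear
from .layers import Adam
from .metrics import confusion, mean_iou
from .network import SegFormer

__all__ = ["TrainConfig", "CalibratedPredictor", "train", "fit_temperature",
           "uncertainty_map", "majority_baseline_miou"]


@dataclass
class TrainConfig:
    batch_size: int = 8
    epochs: int = 50
    learning_rate: float = 6e-4
    dropout: float = 0.1
    layer_norm_eps: float = 1e-6
    seed: int = 0
    max_steps: int | None = None    # optional cap for short (smoke) runs

    def __post_init__(self):
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be positive")
        if not 0 < self.learning_rate < 1:
            raise ValueError("learning rate must be in (0, 1)")
        if not 0 <= self.dropout <= 1:
            raise ValueError("dropout must be in [0, 1]")
        if self.layer_norm_eps <= 0:
            raise ValueError("layer_norm_eps must be positive")


def _stack_tiles(tiles) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Tiles -> (images uint8 (B,H,W,3), masks (B,H,W), valid (B,H,W))."""
    imgs = np.stack([t.image for t in tiles])
    masks = np.stack([t.mask for t in tiles])
    valids = np.stack([getattr(t, "valid", np.ones_like(t.mask, bool))
                       for t in tiles])
    return imgs, masks.astype(np.int64), valids.astype(bool)


def _batch_loss(model: SegFormer, images, masks, valids) -> Tensor:
    x = Tensor(model.normalize(images))
    logits = model(x)
    B, Hm, Wm = masks.shape
    full = _resize_bilinear(logits, Hm, Wm)
    K = full.shape[-1]
    return softmax_cross_entropy(full.reshape(B * Hm * Wm, K),
                                 masks.reshape(-1), valids.reshape(-1))


def _eval_miou(model: SegFormer, images, masks, valids, K: int) -> float:
    model.eval()
    preds = []
    for img in images:
        pred, _ = model.predict(img)
        preds.append(pred)
    cm = confusion(np.stack(preds), masks, K=K, validity_mask=valids)
    return mean_iou(cm)


def train(model: SegFormer, train_set, val_set, config: TrainConfig):
    """Train ``model`` on tile sets; returns (model, history).

    ``train_set``/``val_set`` are lists of objects with ``image``, ``mask``
    and optional ``valid`` attributes (e.g. :class:`~mitseg.datapipe.Tile`
    or :class:`~mitseg.datapipe.LabeledSpecimen`).  History records the mean
    training loss per epoch and the validation mIoU.
    """
    if not train_set:
        raise ValueError("training set is empty")
    K = model.spec.num_classes
    imgs, masks, valids = _stack_tiles(train_set)
    if masks.max() >= K:
        raise ValueError(
            f"mask contains class index {masks.max()} >= num_classes {K}")
    if val_set:
        vimgs, vmasks, vvalids = _stack_tiles(val_set)
        if vmasks.max() >= K:
            raise ValueError("validation mask contains out-of-range class")

    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    n = len(train_set)
    history = {"epoch": [], "train_loss": [], "val_miou": []}
    step = 0
    done = False
    for epoch in range(config.epochs):
        model.train()
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, config.batch_size):
            idx = order[lo:lo + config.batch_size]
            loss = _batch_loss(model, imgs[idx], masks[idx], valids[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            step += 1
            if config.max_steps is not None and step >= config.max_steps:
                done = True
                break
        history["epoch"].append(epoch)
        history["train_loss"].append(float(np.mean(losses)))
        if val_set:
            history["val_miou"].append(_eval_miou(model, vimgs, vmasks,
                                                  vvalids, K))
        else:
            history["val_miou"].append(float("nan"))
        if done:
            break
    model.eval()
    return model, history


def majority_baseline_miou(masks: np.ndarray, valids: np.ndarray | None = None,
                           K: int = 12) -> float:
    """mIoU of always predicting the most frequent class in ``masks``."""
    masks = np.asarray(masks)
    if valids is None:
        valids = np.ones_like(masks, dtype=bool)
    counts = np.bincount(masks[valids].ravel(), minlength=K)
    majority = int(counts.argmax())
    pred = np.full_like(masks, majority)
    cm = confusion(pred, masks, K=K, validity_mask=valids)
    return mean_iou(cm)


@dataclass
class CalibratedPredictor:
    """A segmenter plus its fitted softmax temperature."""
    model: SegFormer
    temperature: float = 1.0

    def __post_init__(self):
        if not np.isfinite(self.temperature) or self.temperature <= 0:
            raise ValueError("temperature must be finite and positive")

    def predict(self, image: np.ndarray):
        return self.model.predict(image, temperature=self.temperature)

    def uncertainty(self, image: np.ndarray) -> np.ndarray:
        _, probs = self.predict(image)
        return uncertainty_map(probs)


def _nll(logits: np.ndarray, labels: np.ndarray, T: float) -> float:
    z = logits / T
    return float(np.mean(logsumexp(z, axis=1) -
                         z[np.arange(len(labels)), labels]))


def fit_temperature(val_logits: np.ndarray, val_labels: np.ndarray,
                    model: SegFormer | None = None) -> CalibratedPredictor:
    """Fit the scaling temperature on validation logits.

    ``val_logits``: (N, K) pre-softmax scores; ``val_labels``: (N,) class
    indices.  T minimizes the negative log-likelihood of softmax(logits/T)
    (a 1-D convex problem, solved on log T).  A degenerate single-class
    validation set yields T = 1 with a warning.
    """
    val_logits = np.asarray(val_logits, dtype=np.float64)
    val_labels = np.asarray(val_labels).reshape(-1)
    if val_logits.ndim != 2 or val_logits.shape[0] != val_labels.shape[0]:
        raise ValueError("logits must be (N, K) matching N labels")
    if val_labels.size == 0:
        raise ValueError("empty validation set")
    if len(np.unique(val_labels)) < 2:
        warnings.warn("single-class validation set; temperature left at 1.0")
        return CalibratedPredictor(model=model, temperature=1.0)

    res = minimize_scalar(
        lambda logt: _nll(val_logits, val_labels, float(np.exp(logt))),
        bounds=(np.log(0.05), np.log(20.0)), method="bounded",
        options={"xatol": 1e-6})
    T = float(np.exp(res.x))
    # optimization contract: never worse than the uncalibrated model
    if _nll(val_logits, val_labels, T) > _nll(val_logits, val_labels, 1.0):
        T = 1.0
    return CalibratedPredictor(model=model, temperature=T)


def uncertainty_map(probs: np.ndarray) -> np.ndarray:
    """Per-pixel uncertainty 1 - max_c p_c of a probability field.

    ``probs`` has classes on the last axis; rows must sum to 1 (tolerance
    1e-4).  The result is in [0, 1 - 1/K] pixelwise.
    """
    probs = np.asarray(probs, dtype=np.float64)
    sums = probs.sum(axis=-1)
    if np.abs(sums - 1.0).max() > 1e-4:
        raise ValueError("probability rows must sum to 1 (within 1e-4)")
    return 1.0 - probs.max(axis=-1)
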