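"""Encoder-decoder segmentation of positive T-cells, one model per marker.

The network is a residual-encoder U-Net (7x7/64 stem, four residual stages,
/32 bottleneck, transpose-convolution decoder with skip connections) trained
with weighted cross-entropy on patches normalised to [0, 1]. Splits are made
patient-wise at 70/16/14 so no patient contributes to more than one subset.
Defaults follow the reference training recipe: Adam, lr 1e-4, batch 16,
100 epochs, rotation up to 30 degrees plus horizontal/vertical flips at
p=0.5, and a 0.5 binarisation threshold; tests run a narrower channel plan.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from . import nn
from .types import AnnotatedPatch

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "SegmentationModel",
    "split_by_patient",
    "build_model",
    "compute_class_weights",
    "weighted_cross_entropy",
    "augment",
    "train",
    "predict_mask",
    "dice_score",
    "save_model",
    "load_model",
]


@dataclass
class TrainConfig:
    input_size_px: int = 256
    batch_size: int = 16
    learning_rate: float = 1e-4
    epochs: int = 100
    optimizer: str = "adam"
    loss: str = "wce"
    augment_rotation_max_deg: float = 30.0
    augment_flip_prob: float = 0.5
    encoder_pretrained: bool = False
    pretrained_weights_path: str | None = None
    binarize_threshold: float = 0.5
    split_ratios: tuple = (0.70, 0.16, 0.14)
    seed: int = 0
    # capacity knobs (default = full reference plan)
    base_channels: int = 64
    blocks_per_stage: tuple = (2, 2, 2, 2)
    class_weight_cap: float = 100.0

    def __post_init__(self):
        if abs(sum(self.split_ratios) - 1.0) > 1e-9:
            raise ValueError("split ratios must sum to 1")
        if not 0.0 < self.binarize_threshold < 1.0 and self.binarize_threshold != 1.0:
            raise ValueError("threshold must lie in (0, 1]")


@dataclass
class SegmentationModel:
    marker: str
    net: nn.ResUNet
    config: TrainConfig
    history: list = field(default_factory=list)
    class_weights: tuple = (1.0, 1.0)


def split_by_patient(patches, ratios=(0.70, 0.16, 0.14), seed=0):
    """Patient-level train/val/test split; every patient lands in one subset."""
    order = []
    for p in patches:
        if p.patient_id not in order:
            order.append(p.patient_id)
    n = len(order)
    if n < 3:
        raise ValueError(f"need at least 3 distinct patients, got {n}")
    rng = np.random.default_rng(seed)
    ids = list(rng.permutation(order))
    n_train = max(1, int(round(ratios[0] * n)))
    n_val = max(1, int(round(ratios[1] * n)))
    if n_train + n_val >= n:        # keep the test set non-empty
        n_train = n - n_val - 1
    groups = (set(ids[:n_train]), set(ids[n_train : n_train + n_val]),
              set(ids[n_train + n_val :]))
    return tuple([p for p in patches if p.patient_id in g] for g in groups)


def build_model(marker: str, config: TrainConfig | None = None) -> SegmentationModel:
    """Untrained model; optionally initialise the state from a local .npz."""
    config = config or TrainConfig()
    net = nn.ResUNet(config.base_channels, config.blocks_per_stage, seed=config.seed)
    if config.encoder_pretrained:
        if config.pretrained_weights_path:
            with np.load(config.pretrained_weights_path) as npz:
                net.load_state_dict(dict(npz))
        else:
            logger.warning("encoder_pretrained set but no weights path; "
                           "keeping random initialisation")
    return SegmentationModel(marker=marker, net=net, config=config)


def compute_class_weights(masks, cap=100.0):
    """Inverse-frequency pixel weights normalised to mean 1.

    w_c = N_total / (2 N_c); a class absent from every mask gets the cap.
    """
    n_fg = sum(int(m.sum()) for m in masks)
    n_px = sum(m.size for m in masks)
    n_bg = n_px - n_fg
    if n_fg == 0 or n_bg == 0:
        logger.warning("one pixel class absent from all masks; capping weight")
    w_fg = min(n_px / (2.0 * n_fg), cap) if n_fg else cap
    w_bg = min(n_px / (2.0 * n_bg), cap) if n_bg else cap
    return float(w_fg), float(w_bg)


def weighted_cross_entropy(prob_map, target_mask, class_weights=(1.0, 1.0),
                           eps=1e-7):
    """Mean pixelwise weighted cross-entropy with probability clipping."""
    p = np.asarray(prob_map, dtype=float)
    t = np.asarray(target_mask, dtype=float)
    if p.shape != t.shape:
        raise ValueError("shape mismatch")
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(t))):
        raise ValueError("non-finite inputs")
    w_fg, w_bg = class_weights
    if w_fg <= 0 or w_bg <= 0:
        raise ValueError("class weights must be positive")
    p = np.clip(p, eps, 1.0 - eps)
    return float(-np.mean(w_fg * t * np.log(p) + w_bg * (1.0 - t) * np.log1p(-p)))


def _wce_grad_wrt_logits(p, t, w_fg, w_bg):
    # d/dz of mean WCE through the sigmoid (clipping treated as identity)
    return (w_fg * t * (p - 1.0) + w_bg * (1.0 - t) * p) / p.size


def augment(patch: AnnotatedPatch, config: TrainConfig, rng) -> AnnotatedPatch:
    """Random rotation and flips, applied identically to image and mask.

    Image rotation uses bilinear interpolation with reflect fill; the mask
    uses nearest-neighbour with constant-0 fill so it stays binary.
    """
    img = patch.image.astype(float)
    mask = patch.mask.copy()
    angle = rng.uniform(-config.augment_rotation_max_deg,
                        config.augment_rotation_max_deg)
    if angle != 0.0:
        img = ndimage.rotate(img, angle, axes=(0, 1), reshape=False,
                             order=1, mode="reflect")
        mask = ndimage.rotate(mask, angle, axes=(0, 1), reshape=False,
                              order=0, mode="constant", cval=0)
    if rng.random() < config.augment_flip_prob:
        img, mask = img[:, ::-1], mask[:, ::-1]
    if rng.random() < config.augment_flip_prob:
        img, mask = img[::-1, :], mask[::-1, :]
    return AnnotatedPatch(
        image=np.clip(np.round(img), 0, 255).astype(np.uint8),
        mask=np.ascontiguousarray(mask).astype(np.uint8),
        marker=patch.marker, patient_id=patch.patient_id,
        institution_id=patch.institution_id, n_cells=patch.n_cells,
    )


def _to_input(image, size):
    """uint8 HxWx3 -> float (3,size,size) in [0,1]."""
    x = np.asarray(image, dtype=float) / 255.0
    if x.shape[0] != size or x.shape[1] != size:
        x = resize(x, (size, size, 3), order=1, anti_aliasing=True,
                   preserve_range=True)
    return x.transpose(2, 0, 1)


def _mask_to_size(mask, size):
    if mask.shape == (size, size):
        return mask.astype(float)
    return resize(mask.astype(float), (size, size), order=0,
                  anti_aliasing=False, preserve_range=True)


def dice_score(pred, gt):
    """Dice of two binary masks; 1.0 when both are empty."""
    pred = np.asarray(pred).astype(bool)
    gt = np.asarray(gt).astype(bool)
    denom = pred.sum() + gt.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(pred, gt).sum() / denom


def train(model: SegmentationModel, train_set, val_set,
          config: TrainConfig | None = None) -> SegmentationModel:
    """Adam/WCE training loop keeping the best-validation-Dice state."""
    config = config or model.config
    if not train_set:
        raise ValueError("empty training set")
    if config.epochs == 0:
        return model
    rng = np.random.default_rng(config.seed)
    size = config.input_size_px
    model.class_weights = compute_class_weights(
        [p.mask for p in train_set], cap=config.class_weight_cap
    )
    w_fg, w_bg = model.class_weights
    opt = nn.Adam(model.net.parameters(), lr=config.learning_rate)

    best_dice, best_state = -1.0, None
    for epoch in range(config.epochs):
        order = rng.permutation(len(train_set))
        losses = []
        for start in range(0, len(order), config.batch_size):
            batch = [train_set[i] for i in order[start : start + config.batch_size]]
            if config.augment_rotation_max_deg or config.augment_flip_prob:
                batch = [augment(p, config, rng) for p in batch]
            x = np.stack([_to_input(p.image, size) for p in batch])
            t = np.stack([_mask_to_size(p.mask, size) for p in batch])[:, None]
            logits = model.net.forward(x, train=True)
            p = nn.sigmoid(logits)
            loss = weighted_cross_entropy(p, t, (w_fg, w_bg))
            if not np.isfinite(loss):
                raise RuntimeError(f"NaN/inf loss at epoch {epoch}")
            model.net.backward(_wce_grad_wrt_logits(p, t, w_fg, w_bg))
            opt.step()
            losses.append(loss)

        val_dice = _mean_dice(model, val_set or train_set, config)
        model.history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                              "val_dice": val_dice})
        if val_dice >= best_dice:
            best_dice, best_state = val_dice, model.net.copy_state()
    if best_state is not None:
        model.net.load_state_dict(best_state)
    return model


def _mean_dice(model, patches, config):
    size = config.input_size_px
    scores = []
    for p in patches:
        pred = predict_mask(model, p.image, config.binarize_threshold,
                            input_size=size)
        scores.append(dice_score(pred, _mask_to_size(p.mask, pred.shape[0]) > 0.5))
    return float(np.mean(scores))


def predict_mask(model: SegmentationModel, image, threshold=0.5,
                 input_size: int | None = None) -> np.ndarray:
    """Binary mask (p >= threshold) at the input's spatial size.

    Inputs whose sides are not divisible by 32 are reflect-padded for the
    forward pass and cropped back. ``input_size`` resizes before inference
    (and the mask is resized back), matching the training resolution.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an RGB HxWx3 image")
    h, w = image.shape[:2]
    if input_size is not None and (h != input_size or w != input_size):
        x = _to_input(image, input_size)[None]
    else:
        x = (image.astype(float) / 255.0).transpose(2, 0, 1)[None]
    ph = (-x.shape[2]) % 32
    pw = (-x.shape[3]) % 32
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)), mode="reflect")
    prob = nn.sigmoid(model.net.forward(x, train=False))[0, 0]
    if ph or pw:
        prob = prob[: prob.shape[0] - ph, : prob.shape[1] - pw]
    mask = (prob >= threshold).astype(np.uint8)
    if mask.shape != (h, w):
        mask = (resize(mask.astype(float), (h, w), order=0,
                       preserve_range=True) > 0.5).astype(np.uint8)
    return mask


def save_model(model: SegmentationModel, path) -> None:
    meta = {"marker": model.marker, "config": asdict(model.config),
            "history": model.history, "class_weights": list(model.class_weights)}
    np.savez_compressed(path, __meta__=json.dumps(meta),
                        **model.net.state_dict())


def load_model(path) -> SegmentationModel:
    with np.load(path, allow_pickle=False) as npz:
        meta = json.loads(str(npz["__meta__"]))
        state = {k: npz[k] for k in npz.files if k != "__meta__"}
    cfg = meta["config"]
    cfg["split_ratios"] = tuple(cfg["split_ratios"])
    cfg["blocks_per_stage"] = tuple(cfg["blocks_per_stage"])
    config = TrainConfig(**cfg)
    model = build_model(meta["marker"], config)
    model.net.load_state_dict(state)
    model.history = meta["history"]
    model.class_weights = tuple(meta["class_weights"])
    return model
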