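"""Training, evaluation, prediction and ablation orchestration.

The training objective is the joint loss ``lambda1 * L_mask + lambda2 *
L_edge``: binary cross-entropy on the predicted mask plus a class-balanced
cross-entropy between the differentiable soft edge of the prediction and
the Canny edge map of the ground-truth mask (the hard Canny operator is
applied to the label side only, where no gradient is needed).

Ablation variants mirror the component study: ``backbone`` (plain U-Net),
``backbone+AM`` (attention gates), ``backbone+EI`` (edge loss) and
``backbone+EI+AM`` (the full model).  All variants share bit-identical
backbone initialisation and data order for a given seed.

Two problem scales are bundled: the clinical protocol (256x512 crops,
depth-4/base-64 network, 300 epochs, Adam, lr 1e-4, batch 4) and a desk
scale for end-to-end testing on phantoms (64x128 images, depth-2/base-4
network, 15 epochs, lr 1e-3 — the learning rate is scaled up because the
step budget is roughly 75x smaller).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import data_io, edge_ops, losses, metrics
from .network import AttentionUNet, NetworkConfig, build_model, load_checkpoint, save_checkpoint
from .phantom import PhantomConfig, generate_phantom
from . import nn

__all__ = [
    "VARIANTS", "TrainConfig", "ArrayDataset", "TrainResult",
    "desk_phantom_config", "desk_train_config", "make_phantom_splits",
    "load_split_datasets", "train", "evaluate", "predict", "ablate",
    "overfit_single", "train_config_from_yaml",
]

#: variant name -> (use_attention, use_edge_head)
VARIANTS: dict[str, tuple[bool, bool]] = {
    "backbone": (False, False),
    "backbone+AM": (True, False),
    "backbone+EI": (False, True),
    "backbone+EI+AM": (True, True),
}


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol + network size + loss configuration."""

    epochs: int = 300
    learning_rate: float = 1e-4
    batch_size: int = 4
    optimizer: str = "adam"
    mask_loss: str = "bce"              # "bce" or "dice"
    lambda1: float = 1.0
    lambda2: float = 1.0
    edge_low: float = 0.1 * edge_ops.MAX_GRADIENT_MAGNITUDE
    edge_high: float = 0.2 * edge_ops.MAX_GRADIENT_MAGNITUDE
    variant: str = "backbone+EI+AM"
    depth: int = 4
    base_channels: int = 64
    learned_edge_head: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; one of {sorted(VARIANTS)}")
        if self.mask_loss not in ("bce", "dice"):
            raise ValueError("mask_loss must be 'bce' or 'dice'")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")

    @property
    def loss_weights(self) -> losses.LossWeights:
        return losses.LossWeights(lambda1=self.lambda1, lambda2=self.lambda2)

    def network_config(self, input_size: tuple[int, int]) -> NetworkConfig:
        use_att, use_edge = VARIANTS[self.variant]
        return NetworkConfig(depth=self.depth, base_channels=self.base_channels,
                             use_attention=use_att, use_edge_head=use_edge,
                             learned_edge_head=self.learned_edge_head,
                             input_size=input_size, seed=self.seed)


@dataclass
class ArrayDataset:
    """In-memory image/mask arrays: (n, H, W) float32 and (n, H, W) uint8."""

    images: np.ndarray
    masks: np.ndarray

    def __post_init__(self) -> None:
        if self.images.shape != self.masks.shape:
            raise ValueError("images and masks must have identical shapes")
        if len(self.images) == 0:
            raise ValueError("dataset is empty")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def image_size(self) -> tuple[int, int]:
        return self.images.shape[1], self.images.shape[2]


@dataclass
class TrainResult:
    model: AttentionUNet
    history: pd.DataFrame
    best_val_dice: float
    checkpoint_path: Path | None = None


def desk_phantom_config() -> PhantomConfig:
    """Scaled-down phantom conditions for end-to-end testing.

    Quarter the clinical crop linearly (64x128), follicle semi-axes scaled
    to 3–15 px, boundary blur 1 px; speckle strength and intensity levels
    unchanged.
    """
    return PhantomConfig(height=64, width=128, follicle_count_range=(1, 6),
                         axis_range=(3.0, 15.0), boundary_blur_sigma=1.0)


def desk_train_config(**overrides) -> TrainConfig:
    """Desk-scale training protocol (15 epochs, depth-2/base-4 net, lr 1e-3)."""
    base = dict(epochs=15, learning_rate=1e-3, depth=2, base_channels=4)
    base.update(overrides)
    return TrainConfig(**base)


def make_phantom_splits(cfg: PhantomConfig, n_train: int, n_val: int, n_test: int,
                        seed: int) -> dict[str, ArrayDataset]:
    """Generate train/val/test phantom datasets in memory (no file round trip)."""
    master = np.random.default_rng(seed)
    out = {}
    for split, n in (("train", n_train), ("val", n_val), ("test", n_test)):
        seeds = master.integers(0, 2 ** 31, size=n)
        imgs = np.empty((n, cfg.height, cfg.width), dtype=np.float32)
        msks = np.empty((n, cfg.height, cfg.width), dtype=np.uint8)
        for i, s in enumerate(seeds):
            sample = generate_phantom(cfg, int(s))
            imgs[i] = sample.image
            msks[i] = sample.mask
        out[split] = ArrayDataset(images=imgs, masks=msks)
    return out


def load_split_datasets(root) -> dict[str, ArrayDataset]:
    """Load a generated dataset directory with a ``split.json`` assignment."""
    root = Path(root)
    with open(root / "split.json") as fh:
        split_doc = json.load(fh)
    out = {}
    for split in ("train", "val", "test"):
        pairs = [(e["image"], e["mask"]) for e in split_doc["entries"]
                 if e["split"] == split]
        if not pairs:
            continue
        imgs = np.stack([data_io.load_image(root / img) for img, _ in pairs])
        msks = np.stack([data_io.load_mask(root / msk) for _, msk in pairs])
        out[split] = ArrayDataset(images=imgs.astype(np.float32), masks=msks)
    return out


def write_split(root, ratios=(0.7, 0.15, 0.15), seed: int = 0) -> dict:
    """Assign the samples of a generated dataset directory to splits."""
    root = Path(root)
    with open(root / "manifest.json") as fh:
        manifest = json.load(fh)
    pairs = [(e["image"], e["mask"]) for e in manifest["entries"]]
    m = data_io.make_manifest(pairs, ratios=ratios, seed=seed)
    doc = {"ratios": list(m.ratios), "split_seed": m.split_seed,
           "entries": [{"image": img, "mask": msk, "split": s} for img, msk, s in m.entries]}
    with open(root / "split.json", "w") as fh:
        json.dump(doc, fh, indent=1)
    return doc


# -- training --------------------------------------------------------------

def _bce_from_logits(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean BCE over all pixels and its gradient w.r.t. the logits."""
    # BCE = y*softplus(-z) + (1-y)*softplus(z); softplus via logaddexp for stability
    loss = float(np.mean(y * np.logaddexp(0.0, -z) + (1.0 - y) * np.logaddexp(0.0, z)))
    p = nn.sigmoid(z)
    return loss, (p - y) / z.size


def _dice_from_probs(p: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Soft Dice loss and its gradient w.r.t. the probabilities."""
    smooth = 1.0
    inter = float(np.sum(p * y))
    denom = float(np.sum(p) + np.sum(y))
    loss = 1.0 - (2.0 * inter + smooth) / (denom + smooth)
    grad = -(2.0 * y * (denom + smooth) - (2.0 * inter + smooth)) / (denom + smooth) ** 2
    return loss, grad


def _gt_edges(masks: np.ndarray, cfg: TrainConfig) -> np.ndarray:
    """Canny edge maps of ground-truth masks (label side of the edge loss)."""
    out = np.empty(masks.shape, dtype=np.uint8)
    for i, m in enumerate(masks):
        out[i] = edge_ops.canny(m.astype(float), low=cfg.edge_low, high=cfg.edge_high)
    return out


def _batch_dice(model: AttentionUNet, ds: ArrayDataset, batch: int = 8) -> float:
    preds = predict_masks(model, ds.images, batch=batch)
    agg = metrics.evaluate_dataset(list(zip(preds, ds.masks)))
    return agg.dice


def predict_masks(model: AttentionUNet, images: np.ndarray, batch: int = 8,
                  threshold: float = 0.5) -> np.ndarray:
    """Binarised predictions (n, H, W) for an image stack."""
    out = np.empty(images.shape, dtype=np.uint8)
    for i in range(0, len(images), batch):
        prob, _ = model.forward(images[i:i + batch])
        out[i:i + batch] = (prob >= threshold).astype(np.uint8)
    return out


def train(data: dict[str, ArrayDataset] | str | Path, cfg: TrainConfig,
          out_dir=None) -> TrainResult:
    """Train one model; returns the best-validation-Dice parameters.

    ``data`` is either a dict with "train"/"val" :class:`ArrayDataset` items
    or a dataset directory (see :func:`load_split_datasets`).  Fully seeded:
    identical (data, config) give identical training logs.
    """
    if not isinstance(data, dict):
        data = load_split_datasets(data)
    if "train" not in data or "val" not in data:
        raise ValueError("training requires non-empty 'train' and 'val' splits")
    ds_train, ds_val = data["train"], data["val"]

    model = build_model(cfg.network_config(ds_train.image_size))
    params = model.params()
    opt = nn.Adam(params, lr=cfg.learning_rate)
    use_edge = model.config.use_edge_head
    w = cfg.loss_weights

    gt_edges = _gt_edges(ds_train.masks, cfg) if use_edge else None
    order_rng = np.random.default_rng(cfg.seed)

    rows = []
    best_dice = -1.0
    best_params = [p.data.copy() for p in params]
    for epoch in range(cfg.epochs):
        perm = order_rng.permutation(len(ds_train))
        epoch_mask, epoch_edge, epoch_joint, steps = 0.0, 0.0, 0.0, 0
        for start in range(0, len(perm), cfg.batch_size):
            idx = perm[start:start + cfg.batch_size]
            x = ds_train.images[idx][..., None]
            y = ds_train.masks[idx][..., None].astype(np.float32)
            z = model.forward_logits(x)
            if cfg.mask_loss == "bce":
                l_mask, g_z = _bce_from_logits(z, y)
            else:
                p = nn.sigmoid(z)
                l_mask, g_p = _dice_from_probs(p, y)
                g_z = g_p * p * (1.0 - p)
            g_z = (w.lambda1 * g_z).astype(nn.DTYPE)

            l_edge = 0.0
            if use_edge and w.lambda2 > 0.0:
                p = nn.sigmoid(z)
                e = model.edge_head(p)
                ye = gt_edges[idx].astype(np.float32)
                g_e = np.empty_like(e)
                for b in range(len(idx)):
                    l_edge += losses.balanced_edge_loss(e[b, :, :, 0], ye[b])
                    g_e[b, :, :, 0] = losses.balanced_edge_loss_grad(e[b, :, :, 0], ye[b])
                l_edge /= len(idx)
                g_e /= len(idx)
                g_p_edge = model.edge_head_backward((w.lambda2 * g_e).astype(nn.DTYPE))
                g_z = g_z + (g_p_edge * p * (1.0 - p)).astype(nn.DTYPE)

            opt.zero_grad()
            model.backward(g_z)
            opt.step()
            joint = w.lambda1 * l_mask + w.lambda2 * l_edge
            epoch_mask += l_mask
            epoch_edge += l_edge
            epoch_joint += joint
            steps += 1

        val_dice = _batch_dice(model, ds_val)
        rows.append({"epoch": epoch, "steps": steps,
                     "mask_loss": epoch_mask / steps, "edge_loss": epoch_edge / steps,
                     "joint_loss": epoch_joint / steps, "val_dice": val_dice})
        if val_dice > best_dice:
            best_dice = val_dice
            best_params = [p.data.copy() for p in params]

    for p, best in zip(params, best_params):
        p.data[...] = best
    history = pd.DataFrame(rows)

    ckpt_path = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        ckpt_path = out_dir / "checkpoint.npz"
        save_checkpoint(model, ckpt_path,
                        extra={"train_config": dataclasses.asdict(cfg),
                               "best_val_dice": best_dice})
        history.to_csv(out_dir / "training_log.csv", index=False)
    return TrainResult(model=model, history=history, best_val_dice=best_dice,
                       checkpoint_path=ckpt_path)


# -- evaluation / prediction ----------------------------------------------

def evaluate(model_or_checkpoint, data: dict[str, ArrayDataset] | str | Path,
             split: str = "test", out_csv=None
             ) -> tuple[metrics.SegmentationScores, pd.DataFrame]:
    """Per-image and aggregate scores of a trained model on one split."""
    model = model_or_checkpoint
    if not isinstance(model, AttentionUNet):
        model, _ = load_checkpoint(model_or_checkpoint)
    if not isinstance(data, dict):
        data = load_split_datasets(data)
    if split not in data or len(data[split]) == 0:
        raise ValueError(f"split {split!r} is empty")
    ds = data[split]
    preds = predict_masks(model, ds.images)
    pairs = list(zip(preds, ds.masks))
    frame = metrics.report_frame(pairs)
    agg = metrics.evaluate_dataset(pairs)
    if out_csv is not None:
        frame.to_csv(out_csv, index=False)
    return agg, frame


def predict(model_or_checkpoint, in_path, out_dir, edge_maps: bool = False) -> list[Path]:
    """Predict 0/255 mask PNGs for an image file or directory."""
    model = model_or_checkpoint
    if not isinstance(model, AttentionUNet):
        model, _ = load_checkpoint(model_or_checkpoint)
    in_path, out_dir = Path(in_path), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = sorted(in_path.glob("*.png")) + sorted(in_path.glob("*.tif*")) \
        if in_path.is_dir() else [in_path]
    written = []
    for f in files:
        img = data_io.load_image(f)
        prob, _ = model.forward(img[None].astype(np.float32))
        mask = (prob[0] >= 0.5).astype(np.uint8)
        out = out_dir / f"{f.stem}_mask.png"
        data_io.save_mask(mask, out)
        written.append(out)
        if edge_maps:
            edge = edge_ops.canny(mask.astype(float))
            edge_out = out_dir / f"{f.stem}_edge.png"
            data_io.save_mask(edge, edge_out)
            written.append(edge_out)
    return written


def ablate(data: dict[str, ArrayDataset] | str | Path, base_cfg: TrainConfig,
           variants: list[str], seeds: list[int]) -> pd.DataFrame:
    """Train each variant for each seed; report mean +/- sd of test metrics."""
    if len(variants) < 2 or len(seeds) < 1:
        raise ValueError("need at least 2 variants and 1 seed")
    if not isinstance(data, dict):
        data = load_split_datasets(data)
    rows = []
    for variant in variants:
        per_seed = []
        for seed in seeds:
            cfg = dataclasses.replace(base_cfg, variant=variant, seed=seed)
            result = train(data, cfg)
            agg, _ = evaluate(result.model, data, "test")
            per_seed.append(agg.as_dict())
        row = {"variant": variant, "n_seeds": len(seeds)}
        for name in ("recall", "precision", "jaccard", "dice"):
            vals = [d[name] for d in per_seed]
            row[f"{name}_mean"] = float(np.mean(vals))
            row[f"{name}_sd"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def overfit_single(sample_image: np.ndarray, sample_mask: np.ndarray,
                   steps: int = 200, lr: float = 6e-3,
                   cfg: TrainConfig | None = None) -> pd.DataFrame:
    """Learnability smoke test: drive the joint loss down on a single image.

    Runs ``steps`` Adam updates of the full model on one (image, mask) pair
    and returns the per-step loss trace.  The learning rate defaults to a
    value suited to a few hundred steps rather than a full training run.
    """
    if cfg is None:
        cfg = desk_train_config()
    cfg = dataclasses.replace(cfg, learning_rate=lr, epochs=1, batch_size=1)
    ds = ArrayDataset(images=sample_image[None].astype(np.float32),
                      masks=sample_mask[None].astype(np.uint8))
    model = build_model(cfg.network_config(ds.image_size))
    opt = nn.Adam(model.params(), lr=lr)
    use_edge = model.config.use_edge_head
    w = cfg.loss_weights
    gt_edge = _gt_edges(ds.masks, cfg)[0].astype(np.float32) if use_edge else None

    x = ds.images[..., None]
    y = ds.masks[..., None].astype(np.float32)
    rows = []
    for step in range(steps):
        z = model.forward_logits(x)
        l_mask, g_z = _bce_from_logits(z, y)
        g_z = (w.lambda1 * g_z).astype(nn.DTYPE)
        l_edge = 0.0
        if use_edge and w.lambda2 > 0:
            p = nn.sigmoid(z)
            e = model.edge_head(p)
            l_edge = losses.balanced_edge_loss(e[0, :, :, 0], gt_edge)
            g_e = losses.balanced_edge_loss_grad(e[0, :, :, 0], gt_edge)[None, :, :, None]
            g_p_edge = model.edge_head_backward((w.lambda2 * g_e).astype(nn.DTYPE))
            g_z = g_z + (g_p_edge * p * (1.0 - p)).astype(nn.DTYPE)
        opt.zero_grad()
        model.backward(g_z)
        opt.step()
        rows.append({"step": step, "mask_loss": l_mask, "edge_loss": l_edge,
                     "joint_loss": w.lambda1 * l_mask + w.lambda2 * l_edge})
    return pd.DataFrame(rows)


# -- config files ----------------------------------------------------------

def train_config_from_yaml(path) -> TrainConfig:
    """Load a YAML mapping of TrainConfig fields (missing fields -> defaults)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(TrainConfig)}
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return TrainConfig(**doc)
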