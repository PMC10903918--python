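"""Tile streaming, augmentation and the optimization loop.

Training operates on square 2D tiles sampled from z-stacks: raw image
plus binary spine and dendrite target masks. Image intensities are
linearly rescaled to [−1, 1] per tile; augmentation applies geometric
transforms (flips, 90° and small-angle rotations) identically to image
and targets and photometric transforms (Gaussian noise, brightness,
contrast) to the image only.

The optimizer is Adam with a flat-then-exponential learning-rate
schedule: lr₀ = 0.5·10⁻³ held for 15 epochs, then decayed by
exp(−0.1·(epoch − 15)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import numpy as np
import yaml
from skimage.transform import rotate as _sk_rotate

from ._nn import Adam, backward, dice_loss_node, mse_loss_node
from .network import SegmentationModel
from .stack_io import ImageStack, read_stack, rescale_stack


@dataclass
class TrainingSample:
    image_tile: np.ndarray     # float in [−1, 1]
    spine_target: np.ndarray   # binary
    dendrite_target: np.ndarray
    voxel_size_xy_um: float


@dataclass
class AugmentConfig:
    """Per-transform application probabilities and magnitudes."""

    p_flip: float = 0.5
    p_rot90: float = 0.5
    p_rot_small: float = 0.5
    max_small_angle_deg: float = 10.0
    p_noise: float = 0.5
    noise_sd: float = 0.05          # on the [−1, 1] scale
    p_brightness: float = 0.5
    brightness_delta: float = 0.2
    p_contrast: float = 0.5
    contrast_range: tuple[float, float] = (0.8, 1.2)

    @classmethod
    def disabled(cls) -> "AugmentConfig":
        return cls(p_flip=0, p_rot90=0, p_rot_small=0, p_noise=0,
                   p_brightness=0, p_contrast=0)


@dataclass
class TrainConfig:
    lr0: float = 0.5e-3
    warm_epochs: int = 15
    decay_time_constant: float = 0.1
    tile_size: int = 128
    batch_size: int = 32
    epochs: int = 50
    steps_per_epoch: Optional[int] = None
    seed: int = 0
    resolution_mode: str = "mixed"          # "mixed" | "fixed"
    target_xy_um: float = 0.094             # used in fixed mode
    loss_mode: str = "sum"                  # "sum" | "alternate"
    augment: AugmentConfig = field(default_factory=AugmentConfig)

    def __post_init__(self):
        if self.lr0 <= 0 or self.epochs < 1:
            raise ValueError("lr0 must be > 0 and epochs ≥ 1")
        if self.resolution_mode not in ("mixed", "fixed"):
            raise ValueError("resolution_mode must be 'mixed' or 'fixed'")
        if self.loss_mode not in ("sum", "alternate"):
            raise ValueError("loss_mode must be 'sum' or 'alternate'")


# --------------------------------------------------------------------------
# normalization & augmentation
# --------------------------------------------------------------------------

def normalize_intensity(tile: np.ndarray) -> np.ndarray:
    """Linearly rescale so min → −1 and max → +1; constant tiles → 0."""
    tile = np.asarray(tile, dtype=np.float64)
    lo, hi = tile.min(), tile.max()
    if hi == lo:
        return np.zeros_like(tile)
    return 2.0 * (tile - lo) / (hi - lo) - 1.0


def augment_tile(sample: TrainingSample, seed,
                 config: Optional[AugmentConfig] = None) -> TrainingSample:
    """Apply seeded augmentation.

    Geometric transforms move image and both targets together (bilinear
    image / nearest-neighbor target interpolation, re-binarized at 0.5);
    photometric transforms touch the image only.
    """
    cfg = config or AugmentConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    img = sample.image_tile.astype(np.float64)
    spine = sample.spine_target.astype(np.float64)
    dend = sample.dendrite_target.astype(np.float64)

    if rng.random() < cfg.p_flip:
        axis = int(rng.integers(2))
        img, spine, dend = (np.flip(a, axis=axis) for a in (img, spine, dend))
    if rng.random() < cfg.p_rot90:
        k = int(rng.integers(1, 4))
        img, spine, dend = (np.rot90(a, k) for a in (img, spine, dend))
    if rng.random() < cfg.p_rot_small:
        angle = rng.uniform(-cfg.max_small_angle_deg, cfg.max_small_angle_deg)
        img = _sk_rotate(img, angle, order=1, mode="reflect", preserve_range=True)
        spine = _sk_rotate(spine, angle, order=0, mode="constant",
                           preserve_range=True)
        dend = _sk_rotate(dend, angle, order=0, mode="constant",
                          preserve_range=True)
    if rng.random() < cfg.p_noise:
        img = img + rng.normal(0, cfg.noise_sd, img.shape)
    if rng.random() < cfg.p_brightness:
        img = img + rng.uniform(-cfg.brightness_delta, cfg.brightness_delta)
    if rng.random() < cfg.p_contrast:
        img = img * rng.uniform(*cfg.contrast_range)

    return TrainingSample(
        image_tile=np.clip(np.ascontiguousarray(img), -1.0, 1.0),
        spine_target=(np.ascontiguousarray(spine) > 0.5).astype(np.uint8),
        dendrite_target=(np.ascontiguousarray(dend) > 0.5).astype(np.uint8),
        voxel_size_xy_um=sample.voxel_size_xy_um,
    )


# --------------------------------------------------------------------------
# manifest & streaming
# --------------------------------------------------------------------------

def load_manifest(manifest_path) -> list[dict]:
    """Load a training manifest and its stacks into memory."""
    manifest_path = Path(manifest_path)
    data = yaml.safe_load(manifest_path.read_text())
    root = manifest_path.parent
    loaded = []
    for entry in data["entries"]:
        vs = tuple(entry["voxel_size_um"])
        loaded.append({
            "raw": read_stack(root / entry["raw"], vs),
            "spines": read_stack(root / entry["spines"], vs),
            "dendrites": read_stack(root / entry["dendrites"], vs),
            "voxel_size_um": vs,
        })
    return loaded


def _reflect_pad_to(arr: np.ndarray, size: int) -> np.ndarray:
    py = max(0, size - arr.shape[0])
    px = max(0, size - arr.shape[1])
    if py or px:
        arr = np.pad(arr, ((0, py), (0, px)), mode="reflect")
    return arr


def tile_stream(manifest, config: TrainConfig, seed: Optional[int] = None
                ) -> Iterator[list[TrainingSample]]:
    """Infinite iterator of augmented training batches.

    Sampling is uniform over (stack, plane, window). In fixed resolution
    mode all stacks are first resampled to ``target_xy_um``; in mixed mode
    native resolutions are used. Stacks smaller than the tile are
    reflect-padded.
    """
    entries = load_manifest(manifest) if isinstance(manifest, (str, Path)) else manifest
    if not entries:
        raise ValueError("empty manifest")
    if config.resolution_mode == "fixed":
        prepared = []
        for e in entries:
            raw = rescale_stack(e["raw"], config.target_xy_um)
            spines = rescale_stack(
                ImageStack(e["spines"].voxels.astype(np.float32), e["spines"].voxel_size),
                config.target_xy_um)
            dend = rescale_stack(
                ImageStack(e["dendrites"].voxels.astype(np.float32),
                           e["dendrites"].voxel_size),
                config.target_xy_um)
            prepared.append({
                "raw": raw,
                "spines": ImageStack(spines.voxels > 0.5, spines.voxel_size),
                "dendrites": ImageStack(dend.voxels > 0.5, dend.voxel_size),
                "voxel_size_um": raw.voxel_size,
            })
        entries = prepared

    rng = np.random.default_rng(config.seed if seed is None else seed)
    ts = config.tile_size
    while True:
        batch = []
        for _ in range(config.batch_size):
            e = entries[rng.integers(len(entries))]
            raw = e["raw"].voxels
            k = int(rng.integers(raw.shape[0]))
            img = _reflect_pad_to(raw[k].astype(np.float64), ts)
            spn = _reflect_pad_to(e["spines"].voxels[k].astype(np.float64), ts)
            dnd = _reflect_pad_to(e["dendrites"].voxels[k].astype(np.float64), ts)
            y0 = int(rng.integers(img.shape[0] - ts + 1))
            x0 = int(rng.integers(img.shape[1] - ts + 1))
            sample = TrainingSample(
                image_tile=normalize_intensity(img[y0:y0 + ts, x0:x0 + ts]),
                spine_target=(spn[y0:y0 + ts, x0:x0 + ts] > 0.5).astype(np.uint8),
                dendrite_target=(dnd[y0:y0 + ts, x0:x0 + ts] > 0.5).astype(np.uint8),
                voxel_size_xy_um=float(e["voxel_size_um"][0]),
            )
            batch.append(augment_tile(sample, rng, config.augment))
        yield batch


# --------------------------------------------------------------------------
# schedule & loop
# --------------------------------------------------------------------------

def learning_rate(epoch: int, config: TrainConfig) -> float:
    """Flat lr₀ for the warm epochs, then exponential decay.

    lr(e) = lr₀ for e < warm_epochs, and
    lr(e) = lr₀·exp(−τ·(e − warm_epochs)) afterwards, with τ the decay
    rate per epoch (default 0.1).
    """
    if epoch < config.warm_epochs:
        return config.lr0
    return config.lr0 * float(
        np.exp(-config.decay_time_constant * (epoch - config.warm_epochs)))


def train_model(model: SegmentationModel, manifest, config: TrainConfig,
                out_dir=None) -> tuple[SegmentationModel, list[dict]]:
    """Optimize the model on streamed tiles; returns (model, loss log).

    The dendrite head minimizes the Dice loss and the spine head the mean
    squared error. In ``sum`` mode both losses back-propagate each step
    (unit weights); in ``alternate`` mode steps alternate strictly
    between the two losses. Logs per-epoch mean losses and checkpoints
    the best (lowest combined loss) parameters.
    """
    entries = load_manifest(manifest) if isinstance(manifest, (str, Path)) else manifest
    if not entries:
        raise ValueError("empty manifest")
    if config.steps_per_epoch is None:
        total_tiles = sum(e["raw"].voxels.shape[0] for e in entries)
        steps = max(1, int(np.ceil(total_tiles / config.batch_size)))
    else:
        steps = config.steps_per_epoch

    stream = tile_stream(entries, config)
    opt = Adam(model.parameters(), lr=config.lr0)
    log: list[dict] = []
    best = None
    for epoch in range(config.epochs):
        opt.lr = learning_rate(epoch, config)
        d_losses, s_losses = [], []
        for step in range(steps):
            batch = next(stream)
            x = np.stack([s.image_tile for s in batch])
            yd = np.stack([s.dendrite_target for s in batch])[:, None]
            ys = np.stack([s.spine_target for s in batch])[:, None]
            d_map, s_map = model.forward(x, training=True)
            ld = dice_loss_node(d_map, yd)
            ls = mse_loss_node(s_map, ys)
            if not np.isfinite(ld.data) or not np.isfinite(ls.data):
                raise RuntimeError(
                    f"training diverged at epoch {epoch} step {step}: "
                    f"dendrite loss {ld.data}, spine loss {ls.data}")
            opt.zero_grad()
            if config.loss_mode == "sum":
                from ._nn import Node
                total = Node(ld.data + ls.data, (ld, ls),
                             lambda g: (g, g))
                backward(total)
            else:
                backward(ld if (epoch * steps + step) % 2 == 0 else ls)
            opt.step()
            d_losses.append(float(ld.data))
            s_losses.append(float(ls.data))
        entry = {
            "epoch": epoch,
            "lr": opt.lr,
            "dendrite_loss": float(np.mean(d_losses)),
            "spine_loss": float(np.mean(s_losses)),
        }
        log.append(entry)
        combined = entry["dendrite_loss"] + entry["spine_loss"]
        if best is None or combined < best[0]:
            best = (combined, {k: v.copy() for k, v in model.state_arrays().items()})
    if best is not None:
        model.load_state_arrays(best[1])
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        model.save(out_dir / "model")
        import csv
        with open(out_dir / "losses.csv", "w", newline="") as fh:
            writer = csv.DictWriter(
                fh, fieldnames=["epoch", "lr", "dendrite_loss", "spine_loss"])
            writer.writeheader()
            writer.writerows(log)
    return model, log
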