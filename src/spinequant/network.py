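"""Dual-decoder segmentation network for dendrites and dendritic spines.

The model is a U-Net-style encoder with residual blocks whose deepest
feature map (the latent space) feeds two structurally identical decoders —
one producing a dendrite probability map, one a spine probability map.
Skip connections pass each encoder scale to the matching decoder stage.
Batch normalization precedes every activation; all hidden activations are
swish, the two single-channel output convolutions use the logistic
function so that both maps are probabilities in [0, 1].

The dendrite head is trained with the Dice loss, the spine head with mean
squared error; the two losses are kept separate (summed gradients by
default, strictly alternating updates optionally).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import _nn
from ._nn import BatchNormState, Node, Param


# --------------------------------------------------------------------------
# activations and losses (plain-array reference forms)
# --------------------------------------------------------------------------

def logistic(x):
    """Standard logistic σ(x) = 1 / (1 + e^(−x)), mapping ℝ → (0, 1)."""
    x = np.asarray(x, dtype=np.float64)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out if out.ndim else float(out)


def swish(x):
    """Swish activation x·σ(x)."""
    x = np.asarray(x, dtype=np.float64)
    out = x * logistic(x)
    return out if out.ndim else float(out)


def dice_loss(y, y_hat, eps: float = 1e-7) -> float:
    """Dice loss ``1 − 2·Σŷᵢyᵢ / (Σŷᵢ² + Σyᵢ²)`` ∈ [0, 1].

    0 for perfect overlap, 1 for an empty prediction against a non-empty
    target. ε guards both terms so an empty tile against an empty
    prediction scores 0 (perfect agreement on absence).
    """
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y.shape != y_hat.shape:
        raise ValueError(f"shape mismatch {y.shape} vs {y_hat.shape}")
    num = 2.0 * float((y_hat * y).sum())
    den = float((y_hat ** 2).sum() + (y ** 2).sum())
    return 1.0 - (num + eps) / (den + eps)


def spine_loss(y, y_hat) -> float:
    """Mean squared error over pixels (tile-size invariant reduction)."""
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y.shape != y_hat.shape:
        raise ValueError(f"shape mismatch {y.shape} vs {y_hat.shape}")
    return float(np.mean((y - y_hat) ** 2))


# --------------------------------------------------------------------------
# architecture
# --------------------------------------------------------------------------

@dataclass
class ArchitectureConfig:
    """Capacity and geometry of the network.

    base_filters scales capacity (8/16/32 are the standard variants);
    depth is the number of 2× pooling stages, so tiles must be divisible
    by ``2**depth``. All kernels are 3×3.
    """

    base_filters: int = 8
    depth: int = 4
    tile_size: int = 128
    kernel_size: int = 3

    def __post_init__(self):
        if self.tile_size % (2 ** self.depth) != 0:
            raise ValueError(
                f"tile_size {self.tile_size} not divisible by 2^depth = {2 ** self.depth}"
            )
        if self.base_filters < 1 or self.depth < 1:
            raise ValueError("base_filters and depth must be positive")


class _ConvBNAct:
    """conv 3×3 → batch-norm → swish."""

    def __init__(self, rng, cin, cout, k=3):
        fan_in = cin * k * k
        self.w = Param(rng.normal(0, np.sqrt(2.0 / fan_in), (cout, cin, k, k)))
        self.b = Param(np.zeros(cout))
        self.gamma = Param(np.ones(cout))
        self.beta = Param(np.zeros(cout))
        self.bn = BatchNormState(cout)

    def params(self):
        return [self.w, self.b, self.gamma, self.beta]

    def __call__(self, x: Node, training: bool) -> Node:
        h = _nn.conv2d(x, self.w, self.b)
        h = _nn.batchnorm(h, self.gamma, self.beta, self.bn, training)
        return _nn.swish_op(h)


class _ResidualBlock:
    """Two conv-BN-swish layers with an identity (or 1×1-projected) shortcut."""

    def __init__(self, rng, cin, cout):
        self.c1 = _ConvBNAct(rng, cin, cout)
        self.c2 = _ConvBNAct(rng, cout, cout)
        if cin != cout:
            self.proj_w = Param(rng.normal(0, np.sqrt(2.0 / cin), (cout, cin, 1, 1)))
            self.proj_b = Param(np.zeros(cout))
        else:
            self.proj_w = None
            self.proj_b = None

    def params(self):
        p = self.c1.params() + self.c2.params()
        if self.proj_w is not None:
            p += [self.proj_w, self.proj_b]
        return p

    def __call__(self, x: Node, training: bool) -> Node:
        h = self.c2(self.c1(x, training), training)
        shortcut = x if self.proj_w is None else _nn.conv2d(x, self.proj_w, self.proj_b)
        return _nn.add(h, shortcut)


class _FinalConv:
    """conv 3×3 to one channel with logistic output (no batch norm)."""

    def __init__(self, rng, cin):
        fan_in = cin * 9
        self.w = Param(rng.normal(0, np.sqrt(2.0 / fan_in), (1, cin, 3, 3)))
        self.b = Param(np.zeros(1))

    def params(self):
        return [self.w, self.b]

    def __call__(self, x: Node) -> Node:
        return _nn.sigmoid(_nn.conv2d(x, self.w, self.b))


class SegmentationModel:
    """The dual-decoder network.

    ``forward`` maps a batch of single-channel tiles in [−1, 1] to a pair
    of probability-map nodes (dendrites, spines); ``predict`` is the
    convenience eval-mode wrapper returning plain arrays. The latent
    space is the deepest encoder feature map, shared by both decoders.
    """

    def __init__(self, config: ArchitectureConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        F, D = config.base_filters, config.depth

        self.enc_blocks = []
        cin = 1
        for s in range(D):
            self.enc_blocks.append(_ResidualBlock(rng, cin, F * 2 ** s))
            cin = F * 2 ** s
        self.bottleneck = _ResidualBlock(rng, cin, F * 2 ** D)

        def make_decoder():
            stages = []
            cprev = F * 2 ** D
            for s in reversed(range(D)):
                skip_c = F * 2 ** s
                stages.append(_ConvBNAct(rng, cprev + skip_c, skip_c))
                cprev = skip_c
            return stages

        self.dec_dendrite = make_decoder()
        self.dec_spine = make_decoder()
        self.head_dendrite = _FinalConv(rng, F)
        self.head_spine = _FinalConv(rng, F)

    # -- parameter bookkeeping ------------------------------------------------
    def _groups(self):
        blocks = self.enc_blocks + [self.bottleneck] + self.dec_dendrite + \
            self.dec_spine + [self.head_dendrite, self.head_spine]
        return blocks

    def parameters(self) -> list[Param]:
        out = []
        for b in self._groups():
            out.extend(b.params())
        return out

    def encoder_parameters(self) -> list[Param]:
        out = []
        for b in self.enc_blocks + [self.bottleneck]:
            out.extend(b.params())
        return out

    def decoder_parameters(self, which: str) -> list[Param]:
        blocks = {"dendrite": self.dec_dendrite + [self.head_dendrite],
                  "spine": self.dec_spine + [self.head_spine]}[which]
        out = []
        for b in blocks:
            out.extend(b.params())
        return out

    # -- forward --------------------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> tuple[Node, Node]:
        if x.ndim == 2:
            x = x[None, None]
        elif x.ndim == 3:
            x = x[:, None]
        H, W = x.shape[2], x.shape[3]
        div = 2 ** self.config.depth
        if H % div or W % div:
            raise ValueError(f"tile {H}×{W} not divisible by 2^depth = {div}")
        h = Node(x)
        skips = []
        for block in self.enc_blocks:
            h = block(h, training)
            skips.append(h)
            h = _nn.maxpool2(h)
        latent = self.bottleneck(h, training)

        def run_decoder(stages, head):
            d = latent
            for stage, skip in zip(stages, reversed(skips)):
                d = _nn.upsample2(d)
                d = _nn.concat(d, skip)
                d = stage(d, training)
            return head(d)

        return (run_decoder(self.dec_dendrite, self.head_dendrite),
                run_decoder(self.dec_spine, self.head_spine))

    def predict(self, tiles: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Eval-mode forward: (dendrite_map, spine_map) as plain arrays."""
        dn, sn = self.forward(tiles, training=False)
        squeeze = np.asarray(tiles).ndim == 2
        d, s = dn.data[:, 0], sn.data[:, 0]
        return (d[0], s[0]) if squeeze else (d, s)

    # -- persistence ----------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        arrs = {}
        for i, p in enumerate(self.parameters()):
            arrs[f"param_{i:04d}"] = p.data
        bn_idx = 0
        for b in self._groups():
            for attr in ("c1", "c2"):
                layer = getattr(b, attr, None)
                if layer is not None:
                    arrs[f"bn_mean_{bn_idx:04d}"] = layer.bn.mean
                    arrs[f"bn_var_{bn_idx:04d}"] = layer.bn.var
                    bn_idx += 1
            if isinstance(b, _ConvBNAct):
                arrs[f"bn_mean_{bn_idx:04d}"] = b.bn.mean
                arrs[f"bn_var_{bn_idx:04d}"] = b.bn.var
                bn_idx += 1
        return arrs

    def load_state_arrays(self, arrs: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            p.data = np.array(arrs[f"param_{i:04d}"])
        bn_idx = 0
        for b in self._groups():
            for attr in ("c1", "c2"):
                layer = getattr(b, attr, None)
                if layer is not None:
                    layer.bn.mean = np.array(arrs[f"bn_mean_{bn_idx:04d}"])
                    layer.bn.var = np.array(arrs[f"bn_var_{bn_idx:04d}"])
                    bn_idx += 1
            if isinstance(b, _ConvBNAct):
                b.bn.mean = np.array(arrs[f"bn_mean_{bn_idx:04d}"])
                b.bn.var = np.array(arrs[f"bn_var_{bn_idx:04d}"])
                bn_idx += 1

    def save(self, path) -> None:
        """Write weights (.npz) plus a JSON sidecar with the architecture."""
        path = Path(path)
        np.savez_compressed(path.with_suffix(".npz"), **self.state_arrays())
        path.with_suffix(".json").write_text(json.dumps(asdict(self.config)))

    @classmethod
    def load(cls, path) -> "SegmentationModel":
        path = Path(path)
        config = ArchitectureConfig(**json.loads(path.with_suffix(".json").read_text()))
        model = cls(config)
        with np.load(path.with_suffix(".npz")) as arrs:
            model.load_state_arrays(dict(arrs))
        return model


def build_model(config: ArchitectureConfig, seed: int = 0) -> SegmentationModel:
    """Construct the dual-decoder model with seeded He-normal init."""
    return SegmentationModel(config, seed=seed)


def count_parameters(model: SegmentationModel) -> int:
    """Total trainable parameter count (conv weights, biases, BN affine)."""
    return int(sum(p.data.size for p in model.parameters()))
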