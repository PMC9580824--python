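"""Attention-gated encoder–decoder segmentation network with a soft-edge head.

The backbone is a U-Net: per stage two 3x3 convolutions with instance
normalisation and ReLU, 2x2 max-pool downsampling with channel doubling,
and 2x2 transposed-convolution upsampling.  Skip connections optionally
pass through additive attention gates: the skip feature and the coarser
decoder (gating) feature are projected to a common width, summed, rectified
and squashed to a per-pixel coefficient map ``alpha`` in (0, 1) that
re-weights the skip feature, letting the decoder suppress irrelevant
background regions.

The edge head "at the end of the network" is by default the parameter-free
differentiable Sobel edge magnitude of the predicted probability map (a
learned 3x3 head is available behind ``learned_edge_head``), so the model
emits a (mask probability, soft edge) pair per image.

Backbone, attention-gate and edge-head parameters are drawn from separate
seeded RNG streams, so ablation variants share bit-identical backbone
initialisation for a given seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import nn

__all__ = [
    "NetworkConfig",
    "AttentionGateSpec",
    "AttentionGate",
    "attention_gate",
    "AttentionUNet",
    "build_model",
    "forward",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyper-parameters.

    ``input_size`` is (height, width) and must be divisible by ``2**depth``;
    the 512x256 clinical crop convention corresponds to the default
    (256, 512) with depth 4.
    """

    in_channels: int = 1
    depth: int = 4
    base_channels: int = 64
    use_attention: bool = True
    use_edge_head: bool = True
    learned_edge_head: bool = False
    input_size: tuple[int, int] = (256, 512)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_channels < 1 or self.depth < 1 or self.in_channels < 1:
            raise ValueError("in_channels, depth and base_channels must be >= 1")
        h, w = self.input_size
        f = 2 ** self.depth
        if h % f or w % f:
            raise ValueError(
                f"input size {self.input_size} not divisible by 2^depth = {f}")


@dataclass(frozen=True)
class AttentionGateSpec:
    """Bottleneck width of the additive attention gate."""

    inter_channels: int

    def __post_init__(self) -> None:
        if self.inter_channels < 1:
            raise ValueError("inter_channels must be >= 1")


class AttentionGate:
    """Additive attention gate on a skip connection.

    ``alpha = sigmoid(psi(relu(theta(skip) + phi(gate))))`` computed at the
    gate's (coarser) resolution — ``theta`` is a stride-2 1x1 projection of
    the skip, ``phi`` a 1x1 projection of the gate — then upsampled to the
    skip's resolution and multiplied with the skip feature.
    """

    def __init__(self, skip_channels: int, gate_channels: int,
                 spec: AttentionGateSpec, rng: np.random.Generator):
        f = spec.inter_channels
        self.theta = nn.Conv1x1(skip_channels, f, rng, stride=2)
        self.phi = nn.Conv1x1(gate_channels, f, rng)
        self.relu = nn.ReLU()
        self.psi = nn.Conv1x1(f, 1, rng)
        # open-at-init: alpha starts near 1 so the gated network begins as
        # the plain backbone and learns to suppress regions selectively;
        # gates that start half-closed throttle the skips and slow training
        self.psi.bias.data[...] = 3.0
        self.sig = nn.Sigmoid()
        self.up = nn.UpsampleNearest2()
        self.alpha: np.ndarray | None = None
        self._skip: np.ndarray | None = None

    def params(self) -> list[nn.Param]:
        return self.theta.params() + self.phi.params() + self.psi.params()

    def forward(self, skip: np.ndarray, gate: np.ndarray) -> np.ndarray:
        if skip.shape[1] != 2 * gate.shape[1] or skip.shape[2] != 2 * gate.shape[2]:
            raise ValueError(
                f"gate spatial size {gate.shape[1:3]} must be half of skip {skip.shape[1:3]}")
        q = self.relu.forward(self.theta.forward(skip) + self.phi.forward(gate))
        a_small = self.sig.forward(self.psi.forward(q))
        self.alpha = self.up.forward(a_small)
        self._skip = skip
        return skip * self.alpha

    def backward(self, gy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        g_skip = gy * self.alpha
        g_alpha = (gy * self._skip).sum(axis=-1, keepdims=True)
        gq = self.psi.backward(self.sig.backward(self.up.backward(g_alpha)))
        gq = self.relu.backward(gq)
        g_skip = g_skip + self.theta.backward(gq)
        g_gate = self.phi.backward(gq)
        self._skip = None
        return g_skip, g_gate


def attention_gate(skip: np.ndarray, gate: np.ndarray, spec: AttentionGateSpec,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """Apply a freshly initialised attention gate (functional convenience)."""
    rng = np.random.default_rng(0) if rng is None else rng
    layer = AttentionGate(skip.shape[-1], gate.shape[-1], spec, rng)
    return layer.forward(np.asarray(skip, dtype=nn.DTYPE),
                         np.asarray(gate, dtype=nn.DTYPE))


class _ConvBlock:
    """(Conv3x3 -> InstanceNorm -> ReLU) x 2."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.layers = [nn.Conv2d(cin, cout, rng), nn.InstanceNorm2d(cout), nn.ReLU(),
                       nn.Conv2d(cout, cout, rng), nn.InstanceNorm2d(cout), nn.ReLU()]

    def params(self) -> list[nn.Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, gy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy


class AttentionUNet:
    """U-Net backbone with optional attention gates and soft-edge head."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        root = np.random.default_rng(config.seed)
        backbone_rng, gate_rng, edge_rng = root.spawn(3)

        ch = [config.base_channels * 2 ** i for i in range(config.depth + 1)]
        self.enc = []
        cin = config.in_channels
        for i in range(config.depth):
            self.enc.append(_ConvBlock(cin, ch[i], backbone_rng))
            cin = ch[i]
        self.pools = [nn.MaxPool2() for _ in range(config.depth)]
        self.bottleneck = _ConvBlock(ch[config.depth - 1], ch[config.depth], backbone_rng)
        self.ups = []
        self.dec = []
        for i in reversed(range(config.depth)):
            self.ups.append(nn.ConvTranspose2x2(ch[i + 1], ch[i], backbone_rng))
            self.dec.append(_ConvBlock(2 * ch[i], ch[i], backbone_rng))
        self.head = nn.Conv1x1(ch[0], 1, backbone_rng)
        # sign-balanced head init: the head reads nonnegative post-ReLU
        # features, so a random draw with all weights of one sign pins the
        # initial logit to one side of 0 and stalls narrow models.  Keep the
        # drawn magnitudes, alternate the signs.
        w = self.head.weight.data
        w[...] = np.abs(w) * np.where(np.arange(w.shape[1]) % 2 == 0, 1.0, -1.0)

        self.gates: list[AttentionGate] | None = None
        if config.use_attention:
            self.gates = []
            for i in reversed(range(config.depth)):
                spec = AttentionGateSpec(inter_channels=max(ch[i] // 2, 1))
                self.gates.append(AttentionGate(ch[i], ch[i + 1], spec, gate_rng))

        self.edge_layer = nn.SobelEdgeMagnitude()
        self.edge_conv = None
        self.edge_sig = None
        if config.learned_edge_head:
            self.edge_conv = nn.Conv2d(1, 1, edge_rng)
            self.edge_sig = nn.Sigmoid()

        self._prob: np.ndarray | None = None
        self._skip_shapes: list[tuple[int, ...]] | None = None

    # -- parameters -------------------------------------------------------
    def params(self) -> list[nn.Param]:
        out: list[nn.Param] = []
        for block in self.enc:
            out += block.params()
        out += self.bottleneck.params()
        for up, dec in zip(self.ups, self.dec):
            out += up.params() + dec.params()
        out += self.head.params()
        if self.gates is not None:
            for g in self.gates:
                out += g.params()
        if self.edge_conv is not None:
            out += self.edge_conv.params()
        return out

    def backbone_params(self) -> list[nn.Param]:
        out: list[nn.Param] = []
        for block in self.enc:
            out += block.params()
        out += self.bottleneck.params()
        for up, dec in zip(self.ups, self.dec):
            out += up.params() + dec.params()
        out += self.head.params()
        return out

    # -- forward / backward ----------------------------------------------
    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=nn.DTYPE)
        if x.ndim == 3:
            x = x[..., None]
        if x.ndim != 4 or x.shape[-1] != self.config.in_channels:
            raise ValueError(
                f"expected (N, H, W, {self.config.in_channels}) input, got {x.shape}")
        f = 2 ** self.config.depth
        if x.shape[1] % f or x.shape[2] % f:
            raise ValueError(
                f"input spatial size {x.shape[1:3]} not divisible by 2^depth = {f}")
        return x

    def forward_logits(self, x: np.ndarray) -> np.ndarray:
        """Forward pass to 1-channel mask logits, caching for backward."""
        x = self._check_input(x)
        skips = []
        for block, pool in zip(self.enc, self.pools):
            s = block.forward(x)
            skips.append(s)
            x = pool.forward(s)
        x = self.bottleneck.forward(x)
        for j, (up, dec) in enumerate(zip(self.ups, self.dec)):
            skip = skips[-1 - j]
            if self.gates is not None:
                skip = self.gates[j].forward(skip, x)
            u = up.forward(x)
            x = dec.forward(np.concatenate([u, skip], axis=-1))
        self._skip_shapes = [s.shape for s in skips]
        return self.head.forward(x)

    def backward(self, g_logits: np.ndarray) -> None:
        """Accumulate parameter gradients from a logits gradient."""
        gx = self.head.backward(g_logits)
        g_skips: list[np.ndarray | None] = [None] * self.config.depth
        for j in reversed(range(self.config.depth)):
            cat = self.dec[j].backward(gx)
            c_up = self.ups[j].weight.data.shape[1]
            g_u, g_skip = cat[..., :c_up], cat[..., c_up:]
            gx = self.ups[j].backward(g_u)
            if self.gates is not None:
                g_skip, g_gate = self.gates[j].backward(g_skip)
                gx = gx + g_gate
            g_skips[self.config.depth - 1 - j] = g_skip
        gx = self.bottleneck.backward(gx)
        for i in reversed(range(self.config.depth)):
            gs = self.pools[i].backward(gx) + (g_skips[i] if g_skips[i] is not None else 0.0)
            gx = self.enc[i].backward(gs)

    def forward(self, batch: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Inference: (mask probabilities, soft edge maps), shapes (N, H, W)."""
        z = self.forward_logits(batch)
        prob = nn.sigmoid(z)
        edge = self.edge_head(prob)
        return prob[..., 0], edge[..., 0]

    def edge_head(self, prob: np.ndarray) -> np.ndarray:
        """Edge branch applied to a (N, H, W, 1) probability map."""
        if not self.config.use_edge_head:
            return np.zeros_like(prob)
        if self.edge_conv is not None:
            return self.edge_sig.forward(self.edge_conv.forward(prob))
        return self.edge_layer.forward(prob)

    def edge_head_backward(self, g_edge: np.ndarray) -> np.ndarray:
        if self.edge_conv is not None:
            return self.edge_conv.backward(self.edge_sig.backward(g_edge))
        return self.edge_layer.backward(g_edge)


def build_model(config: NetworkConfig) -> AttentionUNet:
    """Construct a deterministically initialised model from a config."""
    return AttentionUNet(config)


def forward(model: AttentionUNet, batch: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Run a batch of grayscale images; returns (mask_prob, edge_soft)."""
    return model.forward(batch)


# -- checkpointing ---------------------------------------------------------

def save_checkpoint(model: AttentionUNet, path, extra: dict | None = None) -> None:
    """Save parameters + config (+ optional metadata) to an ``.npz`` file."""
    cfg = asdict(model.config)
    cfg["input_size"] = list(cfg["input_size"])
    meta = {"config": cfg, "extra": extra or {}}
    arrays = {f"p{i}": p.data for i, p in enumerate(model.params())}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path) -> tuple[AttentionUNet, dict]:
    """Rebuild a model from a checkpoint; returns (model, extra metadata)."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        cfg = meta["config"]
        cfg["input_size"] = tuple(cfg["input_size"])
        model = AttentionUNet(NetworkConfig(**cfg))
        params = model.params()
        for i, p in enumerate(params):
            arr = data[f"p{i}"]
            if arr.shape != p.data.shape:
                raise ValueError("checkpoint incompatible with reconstructed config")
            p.data[...] = arr
    return model, meta["extra"]
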