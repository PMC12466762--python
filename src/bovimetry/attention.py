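"""Shape-preserving attention operators for keypoint-detection backbones.

Three feature-map operators used to strengthen a lightweight pose detector,
implemented as pure-numpy forward passes over B x C x H x W arrays so they
can be exercised and unit-tested without any training machinery:

* SimAM — parameter-free saliency gating: each pixel's closed-form energy is
  computed per channel from that channel's mean and variance, and low-energy
  (more discriminative) pixels get higher weights through a sigmoid;
* Coordinate attention — pools the feature map separately along height and
  width, producing two directional gates that encode positional dependencies;
* CASimAM — SimAM followed by coordinate attention (pixel saliency first,
  spatial structure second);
* MHSA — multi-head self-attention over the flattened spatial positions,
  for global dependencies between distant landmarks;
* DRAMiTransformer — a spatial-attention branch and a channel-attention
  branch computed in parallel, fused by a learned mixing gate, followed by a
  feed-forward network with residual connections.

Blocks with learned parameters hold seeded numpy weight arrays; ``seed``
controls initialization only, every forward pass is deterministic.  Stated
insertion points into a YOLO-style detector are exported by
:func:`insertion_configs`: CASimAM in the backbone, DRAMiTransformer at the
P3 head branch (layer 15, after the C2f block), MHSA-C2f before the
detection head.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BlockConfig",
    "SimAM",
    "CoordAttention",
    "CASimAM",
    "MHSA",
    "DRAMiTransformer",
    "simam_forward",
    "coord_attention_forward",
    "casimam_forward",
    "mhsa_forward",
    "dramit_forward",
    "insertion_configs",
]

INSERTION_POINTS = ("backbone", "p3_head_layer15", "pre_detect_head")


@dataclass(frozen=True)
class BlockConfig:
    channels: int = 64
    num_heads: int = 4
    lam: float = 1e-4
    insertion_point: str = "backbone"
    reduction: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.channels % self.num_heads:
            raise ValueError(
                f"channels ({self.channels}) must be divisible by num_heads ({self.num_heads})"
            )
        if self.lam <= 0:
            raise ValueError(f"lambda must be positive, got {self.lam}")
        if self.insertion_point not in INSERTION_POINTS:
            raise ValueError(f"insertion_point must be one of {INSERTION_POINTS}")


def _check_input(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 4 or min(x.shape) < 1:
        raise ValueError(f"feature map must be B x C x H x W, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("feature map contains non-finite values")
    return x


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


def _softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class _Block:
    """Minimal parameter container so tests can take a parameter census."""

    def parameters(self) -> list[np.ndarray]:
        return [v for v in vars(self).values() if isinstance(v, np.ndarray)]

    def parameter_count(self) -> int:
        return int(sum(p.size for p in self.parameters()))


# ---------------------------------------------------------------------------
# SimAM


def simam_forward(x, lam: float = 1e-4) -> np.ndarray:
    """Parameter-free saliency gating from the per-channel energy function.

    For pixel value t in a channel with mean mu and (biased, n = HW - 1)
    variance v, the inverse minimal energy is (t - mu)^2 / (4 (v + lam)) + 1/2
    and the output is x * sigmoid(1/E).  A constant channel has equal energy
    everywhere, so its gate is uniform and the output proportional to the
    input.
    """
    x = _check_input(x)
    if lam <= 0:
        raise ValueError(f"lambda must be positive, got {lam}")
    B, C, H, W = x.shape
    if H * W < 2:
        raise ValueError("SimAM needs at least 2 spatial positions per channel")
    n = H * W - 1
    mu = x.mean(axis=(2, 3), keepdims=True)
    sq = (x - mu) ** 2
    var = sq.sum(axis=(2, 3), keepdims=True) / n
    inv_energy = sq / (4.0 * (var + lam)) + 0.5
    return x * _sigmoid(inv_energy)


class SimAM(_Block):
    """SimAM as a block object; holds zero parameters by construction."""

    def __init__(self, lam: float = 1e-4) -> None:
        if lam <= 0:
            raise ValueError(f"lambda must be positive, got {lam}")
        self.lam = lam

    def forward(self, x) -> np.ndarray:
        return simam_forward(x, self.lam)


# ---------------------------------------------------------------------------
# Coordinate attention


class CoordAttention(_Block):
    """Directional gating from height- and width-pooled descriptors.

    The map is average-pooled along W (an H-profile) and along H (a
    W-profile); the two profiles pass through a shared channel-reduction
    projection and per-direction expansions, and the resulting sigmoid gates
    multiply the input along their respective axes.
    """

    def __init__(self, channels: int, reduction: int = 8, seed: int = 0) -> None:
        if reduction > channels:
            raise ValueError(f"reduction ({reduction}) exceeds channels ({channels})")
        mid = max(1, channels // reduction)
        rng = np.random.default_rng(seed)
        scale = 1.0 / np.sqrt(channels)
        self.w_reduce = rng.normal(0.0, scale, (channels, mid))
        self.b_reduce = np.zeros(mid)
        self.w_h = rng.normal(0.0, scale, (mid, channels))
        self.b_h = np.zeros(channels)
        self.w_w = rng.normal(0.0, scale, (mid, channels))
        self.b_w = np.zeros(channels)

    def forward(self, x) -> np.ndarray:
        x = _check_input(x)
        pool_h = x.mean(axis=3)                      # (B, C, H)
        pool_w = x.mean(axis=2)                      # (B, C, W)
        joint = np.concatenate([pool_h, pool_w], axis=2)   # (B, C, H+W)
        mid = np.maximum(np.einsum("bcl,cm->bml", joint, self.w_reduce)
                         + self.b_reduce[None, :, None], 0.0)
        H = x.shape[2]
        gate_h = _sigmoid(np.einsum("bml,mc->bcl", mid[:, :, :H], self.w_h)
                          + self.b_h[None, :, None])       # (B, C, H)
        gate_w = _sigmoid(np.einsum("bml,mc->bcl", mid[:, :, H:], self.w_w)
                          + self.b_w[None, :, None])       # (B, C, W)
        return x * gate_h[:, :, :, None] * gate_w[:, :, None, :]


def coord_attention_forward(x, reduction: int = 8, seed: int = 0) -> np.ndarray:
    x = _check_input(x)
    return CoordAttention(x.shape[1], reduction=reduction, seed=seed).forward(x)


class CASimAM(_Block):
    """Pixel saliency first (SimAM), spatial structure second (coordinate attention)."""

    def __init__(self, config: BlockConfig) -> None:
        self.config = config
        self.simam = SimAM(config.lam)
        self.coord = CoordAttention(config.channels, reduction=config.reduction,
                                    seed=config.seed)

    def parameters(self) -> list[np.ndarray]:
        return self.simam.parameters() + self.coord.parameters()

    def forward(self, x) -> np.ndarray:
        return self.coord.forward(self.simam.forward(x))


def casimam_forward(x, config: BlockConfig | None = None) -> np.ndarray:
    x = _check_input(x)
    config = config or BlockConfig(channels=x.shape[1])
    return CASimAM(config).forward(x)


# ---------------------------------------------------------------------------
# Multi-head self-attention


class MHSA(_Block):
    """Scaled dot-product self-attention over flattened spatial positions.

    Independent linear projections produce Q, K and V; each head attends over
    all positions (rows of the attention matrix sum to 1), the head outputs
    are concatenated and fused by a final linear projection.
    """

    def __init__(self, channels: int, num_heads: int = 4, seed: int = 0) -> None:
        if channels % num_heads:
            raise ValueError(
                f"channels ({channels}) must be divisible by num_heads ({num_heads})"
            )
        self.num_heads = num_heads
        rng = np.random.default_rng(seed)
        scale = 1.0 / np.sqrt(channels)
        self.w_q = rng.normal(0.0, scale, (channels, channels))
        self.w_k = rng.normal(0.0, scale, (channels, channels))
        self.w_v = rng.normal(0.0, scale, (channels, channels))
        self.w_o = rng.normal(0.0, scale, (channels, channels))

    def forward(self, x, return_weights: bool = False):
        x = _check_input(x)
        B, C, H, W = x.shape
        nh, dh = self.num_heads, C // self.num_heads
        seq = x.reshape(B, C, H * W).transpose(0, 2, 1)          # (B, L, C)
        q = (seq @ self.w_q).reshape(B, -1, nh, dh).transpose(0, 2, 1, 3)
        k = (seq @ self.w_k).reshape(B, -1, nh, dh).transpose(0, 2, 1, 3)
        v = (seq @ self.w_v).reshape(B, -1, nh, dh).transpose(0, 2, 1, 3)
        attn = _softmax(q @ k.transpose(0, 1, 3, 2) / np.sqrt(dh), axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(B, -1, C) @ self.w_o
        out = out.transpose(0, 2, 1).reshape(B, C, H, W)
        return (out, attn) if return_weights else out


def mhsa_forward(x, num_heads: int = 4, seed: int = 0, return_weights: bool = False):
    x = _check_input(x)
    return MHSA(x.shape[1], num_heads=num_heads, seed=seed).forward(
        x, return_weights=return_weights)


# ---------------------------------------------------------------------------
# DRAMiTransformer


class DRAMiTransformer(_Block):
    """Parallel spatial and channel attention branches with a gated mix and FFN.

    The spatial branch runs reciprocal (shared query/key projection, hence
    symmetric) attention over the flattened positions; the channel branch
    attends across channels, treating each channel's spatial response as its
    token.  A learned scalar gate mixes the branches, the mix is added back
    to the input, and a two-layer feed-forward network with residual closes
    the block.  Setting ``mix_logit`` to a large positive (negative) value
    forces the spatial (channel) branch.
    """

    def __init__(self, config: BlockConfig) -> None:
        self.config = config
        C = config.channels
        rng = np.random.default_rng(config.seed)
        scale = 1.0 / np.sqrt(C)
        self.w_qk = rng.normal(0.0, scale, (C, C))      # shared => reciprocal attention
        self.w_v_sp = rng.normal(0.0, scale, (C, C))
        self.w_v_ch = rng.normal(0.0, scale, (C, C))
        self.mix_logit = np.zeros(1)
        hidden = 2 * C
        self.w_ffn1 = rng.normal(0.0, scale, (C, hidden))
        self.b_ffn1 = np.zeros(hidden)
        self.w_ffn2 = rng.normal(0.0, 1.0 / np.sqrt(hidden), (hidden, C))
        self.b_ffn2 = np.zeros(C)

    def _spatial_branch(self, seq: np.ndarray) -> np.ndarray:
        qk = seq @ self.w_qk                            # (B, L, C)
        attn = _softmax(qk @ qk.transpose(0, 2, 1) / np.sqrt(seq.shape[2]), axis=-1)
        return attn @ (seq @ self.w_v_sp)

    def _channel_branch(self, seq: np.ndarray) -> np.ndarray:
        ch = seq.transpose(0, 2, 1)                     # (B, C, L): channels as tokens
        attn = _softmax(ch @ ch.transpose(0, 2, 1) / np.sqrt(ch.shape[2]), axis=-1)
        return (attn @ (seq @ self.w_v_ch).transpose(0, 2, 1)).transpose(0, 2, 1)

    def _ffn(self, seq: np.ndarray) -> np.ndarray:
        h = np.maximum(seq @ self.w_ffn1 + self.b_ffn1, 0.0)
        return h @ self.w_ffn2 + self.b_ffn2

    def forward(self, x) -> np.ndarray:
        x = _check_input(x)
        B, C, H, W = x.shape
        seq = x.reshape(B, C, H * W).transpose(0, 2, 1)
        g = _sigmoid(self.mix_logit)[0]
        mixed = g * self._spatial_branch(seq) + (1.0 - g) * self._channel_branch(seq)
        y = seq + mixed
        y = y + self._ffn(y)
        return y.transpose(0, 2, 1).reshape(B, C, H, W)


def dramit_forward(x, config: BlockConfig | None = None) -> np.ndarray:
    x = _check_input(x)
    config = config or BlockConfig(channels=x.shape[1], insertion_point="p3_head_layer15")
    return DRAMiTransformer(config).forward(x)


# ---------------------------------------------------------------------------
# Insertion-point export


def insertion_configs(channels: int = 64, num_heads: int = 4) -> dict:
    """Block placement descriptors consumable by a detector-framework model file.

    The three operators slot into a YOLO-style pose network at: the backbone
    (CASimAM), the P3 high-resolution head branch immediately after its C2f
    block at layer 15 (DRAMiTransformer), and right before the detection head
    (MHSA combined with C2f).
    """
    return {
        "casimam": {"block": "CASimAM", "insertion_point": "backbone",
                    "channels": channels, "lambda": 1e-4},
        "dramitransformer": {"block": "DRAMiTransformer",
                             "insertion_point": "p3_head_layer15",
                             "after": "C2f", "layer_index": 15, "channels": channels},
        "mhsa_c2f": {"block": "MHSA", "wrapped_in": "C2f",
                     "insertion_point": "pre_detect_head",
                     "channels": channels, "num_heads": num_heads},
    }


def export_insertion_yaml(path, channels: int = 64, num_heads: int = 4) -> None:
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(insertion_configs(channels, num_heads), fh, sort_keys=True)
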