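"""The translation-equivariant network and its deterministic read-out head.

The network is fully convolutional: three 3x3 conv layers (ReLU), one 2x2
max-pool, eight more 3x3 conv layers (ReLU), and a final 1x1 linear layer
with ``3 + extras`` output channels.  The stride of the whole network is the
pooling factor ``k`` (2), so a ``N x M`` input yields ``N/k x M/k`` feature
maps.  Channels are ordered ``[dx, dy, *extras, rho]``.

The head turns the raw planes into position maps

    x_ij = dx_ij + i*k - N/2,      y_ij = dy_ij + j*k - M/2,

(center-relative; a companion accessor shifts to the top-left convention),
a weight map ``w = sigmoid(rho)`` normalized to sum to one, and the globally
pooled weighted-average prediction.  ``N`` and ``M`` are the *input*
dimensions, so ``i*k`` spans the input grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Conv2d, MaxPool2, ReLU, Sequential

__all__ = [
    "NetworkConfig",
    "FeatureMapStack",
    "PooledPrediction",
    "build_network",
    "forward",
    "position_maps",
    "eval_weights",
    "train_weights",
    "pooled_prediction",
]


@dataclass(frozen=True)
class NetworkConfig:
    in_channels: int = 1
    channels: int = 32
    kernel: int = 3
    pre_pool_layers: int = 3
    post_pool_layers: int = 8
    pool: int = 2
    extra_channels: int = 0

    def __post_init__(self) -> None:
        if self.pool != 2:
            raise ValueError("only a single 2x2 pooling stage is supported")
        if self.extra_channels not in (0, 1, 2):
            raise ValueError("extra_channels must be 0, 1 or 2")

    @property
    def out_channels(self) -> int:
        return 3 + self.extra_channels

    @property
    def stride(self) -> int:
        return self.pool


def build_network(cfg: NetworkConfig, rng: np.random.Generator) -> Sequential:
    """Build the network with seeded He-uniform initial weights."""
    layers = []
    c = cfg.in_channels
    for _ in range(cfg.pre_pool_layers):
        layers += [Conv2d(c, cfg.channels, cfg.kernel, rng), ReLU()]
        c = cfg.channels
    layers.append(MaxPool2())
    for _ in range(cfg.post_pool_layers):
        layers += [Conv2d(c, cfg.channels, cfg.kernel, rng), ReLU()]
    layers.append(Conv2d(cfg.channels, cfg.out_channels, 1, rng))
    return Sequential(layers)


@dataclass
class FeatureMapStack:
    """Raw network output planes plus the input geometry they refer to.

    ``raw`` has shape ``(N/k, M/k, 3+extras)`` with channel order
    ``[dx, dy, *extras, rho]``; ``input_shape`` is the ``(N, M)`` of the image
    that produced it and ``stride`` is ``k``.
    """

    raw: np.ndarray
    input_shape: tuple[int, int]
    stride: int = 2

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.raw)):
            raise ValueError("feature maps contain non-finite values")
        n, m = self.input_shape
        if self.raw.shape[:2] != (n // self.stride, m // self.stride):
            raise ValueError("feature-map size does not match input/stride")

    @property
    def delta_x(self) -> np.ndarray:
        return self.raw[..., 0]

    @property
    def delta_y(self) -> np.ndarray:
        return self.raw[..., 1]

    @property
    def rho(self) -> np.ndarray:
        return self.raw[..., -1]

    @property
    def extras(self) -> np.ndarray:
        return self.raw[..., 2:-1]

    @property
    def n_extras(self) -> int:
        return self.raw.shape[-1] - 3


@dataclass
class PooledPrediction:
    """Globally pooled prediction: position in px (top-left convention),
    optional extra channels, and the total (pre-normalization) weight mass."""

    x: float
    y: float
    extras: np.ndarray = field(default_factory=lambda: np.zeros(0))
    weight_mass: float = 1.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y) and np.all(np.isfinite(self.extras))):
            raise ValueError("prediction is not finite")
        if self.weight_mass <= 0:
            raise ValueError("weight mass must be positive")


def forward(network: Sequential, image: np.ndarray, stride: int = 2) -> FeatureMapStack:
    """Run one image (``(N, M)`` or ``(N, M, C_in)``) through the network."""
    img = np.asarray(image, dtype=np.float32)
    if img.ndim == 2:
        img = img[..., None]
    n, m = img.shape[:2]
    if n % stride or m % stride:
        raise ValueError(f"input dimensions must be divisible by the stride {stride}; pad the image first")
    out = network.forward(img[None], train=False)[0]
    return FeatureMapStack(out.astype(np.float64), (n, m), stride)


def position_maps(stack: FeatureMapStack, convention: str = "center") -> tuple[np.ndarray, np.ndarray]:
    """Decode the position maps from the delta planes.

    ``convention='center'`` gives positions relative to the image center
    (the ``i*k - N/2`` form); ``'top-left'`` shifts by ``(N/2, M/2)`` so
    positions are measured from the top-left pixel center.
    """
    n, m = stack.input_shape
    k = stack.stride
    i = np.arange(stack.raw.shape[0], dtype=float)[:, None] * k
    j = np.arange(stack.raw.shape[1], dtype=float)[None, :] * k
    x = stack.delta_x + i - n / 2.0
    y = stack.delta_y + j - m / 2.0
    if convention == "top-left":
        return x + n / 2.0, y + m / 2.0
    if convention != "center":
        raise ValueError("convention must be 'center' or 'top-left'")
    return x, y


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def eval_weights(rho: np.ndarray, border_margin: int = 0) -> np.ndarray:
    """Evaluation-time weight map: elementwise sigmoid, normalized to sum 1.

    ``border_margin`` zeroes a strip of feature pixels at each edge before
    normalizing.  Zero-padded convolutions produce border artifacts there;
    the pooled-average derivation assumes the weight map vanishes at the
    edges, and masking enforces that assumption.
    """
    s = _sigmoid(np.asarray(rho, dtype=float))
    if border_margin > 0:
        mask = np.zeros_like(s)
        mask[border_margin:-border_margin, border_margin:-border_margin] = 1.0
        s = s * mask
    total = s.sum()
    if total <= 0:
        raise ValueError("degenerate weight map: sigmoid mass is zero")
    return s / total


def train_weights(
    rho: np.ndarray,
    rng: np.random.Generator,
    dropout_rate: float = 0.01,
    eps: float = 1e-6,
) -> np.ndarray:
    """Training-time weight map with dropout and an epsilon floor.

    ``w = (eps + D[S(rho)]) / (M*N*eps + sum D[S(rho)])`` where ``D`` masks
    each element with probability ``dropout_rate``.  The map sums to one and
    every entry is strictly positive.
    """
    s = _sigmoid(np.asarray(rho, dtype=float))
    if dropout_rate > 0:
        s = s * (rng.random(s.shape) >= dropout_rate)
    num = eps + s
    return num / num.sum()


def pooled_prediction(
    stack: FeatureMapStack,
    mode: str = "eval",
    rng: np.random.Generator | None = None,
    weights: np.ndarray | None = None,
    border_margin: int = 0,
) -> PooledPrediction:
    """Weighted global average of the decoded channels (top-left convention)."""
    if weights is None:
        if mode == "eval":
            weights = eval_weights(stack.rho, border_margin)
        elif mode == "train":
            if rng is None:
                raise ValueError("train mode requires an rng for dropout")
            weights = train_weights(stack.rho, rng)
        else:
            raise ValueError("mode must be 'eval' or 'train'")
    total = weights.sum()
    if total <= 0:
        raise ValueError("zero total weight")
    w = weights / total
    x, y = position_maps(stack, convention="top-left")
    extras = np.array([(stack.extras[..., e] * w).sum() for e in range(stack.n_extras)])
    mass = float(_sigmoid(stack.rho).sum())
    return PooledPrediction(float((x * w).sum()), float((y * w).sum()), extras, mass)
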