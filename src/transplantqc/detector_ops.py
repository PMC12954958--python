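"""Forward-pass implementations of two custom convolution operators.

These are the building blocks of the seedling detector's architecture,
implemented as pure NumPy forward passes (no training, no autograd):

* **dynamic convolution** — a convolution whose effective kernel is an
  input-conditioned convex mixture of M kernels, Y = Σᵢ αᵢ (Wᵢ * X), with
  α = softmax(MLP(GlobalAvgPool(X))).
* **pinwheel-shaped convolution** — four directional 3-extent kernels
  (1×3 / 3×1), each fed an asymmetrically padded copy of the input so the
  arms extend in four different directions, concatenated and fused by a
  2×2 convolution.  The union receptive field of one fused output position
  covers 25 input positions versus 9 for a standard 3×3 convolution.

An impulse-response analyzer (:func:`receptive_footprint`) measures such
receptive fields empirically, which is also how the kernel-to-padding
pairing was disambiguated: each 3-extent kernel must be oriented along the
axis its padding extends by 3 pixels, otherwise the four branch outputs do
not even share a spatial shape.

Convolution here means cross-correlation ('valid'), the deep-learning
convention.  Batch norm is exposed with identity statistics by default so
the operators are analyzable as linear maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, FrozenSet, List, Sequence, Tuple

import numpy as np
from scipy.signal import correlate2d

__all__ = [
    "DynamicConvSpec",
    "PinwheelSpec",
    "Footprint",
    "dynamic_conv_forward",
    "dynamic_conv_forward_mixed",
    "pinwheel_forward",
    "receptive_footprint",
    "standard_conv_footprint",
    "pinwheel_footprint",
]

# (left, right, top, bottom) paddings, in the printed branch order
PINWHEEL_PADDINGS: Tuple[Tuple[int, int, int, int], ...] = (
    (1, 0, 0, 3),
    (0, 3, 0, 1),
    (0, 1, 3, 0),
    (3, 0, 1, 0),
)
# kernel (kh, kw) per branch: the 3-extent axis follows the padded axis
PINWHEEL_KERNEL_SHAPES: Tuple[Tuple[int, int], ...] = ((3, 1), (1, 3), (3, 1), (1, 3))


def _silu(x: np.ndarray) -> np.ndarray:
    return x / (1.0 + np.exp(-x))


def _identity(x: np.ndarray) -> np.ndarray:
    return x


def conv2d(X: np.ndarray, W: np.ndarray, stride: int = 1) -> np.ndarray:
    """Multi-channel 'valid' cross-correlation.

    X: (c_in, h, w); W: (c_out, c_in, kh, kw) → (c_out, h', w').
    """
    c_out, c_in, kh, kw = W.shape
    if X.shape[0] != c_in:
        raise ValueError(f"input has {X.shape[0]} channels, kernel expects {c_in}")
    h, w = X.shape[1:]
    if h < kh or w < kw:
        raise ValueError(f"input {h}x{w} smaller than kernel {kh}x{kw}")
    out = np.empty((c_out, h - kh + 1, w - kw + 1), dtype=float)
    for o in range(c_out):
        acc = np.zeros((h - kh + 1, w - kw + 1))
        for c in range(c_in):
            acc += correlate2d(X[c], W[o, c], mode="valid")
        out[o] = acc
    if stride > 1:
        out = out[:, ::stride, ::stride]
    return out


def _pad(X: np.ndarray, lrtb: Tuple[int, int, int, int]) -> np.ndarray:
    left, right, top, bottom = lrtb
    return np.pad(X, ((0, 0), (top, bottom), (left, right)))


# --------------------------------------------------------------------------
# dynamic convolution


@dataclass
class DynamicConvSpec:
    """M candidate kernels plus the gating MLP that mixes them.

    ``kernels`` is (M, c_out, c_in, kh, kw).  The gate pools the input
    globally, passes it through a two-layer perceptron (hidden width
    ``max(1, c_in // 4)`` by default, ReLU in between) and a softmax,
    producing one convex coefficient per kernel.
    """

    kernels: np.ndarray
    w1: np.ndarray  # (hidden, c_in)
    b1: np.ndarray  # (hidden,)
    w2: np.ndarray  # (M, hidden)
    b2: np.ndarray  # (M,)

    def __post_init__(self) -> None:
        if self.kernels.ndim != 5:
            raise ValueError("kernels must be (M, c_out, c_in, kh, kw)")
        M = self.kernels.shape[0]
        if M < 1:
            raise ValueError("need at least one kernel")
        if self.w2.shape[0] != M:
            raise ValueError("gate output width must equal M")
        if self.w1.shape[1] != self.kernels.shape[2]:
            raise ValueError("gate input width must equal in-channels")

    @property
    def n_kernels(self) -> int:
        return self.kernels.shape[0]

    @classmethod
    def random(
        cls,
        c_in: int,
        c_out: int,
        k: int = 3,
        M: int = 4,
        rng: np.random.Generator | None = None,
        mlp_hidden: int | None = None,
    ) -> "DynamicConvSpec":
        rng = rng or np.random.default_rng(0)
        hidden = mlp_hidden if mlp_hidden is not None else max(1, c_in // 4)
        return cls(
            kernels=rng.standard_normal((M, c_out, c_in, k, k)),
            w1=rng.standard_normal((hidden, c_in)),
            b1=rng.standard_normal(hidden),
            w2=rng.standard_normal((M, hidden)),
            b2=rng.standard_normal(M),
        )


def dynamic_coefficients(X: np.ndarray, spec: DynamicConvSpec) -> np.ndarray:
    """Gate coefficients α = softmax(MLP(GlobalAvgPool(X))); α ≥ 0, Σα = 1."""
    if X.shape[0] != spec.kernels.shape[2]:
        raise ValueError(
            f"input has {X.shape[0]} channels, kernels expect {spec.kernels.shape[2]}"
        )
    pooled = X.mean(axis=(1, 2))
    hidden = np.maximum(spec.w1 @ pooled + spec.b1, 0.0)
    logits = spec.w2 @ hidden + spec.b2
    logits = logits - logits.max()
    e = np.exp(logits)
    return e / e.sum()


def dynamic_conv_forward(X: np.ndarray, spec: DynamicConvSpec) -> np.ndarray:
    """Sum-of-convolutions form: Y = Σᵢ αᵢ (Wᵢ * X)."""
    alpha = dynamic_coefficients(X, spec)
    out = None
    for a, W in zip(alpha, spec.kernels):
        y = a * conv2d(X, W)
        out = y if out is None else out + y
    return out


def dynamic_conv_forward_mixed(X: np.ndarray, spec: DynamicConvSpec) -> np.ndarray:
    """Mixed-kernel form: convolve once with Σᵢ αᵢ Wᵢ (equivalent by linearity)."""
    alpha = dynamic_coefficients(X, spec)
    W_mix = np.tensordot(alpha, spec.kernels, axes=1)
    return conv2d(X, W_mix)


# --------------------------------------------------------------------------
# pinwheel-shaped convolution


@dataclass
class BatchNormParams:
    """Per-channel normalization y = γ·(x − μ)/√(σ² + ε) + β."""

    mean: np.ndarray
    var: np.ndarray
    gamma: np.ndarray
    beta: np.ndarray
    eps: float = 1e-5

    @classmethod
    def identity(cls, channels: int, eps: float = 0.0) -> "BatchNormParams":
        return cls(
            mean=np.zeros(channels),
            var=np.ones(channels),
            gamma=np.ones(channels),
            beta=np.zeros(channels),
            eps=eps,
        )

    def __call__(self, x: np.ndarray) -> np.ndarray:
        scale = self.gamma / np.sqrt(self.var + self.eps)
        shift = self.beta - self.mean * scale
        return x * scale[:, None, None] + shift[:, None, None]


@dataclass
class PinwheelSpec:
    """Four directional branches plus a 2×2 fusion convolution.

    ``branch_kernels`` holds four weight tensors of shape
    (c′, c_in, kh, kw) with (kh, kw) following
    :data:`PINWHEEL_KERNEL_SHAPES`; ``fusion_kernel`` has shape
    (c2, 4·c′, 2, 2) with c′ = c2/4.  ``branch_stride`` defaults to 2
    (the block replaces downsampling convolutions in the detector
    backbone); use stride 1 for receptive-field analysis.  No bias terms —
    they are absorbed by batch norm.
    """

    branch_kernels: Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]
    fusion_kernel: np.ndarray
    branch_stride: int = 2
    branch_bn: List[BatchNormParams] | None = None
    fusion_bn: BatchNormParams | None = None
    activation: Callable[[np.ndarray], np.ndarray] = _silu

    def __post_init__(self) -> None:
        if len(self.branch_kernels) != 4:
            raise ValueError("pinwheel needs exactly four branch kernels")
        for W, shape in zip(self.branch_kernels, PINWHEEL_KERNEL_SHAPES):
            if W.shape[2:] != shape:
                raise ValueError(
                    f"branch kernel spatial shape {W.shape[2:]} != required {shape}"
                )
        c_prime = self.branch_kernels[0].shape[0]
        if any(W.shape[0] != c_prime for W in self.branch_kernels):
            raise ValueError("all branches must emit the same channel count")
        c2 = self.fusion_kernel.shape[0]
        if c2 != 4 * c_prime or c2 % 4 != 0:
            raise ValueError("fusion output channels must equal 4·c′ (divisible by 4)")
        if self.fusion_kernel.shape[1] != 4 * c_prime:
            raise ValueError("fusion input channels must equal 4·c′")
        if self.branch_bn is None:
            self.branch_bn = [BatchNormParams.identity(c_prime) for _ in range(4)]
        if self.fusion_bn is None:
            self.fusion_bn = BatchNormParams.identity(c2)

    @classmethod
    def random(
        cls,
        c_in: int,
        c2: int,
        branch_stride: int = 2,
        rng: np.random.Generator | None = None,
    ) -> "PinwheelSpec":
        if c2 % 4 != 0:
            raise ValueError(f"c2 must be divisible by 4, got {c2}")
        rng = rng or np.random.default_rng(0)
        c_prime = c2 // 4
        branches = tuple(
            rng.standard_normal((c_prime, c_in) + shape)
            for shape in PINWHEEL_KERNEL_SHAPES
        )
        fusion = rng.standard_normal((c2, 4 * c_prime, 2, 2))
        return cls(branch_kernels=branches, fusion_kernel=fusion, branch_stride=branch_stride)

    @classmethod
    def ones(
        cls, c_in: int = 1, c2: int = 4, branch_stride: int = 1
    ) -> "PinwheelSpec":
        """All-ones weights, identity activation — for footprint analysis."""
        c_prime = c2 // 4
        spec = cls(
            branch_kernels=tuple(
                np.ones((c_prime, c_in) + shape) for shape in PINWHEEL_KERNEL_SHAPES
            ),
            fusion_kernel=np.ones((c2, 4 * c_prime, 2, 2)),
            branch_stride=branch_stride,
        )
        spec.activation = _identity
        return spec


def pinwheel_forward(X: np.ndarray, spec: PinwheelSpec) -> np.ndarray:
    """Forward pass of the pinwheel block: pad → branch conv → BN → act,
    concatenate, 2×2 fusion conv → BN → act."""
    branches = []
    for pad, W, bn in zip(PINWHEEL_PADDINGS, spec.branch_kernels, spec.branch_bn):
        y = conv2d(_pad(X, pad), W, stride=spec.branch_stride)
        branches.append(spec.activation(bn(y)))
    shapes = {b.shape[1:] for b in branches}
    if len(shapes) != 1:  # guaranteed by the kernel/padding pairing
        raise RuntimeError(f"branch spatial shapes disagree: {shapes}")
    cat = np.concatenate(branches, axis=0)
    fused = conv2d(cat, spec.fusion_kernel)
    return spec.activation(spec.fusion_bn(fused))


# --------------------------------------------------------------------------
# receptive-field analysis


@dataclass(frozen=True)
class Footprint:
    """Input positions influencing one output position of an operator."""

    positions: FrozenSet[Tuple[int, int]]

    @property
    def size(self) -> int:
        return len(self.positions)

    def ascii_art(self) -> str:
        """Render the footprint mask relative to its bounding box."""
        if not self.positions:
            return "(empty)"
        rows = [p[0] for p in self.positions]
        cols = [p[1] for p in self.positions]
        r0, r1 = min(rows), max(rows)
        c0, c1 = min(cols), max(cols)
        lines = []
        for r in range(r0, r1 + 1):
            lines.append(
                "".join(
                    "#" if (r, c) in self.positions else "." for c in range(c0, c1 + 1)
                )
            )
        return "\n".join(lines)


def receptive_footprint(
    forward: Callable[[np.ndarray], np.ndarray],
    input_shape: Tuple[int, int],
    output_pos: Tuple[int, int] | None = None,
) -> Footprint:
    """Measure an operator's receptive field by impulse response.

    ``forward`` maps a single-channel (h, w) image to a single-channel
    spatial map.  A unit impulse is placed at every input position in turn;
    the positions whose impulse produces a nonzero response at
    ``output_pos`` (default: the centre of the output) form the footprint.
    The operator must be configured linearly (nonzero constant weights,
    identity activations/normalization) for the count to be exact.
    """
    h, w = input_shape
    probe = forward(np.zeros((h, w)))
    oh, ow = probe.shape
    if output_pos is None:
        output_pos = (oh // 2, ow // 2)
    r, c = output_pos
    if not (0 <= r < oh and 0 <= c < ow):
        raise IndexError(f"output position {output_pos} outside output {probe.shape}")
    baseline = probe[r, c]
    hits = set()
    for i in range(h):
        for j in range(w):
            X = np.zeros((h, w))
            X[i, j] = 1.0
            if abs(forward(X)[r, c] - baseline) > 1e-12:
                hits.add((i, j))
    return Footprint(positions=frozenset(hits))


def standard_conv_footprint(k: Tuple[int, int] | int = 3, margin: int = 4) -> Footprint:
    """Footprint of a plain k×k (or kh×kw) convolution, measured by impulse."""
    if isinstance(k, int):
        kh, kw = k, k
    else:
        kh, kw = k
    W = np.ones((1, 1, kh, kw))

    def fwd(x: np.ndarray) -> np.ndarray:
        return conv2d(x[None], W)[0]

    side_h = kh + 2 * margin
    side_w = kw + 2 * margin
    return receptive_footprint(fwd, (side_h, side_w))


def pinwheel_footprint(margin: int = 6) -> Footprint:
    """Footprint of the pinwheel block (branch and fusion stride 1)."""
    spec = PinwheelSpec.ones(c_in=1, c2=4, branch_stride=1)

    def fwd(x: np.ndarray) -> np.ndarray:
        return pinwheel_forward(x[None], spec).sum(axis=0)

    side = 3 + 2 * margin
    return receptive_footprint(fwd, (side, side))
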