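"""Declarative construction and audit of the YOLO-BRFB detector graph.

The detector is a standard single-stage architecture (CSP-style backbone,
PAN-FPN neck, decoupled anchor-free head) in which the terminal backbone
pooling-pyramid block (SPPF) is replaced by a BasicRFB receptive-field
block: three parallel branches of channel-reducing 1x1 convolutions
followed by 3x3 convolutions at dilation rates 1, 3 and 5, concatenated,
fused by a 1x1 convolution and added back to a shortcut path.  Dilated
branches emulate receptive fields of growing size and eccentricity at
near-constant parameter cost.

This module is an audit engine, not a training framework: blocks are
declarative specs that support exact shape inference, closed-form parameter
counting, JSON export, and a randomly-initialized numeric forward pass
(pure numpy, im2col convolutions) used for smoke and residual-identity
checks.  Losses, target assignment and training schedules are out of scope.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

__all__ = [
    "ConvSpec",
    "RFBSpec",
    "DetectorGraph",
    "GraphAudit",
    "SCALES",
    "build_basic_rfb",
    "build_sppf",
    "build_yolo_brfb",
    "build_yolov8",
    "forward_shapes",
    "forward",
    "audit",
    "residual_identity_check",
    "receptive_field",
    "GraphError",
    "ShapeError",
]


class GraphError(ValueError):
    """Invalid block construction or unknown configuration key."""


class ShapeError(GraphError):
    """Shape mismatch along a graph edge; message names the edge."""


Shape = tuple[int, int, int]  # (C, H, W)


def _silu(x: np.ndarray) -> np.ndarray:
    return x / (1.0 + np.exp(-x))


def _conv2d(x: np.ndarray, w: np.ndarray, stride: int, pad: int, dilation: int) -> np.ndarray:
    """Direct im2col 2-D convolution. x: (C,H,W), w: (Cout,Cin,k,k)."""
    cout, cin, k, _ = w.shape
    span = dilation * (k - 1) + 1
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
    if k == 1 and dilation == 1:
        patches = xp[:, ::stride, ::stride]
        ho, wo = patches.shape[1], patches.shape[2]
        out = np.tensordot(w[:, :, 0, 0], patches, axes=([1], [0]))
        return out.reshape(cout, ho, wo)
    v = np.lib.stride_tricks.sliding_window_view(xp, (span, span), axis=(1, 2))
    v = v[:, ::stride, ::stride, ::dilation, ::dilation]  # (C, Ho, Wo, k, k)
    ho, wo = v.shape[1], v.shape[2]
    patches = v.transpose(1, 2, 0, 3, 4).reshape(ho * wo, cin * k * k)
    out = patches @ w.reshape(cout, -1).T
    return out.T.reshape(cout, ho, wo).astype(np.float32, copy=False)


# ---------------------------------------------------------------------------
# Layer specs.  Every spec implements: n_params(), out_shape(shape),
# forward(x, rng), iter_convs() yielding (kernel, c_in, c_out, has_norm,
# has_bias) for independent parameter audits.
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConvSpec:
    """Convolution + batch norm + SiLU (norm/activation optional).

    Padding follows the size-preserving rule ``p = dilation*(kernel-1)//2``,
    so stride-1 convolutions keep H x W and stride-2 halve it (odd inputs
    round up: out = ceil(in/stride)).
    """

    in_channels: int
    out_channels: int
    kernel: int = 1
    stride: int = 1
    dilation: int = 1
    norm: bool = True
    act: bool = True

    def __post_init__(self) -> None:
        if self.in_channels < 1 or self.out_channels < 1:
            raise GraphError(f"channels must be >= 1, got {self.in_channels}->{self.out_channels}")
        if self.kernel % 2 != 1:
            raise GraphError(f"kernel must be odd, got {self.kernel}")
        if self.dilation < 1:
            raise GraphError(f"dilation must be >= 1, got {self.dilation}")

    @property
    def padding(self) -> int:
        return self.dilation * (self.kernel - 1) // 2

    @property
    def bias(self) -> bool:
        return not self.norm

    def n_params(self) -> int:
        n = self.kernel**2 * self.in_channels * self.out_channels
        if self.norm:
            n += 2 * self.out_channels
        else:
            n += self.out_channels  # bias
        return n

    def iter_convs(self) -> Iterator[tuple[int, int, int, bool, bool]]:
        yield (self.kernel, self.in_channels, self.out_channels, self.norm, self.bias)

    def out_shape(self, shape: Shape) -> Shape:
        c, h, w = shape
        if c != self.in_channels:
            raise ShapeError(f"Conv expects {self.in_channels} channels, got {c}")
        eff = self.dilation * (self.kernel - 1) + 1
        ho = (h + 2 * self.padding - eff) // self.stride + 1
        wo = (w + 2 * self.padding - eff) // self.stride + 1
        return (self.out_channels, ho, wo)

    def forward(self, x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        fan_in = self.kernel**2 * self.in_channels
        w = rng.standard_normal(
            (self.out_channels, self.in_channels, self.kernel, self.kernel)
        ).astype(np.float32) * math.sqrt(2.0 / fan_in)
        y = _conv2d(x, w, self.stride, self.padding, self.dilation)
        if self.bias:
            y += rng.standard_normal((self.out_channels, 1, 1)).astype(np.float32) * 0.01
        # norm at init is the identity affine (gamma=1, beta=0)
        return _silu(y) if self.act else y


@dataclass(frozen=True)
class _Sequential:
    layers: tuple

    def n_params(self) -> int:
        return sum(l.n_params() for l in self.layers)

    def iter_convs(self):
        for l in self.layers:
            yield from l.iter_convs()

    def out_shape(self, shape: Shape) -> Shape:
        for l in self.layers:
            shape = l.out_shape(shape)
        return shape

    def forward(self, x, rng):
        for l in self.layers:
            x = l.forward(x, rng)
        return x


@dataclass(frozen=True)
class RFBSpec:
    """BasicRFB block: 3 dilated branches, 1x1 fusion, residual shortcut.

    branch 1: 1x1 reduce -> 3x3 dilation 1
    branch 2: 1x1 reduce -> 3x3 -> 3x3 dilation 3
    branch 3: 1x1 reduce -> 3x3 -> 3x3 dilation 5
    concat(3 branches) -> 1x1 to out_channels, + shortcut (identity when
    in_channels == out_channels, else a 1x1 projection).

    ``inter_ratio`` sets each branch's reduced width (default 1/8 of the
    input channels, at least 1).
    """

    in_channels: int
    out_channels: int
    inter_ratio: float = 0.125
    branches: tuple[_Sequential, ...] = field(init=False, repr=False)
    fuse: ConvSpec = field(init=False, repr=False)
    shortcut: Optional[ConvSpec] = field(init=False, repr=False)

    DILATIONS = (1, 3, 5)

    def __post_init__(self) -> None:
        c = int(self.inter_ratio * self.in_channels)
        if c < 1:
            raise GraphError(
                f"inter_ratio {self.inter_ratio} of {self.in_channels} channels is below 1"
            )
        ci, co = self.in_channels, c
        b1 = _Sequential((ConvSpec(ci, co, 1), ConvSpec(co, co, 3, dilation=1)))
        b2 = _Sequential(
            (ConvSpec(ci, co, 1), ConvSpec(co, co, 3), ConvSpec(co, co, 3, dilation=3))
        )
        b3 = _Sequential(
            (ConvSpec(ci, co, 1), ConvSpec(co, co, 3), ConvSpec(co, co, 3, dilation=5))
        )
        object.__setattr__(self, "branches", (b1, b2, b3))
        object.__setattr__(self, "fuse", ConvSpec(3 * co, self.out_channels, 1, act=False))
        sc = None if ci == self.out_channels else ConvSpec(ci, self.out_channels, 1, act=False)
        object.__setattr__(self, "shortcut", sc)

    @property
    def inter_channels(self) -> int:
        return int(self.inter_ratio * self.in_channels)

    @property
    def dilations(self) -> tuple[int, int, int]:
        return tuple(b.layers[-1].dilation for b in self.branches)

    def n_params(self) -> int:
        n = sum(b.n_params() for b in self.branches) + self.fuse.n_params()
        if self.shortcut is not None:
            n += self.shortcut.n_params()
        return n

    def iter_convs(self):
        for b in self.branches:
            yield from b.iter_convs()
        yield from self.fuse.iter_convs()
        if self.shortcut is not None:
            yield from self.shortcut.iter_convs()

    def out_shape(self, shape: Shape) -> Shape:
        c, h, w = shape
        if c != self.in_channels:
            raise ShapeError(f"RFB expects {self.in_channels} channels, got {c}")
        for i, b in enumerate(self.branches):
            bc, bh, bw = b.out_shape(shape)
            if (bh, bw) != (h, w):
                raise ShapeError(f"RFB branch {i} altered spatial size: {(bh, bw)} != {(h, w)}")
        return (self.out_channels, h, w)

    def forward(self, x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        ys = [b.forward(x, rng) for b in self.branches]
        main = self.fuse.forward(np.concatenate(ys, axis=0), rng)
        short = x if self.shortcut is None else self.shortcut.forward(x, rng)
        return main + short

    def forward_zeroed(self, x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Forward pass with all main-branch weights forced to zero.

        Used by the residual-identity check: the result must equal the
        shortcut path alone.
        """
        c, h, w = x.shape
        main = np.zeros((self.out_channels, h, w), dtype=np.float32)
        short = x if self.shortcut is None else self.shortcut.forward(x, rng)
        return main + short


@dataclass(frozen=True)
class SPPFSpec:
    """Spatial pyramid pooling (fast): the block BasicRFB replaces.

    Kept so audits can assert its absence and baselines can be compared.
    """

    in_channels: int
    out_channels: int
    pool_kernel: int = 5
    cv1: ConvSpec = field(init=False, repr=False)
    cv2: ConvSpec = field(init=False, repr=False)

    def __post_init__(self) -> None:
        c = self.in_channels // 2
        object.__setattr__(self, "cv1", ConvSpec(self.in_channels, c, 1))
        object.__setattr__(self, "cv2", ConvSpec(4 * c, self.out_channels, 1))

    def n_params(self) -> int:
        return self.cv1.n_params() + self.cv2.n_params()

    def iter_convs(self):
        yield from self.cv1.iter_convs()
        yield from self.cv2.iter_convs()

    def out_shape(self, shape: Shape) -> Shape:
        c, h, w = shape
        if c != self.in_channels:
            raise ShapeError(f"SPPF expects {self.in_channels} channels, got {c}")
        return (self.out_channels, h, w)

    def forward(self, x, rng):
        y = self.cv1.forward(x, rng)
        k = self.pool_kernel
        p = k // 2
        pools = [y]
        for _ in range(3):
            yp = np.pad(pools[-1], ((0, 0), (p, p), (p, p)), constant_values=-np.inf)
            v = np.lib.stride_tricks.sliding_window_view(yp, (k, k), axis=(1, 2))
            pools.append(v.max(axis=(3, 4)))
        return self.cv2.forward(np.concatenate(pools, axis=0), rng)


@dataclass(frozen=True)
class BottleneckSpec:
    """Residual 3x3/3x3 bottleneck used inside C2f stages."""

    in_channels: int
    out_channels: int
    shortcut: bool = True
    cv1: ConvSpec = field(init=False, repr=False)
    cv2: ConvSpec = field(init=False, repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "cv1", ConvSpec(self.in_channels, self.out_channels, 3))
        object.__setattr__(self, "cv2", ConvSpec(self.out_channels, self.out_channels, 3))

    @property
    def add(self) -> bool:
        return self.shortcut and self.in_channels == self.out_channels

    def n_params(self) -> int:
        return self.cv1.n_params() + self.cv2.n_params()

    def iter_convs(self):
        yield from self.cv1.iter_convs()
        yield from self.cv2.iter_convs()

    def out_shape(self, shape: Shape) -> Shape:
        return self.cv2.out_shape(self.cv1.out_shape(shape))

    def forward(self, x, rng):
        y = self.cv2.forward(self.cv1.forward(x, rng), rng)
        return x + y if self.add else y


@dataclass(frozen=True)
class C2fSpec:
    """Cross-stage partial stage with n bottlenecks (split/concat fusion)."""

    in_channels: int
    out_channels: int
    n: int = 1
    shortcut: bool = False
    cv1: ConvSpec = field(init=False, repr=False)
    cv2: ConvSpec = field(init=False, repr=False)
    blocks: tuple = field(init=False, repr=False)

    def __post_init__(self) -> None:
        c = self.out_channels // 2
        object.__setattr__(self, "cv1", ConvSpec(self.in_channels, 2 * c, 1))
        object.__setattr__(
            self, "blocks", tuple(BottleneckSpec(c, c, self.shortcut) for _ in range(self.n))
        )
        object.__setattr__(self, "cv2", ConvSpec((2 + self.n) * c, self.out_channels, 1))

    def n_params(self) -> int:
        return self.cv1.n_params() + self.cv2.n_params() + sum(b.n_params() for b in self.blocks)

    def iter_convs(self):
        yield from self.cv1.iter_convs()
        for b in self.blocks:
            yield from b.iter_convs()
        yield from self.cv2.iter_convs()

    def out_shape(self, shape: Shape) -> Shape:
        c, h, w = shape
        if c != self.in_channels:
            raise ShapeError(f"C2f expects {self.in_channels} channels, got {c}")
        return (self.out_channels, h, w)

    def forward(self, x, rng):
        y = self.cv1.forward(x, rng)
        c = y.shape[0] // 2
        parts = [y[:c], y[c:]]
        for b in self.blocks:
            parts.append(b.forward(parts[-1], rng))
        return self.cv2.forward(np.concatenate(parts, axis=0), rng)


@dataclass(frozen=True)
class UpsampleSpec:
    """Nearest-neighbor 2x upsampling (parameter-free)."""

    factor: int = 2

    def n_params(self) -> int:
        return 0

    def iter_convs(self):
        return iter(())

    def out_shape(self, shape: Shape) -> Shape:
        c, h, w = shape
        return (c, h * self.factor, w * self.factor)

    def forward(self, x, rng):
        return np.repeat(np.repeat(x, self.factor, axis=1), self.factor, axis=2)


@dataclass(frozen=True)
class ConcatSpec:
    """Channel concatenation of multiple inputs (parameter-free).

    Inputs whose spatial sizes differ by at most 1 px per dimension — the
    rounding artifact of odd input sizes under stride-2 downsampling and 2x
    upsampling — are corner-cropped to the common minimum; larger
    disagreements are genuine wiring errors and raise :class:`ShapeError`.
    """

    def n_params(self) -> int:
        return 0

    def iter_convs(self):
        return iter(())

    def out_shape_multi(self, shapes: Sequence[Shape]) -> Shape:
        hs = [h for _, h, _ in shapes]
        ws = [w for _, _, w in shapes]
        if max(hs) - min(hs) > 1 or max(ws) - min(ws) > 1:
            raise ShapeError(f"Concat inputs disagree on spatial size: {shapes}")
        return (sum(c for c, _, _ in shapes), min(hs), min(ws))

    def forward_multi(self, xs, rng):
        self.out_shape_multi([x.shape for x in xs])
        h = min(x.shape[1] for x in xs)
        w = min(x.shape[2] for x in xs)
        return np.concatenate([x[:, :h, :w] for x in xs], axis=0)


@dataclass(frozen=True)
class DetectHeadSpec:
    """Decoupled anchor-free head for one feature level.

    Box branch: 3x3, 3x3, 1x1 -> 4*reg_max distribution bins; class branch:
    3x3, 3x3, 1x1 -> n_classes logits; outputs are concatenated per level.
    """

    in_channels: int
    n_classes: int = 1
    reg_max: int = 16
    box_branch: _Sequential = field(init=False, repr=False)
    cls_branch: _Sequential = field(init=False, repr=False)

    def __post_init__(self) -> None:
        c = self.in_channels
        cb = max(16, c // 4, 4 * self.reg_max)
        cc = max(c, min(self.n_classes, 100))
        box = _Sequential(
            (
                ConvSpec(c, cb, 3),
                ConvSpec(cb, cb, 3),
                ConvSpec(cb, 4 * self.reg_max, 1, norm=False, act=False),
            )
        )
        cls = _Sequential(
            (
                ConvSpec(c, cc, 3),
                ConvSpec(cc, cc, 3),
                ConvSpec(cc, self.n_classes, 1, norm=False, act=False),
            )
        )
        object.__setattr__(self, "box_branch", box)
        object.__setattr__(self, "cls_branch", cls)

    def n_params(self) -> int:
        return self.box_branch.n_params() + self.cls_branch.n_params()

    def iter_convs(self):
        yield from self.box_branch.iter_convs()
        yield from self.cls_branch.iter_convs()

    def out_shape(self, shape: Shape) -> Shape:
        c, h, w = shape
        if c != self.in_channels:
            raise ShapeError(f"Detect head expects {self.in_channels} channels, got {c}")
        return (4 * self.reg_max + self.n_classes, h, w)

    def forward(self, x, rng):
        return np.concatenate(
            [self.box_branch.forward(x, rng), self.cls_branch.forward(x, rng)], axis=0
        )


# ---------------------------------------------------------------------------
# Graph assembly
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GraphNode:
    name: str
    block: object
    inputs: tuple[int, ...]  # indices of predecessor nodes; -1 = graph input


@dataclass(frozen=True)
class DetectorGraph:
    """Acyclic node list with designated input and output nodes."""

    nodes: tuple[GraphNode, ...]
    outputs: tuple[int, ...]
    input_shape: Shape = (3, 640, 640)

    def node_types(self) -> dict[str, int]:
        census: dict[str, int] = {}
        for n in self.nodes:
            t = type(n.block).__name__
            census[t] = census.get(t, 0) + 1
        return census

    def n_params(self) -> int:
        return sum(n.block.n_params() for n in self.nodes)

    def iter_convs(self):
        for n in self.nodes:
            yield from n.block.iter_convs()

    def to_json(self) -> str:
        """Plain JSON description of nodes/edges for inspection and diffing."""
        shapes = forward_shapes(self, self.input_shape)
        payload = {
            "input_shape": list(self.input_shape),
            "outputs": list(self.outputs),
            "nodes": [
                {
                    "index": i,
                    "name": n.name,
                    "type": type(n.block).__name__,
                    "inputs": list(n.inputs),
                    "params": n.block.n_params(),
                    "out_shape": list(shapes[i]),
                }
                for i, n in enumerate(self.nodes)
            ],
        }
        return json.dumps(payload, indent=2)


@dataclass(frozen=True)
class GraphAudit:
    """Summary of a graph: parameters, shapes, node-type census."""

    total_params: int
    node_shapes: dict[str, Shape]
    node_types: dict[str, int]

    @property
    def n_rfb(self) -> int:
        return self.node_types.get("RFBSpec", 0)

    @property
    def n_sppf(self) -> int:
        return self.node_types.get("SPPFSpec", 0)


def forward_shapes(g, input_shape: Shape) -> list[Shape]:
    """Inferred output shape of every node (no numeric execution).

    Also accepts a bare block (e.g. an :class:`RFBSpec`), returning a
    single-element list.
    """
    if not isinstance(g, DetectorGraph):
        return [g.out_shape(tuple(input_shape))]
    shapes: list[Shape] = []
    for i, node in enumerate(g.nodes):
        in_shapes = [input_shape if j == -1 else shapes[j] for j in node.inputs]
        try:
            if isinstance(node.block, ConcatSpec):
                shapes.append(node.block.out_shape_multi(in_shapes))
            else:
                shapes.append(node.block.out_shape(in_shapes[0]))
        except ShapeError as e:
            raise ShapeError(f"node {i} ({node.name}): {e}") from e
    return shapes


def forward(g: DetectorGraph, x: np.ndarray, seed: int = 0) -> list[np.ndarray]:
    """Numeric forward pass with fixed-seed fan-in-scaled random weights.

    Returns the activations of the graph's output nodes.  Intended for
    audits (finiteness, residual identities), never for inference quality.
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(x, dtype=np.float32)
    acts: list[np.ndarray] = []
    for node in g.nodes:
        ins = [x if j == -1 else acts[j] for j in node.inputs]
        if isinstance(node.block, ConcatSpec):
            acts.append(node.block.forward_multi(ins, rng))
        else:
            acts.append(node.block.forward(ins[0], rng))
    return [acts[i] for i in g.outputs]


def audit(g: DetectorGraph, input_shape: Optional[Shape] = None) -> GraphAudit:
    """Parameter count, per-node output shapes, and node-type census."""
    shape = tuple(input_shape) if input_shape is not None else g.input_shape
    shapes = forward_shapes(g, shape)
    return GraphAudit(
        total_params=g.n_params(),
        node_shapes={f"{i}:{n.name}": shapes[i] for i, n in enumerate(g.nodes)},
        node_types=g.node_types(),
    )


def build_basic_rfb(in_channels: int, out_channels: int, inter_ratio: float = 0.125) -> RFBSpec:
    """Construct a BasicRFB spec (see :class:`RFBSpec` for the topology)."""
    return RFBSpec(in_channels, out_channels, inter_ratio)


def build_sppf(in_channels: int, out_channels: int) -> SPPFSpec:
    return SPPFSpec(in_channels, out_channels)


# depth multiplier, width multiplier, max channels — the standard scale table
SCALES: dict[str, tuple[float, float, int]] = {
    "n": (0.33, 0.25, 1024),
    "s": (0.33, 0.50, 1024),
    "m": (0.67, 0.75, 768),
    "l": (1.00, 1.00, 512),
    "x": (1.00, 1.25, 512),
}


def _make_divisible(v: float, divisor: int = 8) -> int:
    return max(divisor, int(v + divisor / 2) // divisor * divisor)


def _scaled(c: int, width: float, max_channels: int) -> int:
    return _make_divisible(min(c, max_channels) * width) if c > 3 else c


def _scaled_depth(n: int, depth: float) -> int:
    return max(1, round(n * depth))


def build_detector(
    scale: str | tuple[float, float, int] = "n",
    n_classes: int = 1,
    terminal_block: str = "rfb",
    input_size: int = 640,
    inter_ratio: float = 0.125,
) -> DetectorGraph:
    """Assemble the detector graph at a given scale.

    ``terminal_block`` selects the block closing the backbone: ``"rfb"``
    (the modified architecture) or ``"sppf"`` (the stock baseline).
    """
    if isinstance(scale, str):
        if scale not in SCALES:
            raise GraphError(f"unknown scale {scale!r}; known: {sorted(SCALES)}")
        depth, width, max_ch = SCALES[scale]
    else:
        depth, width, max_ch = scale

    def C(c: int) -> int:
        return _scaled(c, width, max_ch)

    def D(n: int) -> int:
        return _scaled_depth(n, depth)

    nodes: list[GraphNode] = []

    def add(name: str, block, inputs: tuple[int, ...]) -> int:
        nodes.append(GraphNode(name, block, inputs))
        return len(nodes) - 1

    # backbone
    p1 = add("stem", ConvSpec(3, C(64), 3, stride=2), (-1,))
    p2 = add("down2", ConvSpec(C(64), C(128), 3, stride=2), (p1,))
    s2 = add("stage2", C2fSpec(C(128), C(128), D(3), shortcut=True), (p2,))
    p3 = add("down3", ConvSpec(C(128), C(256), 3, stride=2), (s2,))
    s3 = add("stage3", C2fSpec(C(256), C(256), D(6), shortcut=True), (p3,))
    p4 = add("down4", ConvSpec(C(256), C(512), 3, stride=2), (s3,))
    s4 = add("stage4", C2fSpec(C(512), C(512), D(6), shortcut=True), (p4,))
    p5 = add("down5", ConvSpec(C(512), C(1024), 3, stride=2), (s4,))
    s5 = add("stage5", C2fSpec(C(1024), C(1024), D(3), shortcut=True), (p5,))
    if terminal_block == "rfb":
        top = add("rfb", build_basic_rfb(C(1024), C(1024), inter_ratio), (s5,))
    elif terminal_block == "sppf":
        top = add("sppf", build_sppf(C(1024), C(1024)), (s5,))
    else:
        raise GraphError(f"unknown terminal block {terminal_block!r}")

    # neck (PAN-FPN)
    u1 = add("up1", UpsampleSpec(), (top,))
    c1 = add("cat1", ConcatSpec(), (u1, s4))
    n1 = add("neck_p4", C2fSpec(C(1024) + C(512), C(512), D(3)), (c1,))
    u2 = add("up2", UpsampleSpec(), (n1,))
    c2 = add("cat2", ConcatSpec(), (u2, s3))
    n2 = add("neck_p3", C2fSpec(C(512) + C(256), C(256), D(3)), (c2,))
    d1 = add("pan_down3", ConvSpec(C(256), C(256), 3, stride=2), (n2,))
    c3 = add("cat3", ConcatSpec(), (d1, n1))
    n3 = add("pan_p4", C2fSpec(C(256) + C(512), C(512), D(3)), (c3,))
    d2 = add("pan_down4", ConvSpec(C(512), C(512), 3, stride=2), (n3,))
    c4 = add("cat4", ConcatSpec(), (d2, top))
    n4 = add("pan_p5", C2fSpec(C(512) + C(1024), C(1024), D(3)), (c4,))

    # decoupled anchor-free heads at strides 8 / 16 / 32
    h3 = add("head_p3", DetectHeadSpec(C(256), n_classes), (n2,))
    h4 = add("head_p4", DetectHeadSpec(C(512), n_classes), (n3,))
    h5 = add("head_p5", DetectHeadSpec(C(1024), n_classes), (n4,))

    return DetectorGraph(
        nodes=tuple(nodes),
        outputs=(h3, h4, h5),
        input_shape=(3, input_size, input_size),
    )


def build_yolo_brfb(scale: str | tuple[float, float, int] = "n", **kw) -> DetectorGraph:
    """The modified detector: stock topology with SPPF replaced by BasicRFB."""
    return build_detector(scale, terminal_block="rfb", **kw)


def build_yolov8(scale: str | tuple[float, float, int] = "n", **kw) -> DetectorGraph:
    """The stock baseline topology (SPPF terminal block), for comparison."""
    return build_detector(scale, terminal_block="sppf", **kw)


def residual_identity_check(spec: RFBSpec, input_hw: tuple[int, int] = (16, 16), seed: int = 0) -> bool:
    """Verify the additive residual: zeroed main branches leave only the shortcut.

    Runs the block numerically with all main-path weights forced to zero and
    compares against the shortcut path alone; exact equality is required.
    """
    rng_state = np.random.default_rng(seed)
    x = rng_state.standard_normal((spec.in_channels, *input_hw)).astype(np.float32)
    zeroed = spec.forward_zeroed(x, np.random.default_rng(seed + 1))
    short = x if spec.shortcut is None else spec.shortcut.forward(x, np.random.default_rng(seed + 1))
    return bool(np.array_equal(zeroed, short))


def receptive_field(layers: Sequence[ConvSpec]) -> int:
    """Nominal receptive field of a sequential conv stack (standard recursion).

    r_{i} = r_{i-1} + (k_eff - 1) * prod(previous strides), with
    k_eff = dilation*(kernel-1) + 1.
    """
    r = 1
    jump = 1
    for l in layers:
        k_eff = l.dilation * (l.kernel - 1) + 1
        r += (k_eff - 1) * jump
        jump *= l.stride
    return r
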