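"""Declarative layer graph of the fused dense/inception network.

The architecture is described backend-independently as a DAG of
:class:`LayerSpec` nodes, so that the printed structural facts — 71
layers in the dense module (9 residual blocks, 22 convolutions), 44 in
the inception module, 115 after network-level fusion, a 512-wide fused
feature vector and ~6.9 million learnable parameters — can be counted,
audited and round-tripped without instantiating any weights.  The
runtime (:mod:`denseinceps.runtime`) consumes the same graph to build an
executable model.

Counting convention (frozen): every declared node is one layer.  The
44-layer inception subtotal includes the classifier head (fully
connected, softmax, classification); the 71-layer dense subtotal
includes the shared input node.  ``fuse_networks`` strips each branch's
trailing head, merges the two input nodes, and appends the four-node
fusion head (depth concatenation, fully connected, softmax,
classification): 71 + 40 + 4 = 115.

Channel plan notes (frozen manifest): the fourth late dense residual
block mirrors the first (1x1 then 3x3, depth 256); all grouped
convolutions use groups=8.  Under the parameter accounting below this
yields exactly 6,880,061 learnables at width scale 1.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

__all__ = [
    "LayerSpec",
    "NetworkGraph",
    "ArchitectureAudit",
    "StructuralError",
    "KINDS",
    "build_dense_module",
    "build_inception_module",
    "fuse_networks",
    "build_fused_network",
    "count_layers",
    "count_parameters",
    "infer_shapes",
    "audit",
]

KINDS = frozenset({
    "input", "convolution", "grouped-convolution", "batch-norm", "relu",
    "max-pool", "global-average-pool", "depth-concatenation", "flatten",
    "self-attention", "fully-connected", "softmax", "classification",
})

_CONV_KINDS = ("convolution", "grouped-convolution")


class StructuralError(ValueError):
    """A graph violates a structural invariant; the message names the layer."""


@dataclass
class LayerSpec:
    id: str
    kind: str
    inputs: list[str] = field(default_factory=list)
    filter_h: int | None = None
    filter_w: int | None = None
    stride: int | None = None
    out_channels: int | None = None
    groups: int | None = None
    heads: int | None = None        # self-attention only (1 = single head)
    block: str | None = None        # residual-block tag, for block counting

    def __post_init__(self):
        if self.kind not in KINDS:
            raise StructuralError(f"layer {self.id!r}: unknown kind {self.kind!r}")
        if self.kind != "input" and not self.inputs:
            raise StructuralError(f"layer {self.id!r}: non-input layer needs inputs")
        if self.kind == "depth-concatenation" and len(self.inputs) < 2:
            raise StructuralError(
                f"layer {self.id!r}: depth-concatenation needs >= 2 inputs")
        for name in ("filter_h", "filter_w", "stride"):
            v = getattr(self, name)
            if v is not None and (not isinstance(v, int) or v < 1):
                raise StructuralError(
                    f"layer {self.id!r}: {name} must be a positive integer")


@dataclass
class NetworkGraph:
    layers: list[LayerSpec]
    name: str = "net"
    input_shape: tuple[int, int, int] = (227, 227, 3)  # H, W, C

    def __post_init__(self):
        ids = [l.id for l in self.layers]
        if len(set(ids)) != len(ids):
            raise StructuralError("duplicate layer ids")
        inputs = [l for l in self.layers if l.kind == "input"]
        if len(inputs) != 1:
            raise StructuralError(f"graph {self.name!r}: needs exactly one input node")
        known = set()
        for l in self.layers:
            for up in l.inputs:
                if up not in known:
                    raise StructuralError(
                        f"layer {l.id!r}: input {up!r} not defined upstream")
            known.add(l.id)  # topological order doubles as the acyclicity proof

    def __getitem__(self, lid: str) -> LayerSpec:
        for l in self.layers:
            if l.id == lid:
                return l
        raise KeyError(lid)

    # -- JSON round trip ----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps({
            "name": self.name,
            "input_shape": list(self.input_shape),
            "layers": [asdict(l) for l in self.layers],
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "NetworkGraph":
        d = json.loads(text)
        return cls(layers=[LayerSpec(**l) for l in d["layers"]],
                   name=d["name"], input_shape=tuple(d["input_shape"]))


# ---------------------------------------------------------------------------
# shape inference

def _pool_conv_out(size: int, f: int, stride: int) -> int:
    # stride-1 layers use same-padding, stride>=2 valid padding (floor)
    if stride == 1:
        return size
    return (size - f) // stride + 1


def infer_shapes(g: NetworkGraph) -> dict[str, tuple]:
    """Propagate shapes; images are (C, H, W) tuples, vectors are (d,).

    Raises :class:`StructuralError` naming the first offending layer
    (e.g. a depth concatenation whose inputs disagree spatially).
    """
    shapes: dict[str, tuple] = {}
    tokens: dict[str, int] = {}  # flatten id -> token count (H*W of its source)
    for l in g.layers:
        ins = [shapes[i] for i in l.inputs]
        if l.kind == "input":
            h, w, c = g.input_shape
            shapes[l.id] = (c, h, w)
        elif l.kind in _CONV_KINDS:
            (c, h, w), = ins
            if len(ins[0]) != 3:
                raise StructuralError(f"layer {l.id!r}: convolution needs an image input")
            groups = l.groups or 1
            if c % groups or l.out_channels % groups:
                raise StructuralError(
                    f"layer {l.id!r}: channels ({c}->{l.out_channels}) not divisible "
                    f"by groups={groups}")
            shapes[l.id] = (l.out_channels,
                            _pool_conv_out(h, l.filter_h, l.stride),
                            _pool_conv_out(w, l.filter_w, l.stride))
        elif l.kind in ("batch-norm", "relu", "softmax", "classification"):
            shapes[l.id] = ins[0]
        elif l.kind == "max-pool":
            c, h, w = ins[0]
            shapes[l.id] = (c, _pool_conv_out(h, l.filter_h, l.stride),
                            _pool_conv_out(w, l.filter_w, l.stride))
        elif l.kind == "global-average-pool":
            c, h, w = ins[0]
            shapes[l.id] = (c, 1, 1)
        elif l.kind == "depth-concatenation":
            ranks = {len(s) for s in ins}
            if len(ranks) != 1:
                raise StructuralError(
                    f"layer {l.id!r}: concatenation inputs have mixed ranks")
            if ranks == {3}:
                hw = {(s[1], s[2]) for s in ins}
                if len(hw) != 1:
                    raise StructuralError(
                        f"layer {l.id!r}: concatenation inputs differ spatially: "
                        f"{sorted(hw)}")
                shapes[l.id] = (sum(s[0] for s in ins),) + ins[0][1:]
            else:
                shapes[l.id] = (sum(s[0] for s in ins),)
        elif l.kind == "flatten":
            s = ins[0]
            if len(s) == 3:
                c, h, w = s
                shapes[l.id] = (c * h * w,)
                tokens[l.id] = h * w
            else:
                shapes[l.id] = s
                tokens[l.id] = 1
        elif l.kind == "self-attention":
            # tokens = spatial positions of the flattened map, embedding =
            # channels; output is mean-pooled over tokens to one embedding
            src = l.inputs[0]
            m = tokens.get(src, 1)
            d = shapes[src][0] // m if len(shapes[src]) == 1 else shapes[src][0]
            shapes[l.id] = (d,)
        elif l.kind == "fully-connected":
            if len(ins[0]) != 1:
                raise StructuralError(
                    f"layer {l.id!r}: fully-connected needs a vector input")
            shapes[l.id] = (l.out_channels,)
    return shapes


def attention_geometry(g: NetworkGraph, att: LayerSpec,
                       shapes: dict[str, tuple]) -> tuple[int, int]:
    """(tokens m, embedding n) seen by an attention node."""
    src = g[att.inputs[0]]
    if src.kind == "flatten":
        up_shape = shapes[src.inputs[0]]
        if len(up_shape) == 3:
            return up_shape[1] * up_shape[2], up_shape[0]
    return 1, shapes[att.inputs[0]][0]


# ---------------------------------------------------------------------------
# counting and audit

def count_layers(g: NetworkGraph) -> int:
    """Number of declared graph nodes (every node counts as one layer)."""
    return len(g.layers)


def count_parameters(g: NetworkGraph) -> int:
    """Learnable-parameter total.

    conv: fh*fw*(Cin/groups)*Cout + Cout; batch-norm: 2C; fully connected:
    din*dout + dout; self-attention: three square projection maps of the
    embedding (plus one output projection when multi-headed).
    """
    shapes = infer_shapes(g)
    total = 0
    for l in g.layers:
        if l.kind in _CONV_KINDS:
            cin = shapes[l.inputs[0]][0]
            groups = l.groups or 1
            total += l.filter_h * l.filter_w * (cin // groups) * l.out_channels \
                + l.out_channels
        elif l.kind == "batch-norm":
            total += 2 * shapes[l.inputs[0]][0]
        elif l.kind == "fully-connected":
            total += shapes[l.inputs[0]][0] * l.out_channels + l.out_channels
        elif l.kind == "self-attention":
            _, n = attention_geometry(g, l, shapes)
            total += 3 * n * n
            if (l.heads or 1) > 1:
                total += n * n
    return total


@dataclass
class ArchitectureAudit:
    total_layers: int
    layers_by_kind: dict[str, int]
    conv_layer_count: int
    residual_block_count: int
    total_parameters: int
    fused_feature_dim: int | None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ArchitectureAudit":
        return cls(**json.loads(text))


def audit(g: NetworkGraph) -> ArchitectureAudit:
    shapes = infer_shapes(g)
    by_kind: dict[str, int] = {}
    for l in g.layers:
        by_kind[l.kind] = by_kind.get(l.kind, 0) + 1
    blocks = {l.block for l in g.layers if l.block is not None}
    fused_dim = None
    for l in g.layers:
        if l.kind == "depth-concatenation" and len(shapes[l.id]) == 1:
            fused_dim = shapes[l.id][0]
    return ArchitectureAudit(
        total_layers=count_layers(g),
        layers_by_kind=by_kind,
        conv_layer_count=sum(by_kind.get(k, 0) for k in _CONV_KINDS),
        residual_block_count=len(blocks),
        total_parameters=count_parameters(g),
        fused_feature_dim=fused_dim,
    )


# ---------------------------------------------------------------------------
# builders (the frozen manifest)

def _scaled(c: int, s: float) -> int:
    return max(1, round(c * s))


class _Builder:
    def __init__(self, name, width_scale=1.0, input_shape=(227, 227, 3)):
        self.layers: list[LayerSpec] = []
        self.s = width_scale
        self.g = NetworkGraph  # noqa: shorthand only
        self.name = name
        self.input_shape = input_shape
        self.channels: dict[str, int] = {}

    def add(self, lid, kind, inputs, **kw) -> str:
        self.layers.append(LayerSpec(id=lid, kind=kind, inputs=list(inputs), **kw))
        return lid

    def inp(self, lid):
        self.layers.append(LayerSpec(id=lid, kind="input"))
        self.channels[lid] = self.input_shape[2]
        return lid

    def conv(self, lid, src, depth, f, stride=1, block=None):
        fh, fw = f if isinstance(f, tuple) else (f, f)
        c = _scaled(depth, self.s)
        self.channels[lid] = c
        return self.add(lid, "convolution", [src], filter_h=fh, filter_w=fw,
                        stride=stride, out_channels=c, block=block)

    def gconv(self, lid, src, depth, f=3, groups=8, block=None):
        c = _scaled(depth, self.s)
        cin = self.channels[src]
        g = math.gcd(math.gcd(groups, cin), c)
        self.channels[lid] = c
        return self.add(lid, "grouped-convolution", [src], filter_h=f,
                        filter_w=f, stride=1, out_channels=c, groups=g,
                        block=block)

    def bn(self, lid, src, block=None):
        self.channels[lid] = self.channels[src]
        return self.add(lid, "batch-norm", [src], block=block)

    def relu(self, lid, src, block=None):
        self.channels[lid] = self.channels[src]
        return self.add(lid, "relu", [src], block=block)

    def pool(self, lid, src, f=3, stride=2):
        self.channels[lid] = self.channels[src]
        return self.add(lid, "max-pool", [src], filter_h=f, filter_w=f,
                        stride=stride)

    def concat(self, lid, srcs):
        self.channels[lid] = sum(self.channels[s] for s in srcs)
        return self.add(lid, "depth-concatenation", srcs)

    def graph(self) -> NetworkGraph:
        return NetworkGraph(layers=self.layers, name=self.name,
                            input_shape=self.input_shape)


def _dense_residual_block(b: _Builder, tag, src, d1, d2, f2=1):
    """conv, BN, ReLU, conv, ReLU — five layers — then a concat skip join."""
    c1 = b.conv(f"{tag}_c1", src, d1, 1, block=tag)
    n1 = b.bn(f"{tag}_bn", c1, block=tag)
    r1 = b.relu(f"{tag}_r1", n1, block=tag)
    c2 = b.conv(f"{tag}_c2", r1, d2, f2, block=tag)
    r2 = b.relu(f"{tag}_r2", c2, block=tag)
    return b.concat(f"{tag}_dc", [src, r2])


def build_dense_module(width_scale: float = 1.0) -> NetworkGraph:
    """The 71-layer dense module with self-attention.

    Stem conv (3x3, stride 2, depth 32) + BN + ReLU; nine five-layer
    residual blocks joined by depth-concatenation skips; 2x2-stride-2
    transition convolutions (depths 128/256/256) absorbing the depth
    growth; three 3x3-stride-2 max-pools; flatten; self-attention.
    """
    b = _Builder("dense_module", width_scale)
    x = b.inp("d_input")
    x = b.conv("d_stem", x, 32, 3, stride=2)
    x = b.bn("d_stem_bn", x)
    x = b.relu("d_stem_relu", x)
    dc1 = _dense_residual_block(b, "d_rb1", x, 64, 64)
    dc2 = _dense_residual_block(b, "d_rb2", dc1, 96, 64)
    x = b.concat("d_skip_a", [dc1, dc2])
    x = b.conv("d_trans1", x, 128, 2, stride=2)
    x = b.relu("d_trans1_relu", x)
    mp1 = b.pool("d_pool1", x)
    dc3 = _dense_residual_block(b, "d_rb3", mp1, 128, 128)
    dc4 = _dense_residual_block(b, "d_rb4", dc3, 128, 64)
    dc5 = _dense_residual_block(b, "d_rb5", dc4, 128, 128)
    x = b.concat("d_skip_b", [mp1, dc5])
    x = b.conv("d_trans2", x, 256, 2, stride=2)
    x = b.relu("d_trans2_relu", x)
    x = b.pool("d_pool2", x)
    x = _dense_residual_block(b, "d_rb6", x, 256, 256, f2=3)
    x = _dense_residual_block(b, "d_rb7", x, 128, 128)
    x = _dense_residual_block(b, "d_rb8", x, 256, 256)
    x = _dense_residual_block(b, "d_rb9", x, 256, 256, f2=3)
    x = b.conv("d_trans3", x, 256, 2, stride=2)
    x = b.relu("d_trans3_relu", x)
    x = b.pool("d_pool3", x)
    x = b.add("d_flatten", "flatten", [x])
    b.add("d_attention", "self-attention", [x], heads=1)
    return b.graph()


def _inverted_residual_block(b: _Builder, tag, src, d_mid, d_out):
    """conv, ReLU, BN, grouped-conv 3x3, conv, BN — six layers — plus skip."""
    c1 = b.conv(f"{tag}_c1", src, d_mid, 1, block=tag)
    r1 = b.relu(f"{tag}_r1", c1, block=tag)
    n1 = b.bn(f"{tag}_bn1", r1, block=tag)
    gc = b.gconv(f"{tag}_gc", n1, d_mid, block=tag)
    c2 = b.conv(f"{tag}_c2", gc, d_out, 1, block=tag)
    n2 = b.bn(f"{tag}_bn2", c2, block=tag)
    return b.concat(f"{tag}_dc", [src, n2])


def build_inception_module(width_scale: float = 1.0,
                           num_classes: int = 5) -> NetworkGraph:
    """The 44-layer inception module with multiscale self-heads.

    Stem conv (1x1, stride 2, depth 16) + ReLU; an inception block
    with parallel 1x1 / 1x3 / 3x1 / pooled-1x1 branches joined by depth
    concatenation; transition conv (3x3, stride 2, depth 64) + max-pool;
    three six-layer inverted residual blocks (128->256, 128->256,
    256->312) joined by concatenation skips; transition conv (3x3,
    stride 2, depth 256); max-pool; global average pool; flatten;
    4-head self-attention; classifier head (the head carries the
    module's share of the fused network's final layers).
    """
    b = _Builder("inception_module", width_scale)
    x = b.inp("i_input")
    stem = b.conv("i_stem", x, 16, 1, stride=2)
    stem = b.relu("i_stem_relu", stem)
    b1 = b.conv("i_incb_b1", stem, 16, 1)
    b2a = b.conv("i_incb_b2a", stem, 16, 1)
    b2b = b.conv("i_incb_b2b", b2a, 32, (1, 3))
    b3a = b.conv("i_incb_b3a", stem, 16, 1)
    b3b = b.conv("i_incb_b3b", b3a, 32, (3, 1))
    p4 = b.pool("i_incb_pool", stem, f=3, stride=1)
    b4 = b.conv("i_incb_b4", p4, 32, 1)
    x = b.concat("i_incb_dc", [b1, b2b, b3b, b4])
    x = b.conv("i_trans1", x, 64, 3, stride=2)
    x = b.relu("i_trans1_relu", x)
    x = b.pool("i_pool1", x, f=3, stride=1)
    x = _inverted_residual_block(b, "i_ib1", x, 128, 256)
    x = _inverted_residual_block(b, "i_ib2", x, 128, 256)
    x = _inverted_residual_block(b, "i_ib3", x, 256, 312)
    x = b.conv("i_trans2", x, 256, 3, stride=2)
    x = b.relu("i_trans2_relu", x)
    x = b.pool("i_pool2", x, f=3, stride=2)
    x = b.add("i_gap", "global-average-pool", [x])
    x = b.add("i_flatten", "flatten", [x])
    x = b.add("i_attention", "self-attention", [x], heads=4)
    x = b.add("i_fc", "fully-connected", [x], out_channels=num_classes)
    x = b.add("i_softmax", "softmax", [x])
    b.add("i_classification", "classification", [x])
    return b.graph()


_HEAD_KINDS = ("fully-connected", "softmax", "classification")


def _strip_head(g: NetworkGraph) -> tuple[list[LayerSpec], str, int | None]:
    """Drop trailing FC/softmax/classification nodes; return (layers, tail id, C)."""
    layers = list(g.layers)
    num_classes = None
    while layers and layers[-1].kind in _HEAD_KINDS:
        popped = layers.pop()
        if popped.kind == "fully-connected":
            num_classes = popped.out_channels
    return layers, layers[-1].id, num_classes


def fuse_networks(a: NetworkGraph, b: NetworkGraph,
                  num_classes: int | None = None) -> NetworkGraph:
    """Network-level fusion of two branches through a depth concatenation.

    Each branch's trailing classifier head (if any) is stripped, the two
    input nodes are merged, and both terminal feature vectors feed one
    depth-concatenation node of dimension d1+d2, followed by fully
    connected, softmax and classification nodes.
    """
    if a.input_shape != b.input_shape:
        raise StructuralError("branches declare different input shapes")
    la, tail_a, _ = _strip_head(a)
    lb, tail_b, nc_b = _strip_head(b)
    if num_classes is None:
        num_classes = nc_b if nc_b is not None else 5

    sa, sb = infer_shapes(a), infer_shapes(b)
    for g, tail, s in ((a, tail_a, sa), (b, tail_b, sb)):
        if len(s[tail]) != 1:
            raise StructuralError(
                f"branch {g.name!r} terminates in image-shaped activation "
                f"{s[tail]} at {tail!r}; a feature vector is required")

    input_a = next(l for l in la if l.kind == "input")
    input_b = next(l for l in lb if l.kind == "input")
    merged = list(la)
    for l in lb:
        if l.id == input_b.id:
            continue
        inputs = [input_a.id if i == input_b.id else i for i in l.inputs]
        merged.append(LayerSpec(**{**asdict(l), "inputs": inputs}))
    merged.append(LayerSpec(id="fusion_concat", kind="depth-concatenation",
                            inputs=[tail_a, tail_b]))
    merged.append(LayerSpec(id="fusion_fc", kind="fully-connected",
                            inputs=["fusion_concat"], out_channels=num_classes))
    merged.append(LayerSpec(id="fusion_softmax", kind="softmax",
                            inputs=["fusion_fc"]))
    merged.append(LayerSpec(id="fusion_classification", kind="classification",
                            inputs=["fusion_softmax"]))
    fused = NetworkGraph(layers=merged, name=f"{a.name}+{b.name}",
                         input_shape=a.input_shape)
    infer_shapes(fused)  # validate end to end
    return fused


def build_fused_network(width_scale: float = 1.0,
                        num_classes: int = 5) -> NetworkGraph:
    """The full 115-layer fused network."""
    g = fuse_networks(build_dense_module(width_scale),
                      build_inception_module(width_scale, num_classes),
                      num_classes)
    g.name = "DenseIncepS115" if width_scale == 1.0 else \
        f"DenseIncepS115(ws={width_scale:g})"
    return g
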