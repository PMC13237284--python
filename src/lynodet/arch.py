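"""Detector architecture as data: layer specs, shape tracing, cost counting.

The modified single-stage detector enlarges the downsampling kernels to 7x7,
deepens the backbone to six stride-2 stages (adding a P6 level at stride 64
with channel depth up to 2048), and keeps a three-head PAN-FPN neck.  Each
variant of the ablation axis is a declarative :class:`ArchSpec` — an ordered
DAG of :class:`LayerSpec` rows — from which shapes, parameter counts and FLOP
estimates are derived without instantiating any weights.

Variants
--------
baseline   standard nano-width five-stage layout, 3x3 kernels, heads 8/16/32
kernel7    baseline with 7x7 downsampling kernels
hyper      architecturally identical to kernel7 (hyperparameter-only ablation)
extraconv  deepened six-stage backbone at half width, heads 16/32/64
full_p6    the full modified backbone (64..2048 channels, P6), heads 16/32/64
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import yaml

VARIANTS = ("baseline", "kernel7", "hyper", "extraconv", "full_p6")

CLASS_NAMES = [
    "abdominal", "cervical", "lt-subclavicular", "lt-inguinal", "mediastinal",
    "normal", "nose", "pelvis", "retroperitoneal", "rt-cervical",
    "rt-subclavicular", "rt-axillary", "rt-inguinal", "lt-axillary",
    "lt-cervical",
]


class ArchError(ValueError):
    """Invalid geometry or graph construction failure."""


@dataclass
class FeatureShape:
    height: int
    width: int
    channels: int
    stride: int = 1

    def spatial(self):
        return (self.height, self.width)


@dataclass
class LayerSpec:
    index: int
    source: object            # int (earlier layer; 0 = input) or list of ints
    op_kind: str              # conv_block | c2f | sppf | upsample | concat | detect_head
    kernel: int = 0
    stride: int = 1
    padding: int = 0
    out_channels: int = 0
    repeats: int = 1
    notes: str = ""

    def __post_init__(self):
        if self.stride not in (1, 2):
            raise ArchError(f"layer {self.index}: stride must be 1 or 2")
        if self.op_kind == "c2f" and self.repeats < 1:
            raise ArchError(f"layer {self.index}: c2f needs repeats >= 1")
        srcs = self.source if isinstance(self.source, list) else [self.source]
        if any(s >= self.index for s in srcs):
            raise ArchError(f"layer {self.index}: source must be earlier (DAG)")


@dataclass
class ArchSpec:
    variant: str
    input_size: int = 640
    layers: list = field(default_factory=list)
    detect_strides: list = field(default_factory=list)
    num_classes: int = 15
    reg_max: int = 16
    width_mult: float = 1.0

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ArchSpec":
        layers = [LayerSpec(**ls) for ls in d.pop("layers")]
        return cls(layers=layers, **d)

    def save(self, path: str):
        text = (json.dumps(self.to_dict(), indent=2) if str(path).endswith(".json")
                else yaml.safe_dump(self.to_dict(), sort_keys=False))
        with open(path, "w") as fh:
            fh.write(text)

    @classmethod
    def load(cls, path: str) -> "ArchSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls.from_dict(d)


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def conv_output_shape(in_shape: FeatureShape, kernel: int, stride: int,
                      padding: int, out_channels: int | None = None,
                      layer: str = "conv") -> FeatureShape:
    """Floor-mode convolution output geometry."""
    if kernel <= 0 or stride <= 0 or padding < 0:
        raise ArchError(f"{layer}: non-positive conv geometry arguments")
    h = (in_shape.height + 2 * padding - kernel) // stride + 1
    w = (in_shape.width + 2 * padding - kernel) // stride + 1
    if h <= 0 or w <= 0:
        raise ArchError(f"{layer}: computed non-positive output size {h}x{w}")
    return FeatureShape(h, w, out_channels if out_channels is not None
                        else in_shape.channels, in_shape.stride * stride)


def _scale(c: int, width_mult: float) -> int:
    if width_mult == 1.0:
        return c
    return max(4, int(round(c * width_mult / 4)) * 4)


# ---------------------------------------------------------------------------
# Variant construction
# ---------------------------------------------------------------------------

def _backbone_plan(variant: str):
    """Return (kernel, widths, c2f_repeats, neck_repeats, six_stage, width)."""
    if variant in ("baseline", "kernel7", "hyper"):
        k = 3 if variant == "baseline" else 7
        widths = [16, 32, 64, 128, 256]
        reps = [1, 2, 2, 1]
        return k, widths, reps, 1, False, 1.0
    if variant in ("extraconv", "full_p6"):
        w = 0.5 if variant == "extraconv" else 1.0
        widths = [64, 128, 256, 512, 1024, 2048]
        reps = [3, 6, 6, 3]
        return 7, widths, reps, 3, True, w
    raise ArchError(f"unknown variant {variant!r}")


def make_arch_spec(variant: str, input_size: int = 640, num_classes: int = 15,
                   reg_max: int = 16, width_mult: float = 1.0) -> ArchSpec:
    """Build the declarative layer list for a named variant.

    ``width_mult`` scales every channel count (after the variant's own width)
    and is how desk-scale "tiny" models are configured.
    """
    k, widths, reps, neck_n, six, vw = _backbone_plan(variant)
    wm = vw * width_mult
    widths = [_scale(c, wm) for c in widths]
    L: list[LayerSpec] = []
    idx = 0

    def add(source, op, kernel=0, stride=1, padding=0, cout=0, repeats=1, notes=""):
        nonlocal idx
        idx += 1
        L.append(LayerSpec(idx, source, op, kernel, stride, padding, cout,
                           repeats, notes))
        return idx

    if six:
        # three stride-2 convs, then alternating C2f / stride-2 conv, SPPF last
        c1 = add(0, "conv_block", k, 2, k // 2, widths[0], notes="P1")
        c2 = add(c1, "conv_block", k, 2, k // 2, widths[1], notes="P2")
        c3 = add(c2, "conv_block", k, 2, k // 2, widths[2], notes="P3")
        f3 = add(c3, "c2f", cout=widths[2], repeats=reps[0], notes="feature refinement")
        c4 = add(f3, "conv_block", k, 2, k // 2, widths[3], notes="P4")
        f4 = add(c4, "c2f", cout=widths[3], repeats=reps[1], notes="deep features")
        c5 = add(f4, "conv_block", k, 2, k // 2, widths[4], notes="P5")
        f5 = add(c5, "c2f", cout=widths[4], repeats=reps[2], notes="high-level semantics")
        c6 = add(f5, "conv_block", k, 2, k // 2, widths[5], notes="P6")
        f6 = add(c6, "c2f", cout=widths[5], repeats=reps[3], notes="very deep features")
        sp = add(f6, "sppf", kernel=5, cout=widths[5], notes="multi-scale pooling")
        p_lo, p_mid, p_hi = f4, f5, sp            # strides 16 / 32 / 64
        c_lo, c_mid, c_hi = widths[3], widths[4], widths[5]
        detect_strides = [16, 32, 64]
    else:
        c1 = add(0, "conv_block", k, 2, k // 2, widths[0], notes="P1")
        c2 = add(c1, "conv_block", k, 2, k // 2, widths[1], notes="P2")
        f2 = add(c2, "c2f", cout=widths[1], repeats=reps[0])
        c3 = add(f2, "conv_block", k, 2, k // 2, widths[2], notes="P3")
        f3 = add(c3, "c2f", cout=widths[2], repeats=reps[1])
        c4 = add(f3, "conv_block", k, 2, k // 2, widths[3], notes="P4")
        f4 = add(c4, "c2f", cout=widths[3], repeats=reps[2])
        c5 = add(f4, "conv_block", k, 2, k // 2, widths[4], notes="P5")
        f5 = add(c5, "c2f", cout=widths[4], repeats=reps[3])
        sp = add(f5, "sppf", kernel=5, cout=widths[4], notes="multi-scale pooling")
        p_lo, p_mid, p_hi = f3, f4, sp            # strides 8 / 16 / 32
        c_lo, c_mid, c_hi = widths[2], widths[3], widths[4]
        detect_strides = [8, 16, 32]

    # PAN-FPN neck: top-down (2x upsample+concat+C2f), bottom-up
    # (2x stride-2 conv+concat+C2f); three heads, the last fed by SPPF concat.
    u1 = add(p_hi, "upsample", notes="x2 nearest")
    t1 = add([u1, p_mid], "concat")
    n1 = add(t1, "c2f", cout=c_mid, repeats=neck_n, notes="td mid")
    u2 = add(n1, "upsample", notes="x2 nearest")
    t2 = add([u2, p_lo], "concat")
    n2 = add(t2, "c2f", cout=c_lo, repeats=neck_n, notes="td small")
    add(n2, "detect_head", notes="Detect1")
    d1 = add(n2, "conv_block", 3, 2, 1, c_lo, notes="bu downsample")
    t3 = add([d1, n1], "concat")
    n3 = add(t3, "c2f", cout=c_mid, repeats=neck_n, notes="bu mid")
    add(n3, "detect_head", notes="Detect2")
    d2 = add(n3, "conv_block", 3, 2, 1, c_mid, notes="bu downsample")
    t4 = add([d2, p_hi], "concat")
    n4 = add(t4, "c2f", cout=c_hi, repeats=neck_n, notes="bu large")
    add(n4, "detect_head", notes="Detect3")

    spec = ArchSpec(variant=variant, input_size=input_size, layers=L,
                    detect_strides=detect_strides, num_classes=num_classes,
                    reg_max=reg_max, width_mult=width_mult)
    _check_invariants(spec)
    return spec


def _check_invariants(spec: ArchSpec):
    n_s2 = sum(1 for l in spec.layers
               if l.op_kind == "conv_block" and l.stride == 2 and "bu" not in l.notes)
    heads = sum(1 for l in spec.layers if l.op_kind == "detect_head")
    if heads != 3:
        raise ArchError(f"{spec.variant}: expected 3 detect heads, got {heads}")
    shapes = trace_shapes(spec)
    deepest = max(s.stride for s in shapes.values())
    if spec.variant == "full_p6" and (n_s2 != 6 or deepest != 64):
        raise ArchError("full_p6 must have six stride-2 stages, deepest stride 64")
    if spec.variant == "baseline" and (n_s2 != 5 or deepest != 32):
        raise ArchError("baseline must have five stride-2 stages, deepest stride 32")


# ---------------------------------------------------------------------------
# Shape tracing
# ---------------------------------------------------------------------------

def trace_shapes(spec: ArchSpec) -> dict[int, FeatureShape]:
    """Propagate feature geometry through every layer (index -> shape)."""
    shapes = {0: FeatureShape(spec.input_size, spec.input_size, 3, 1)}
    for l in spec.layers:
        srcs = l.source if isinstance(l.source, list) else [l.source]
        ins = [shapes[s] for s in srcs]
        if l.op_kind == "conv_block":
            shapes[l.index] = conv_output_shape(ins[0], l.kernel, l.stride,
                                                l.padding, l.out_channels,
                                                layer=f"layer {l.index}")
        elif l.op_kind in ("c2f", "sppf"):
            s = ins[0]
            shapes[l.index] = FeatureShape(s.height, s.width, l.out_channels, s.stride)
        elif l.op_kind == "upsample":
            s = ins[0]
            shapes[l.index] = FeatureShape(s.height * 2, s.width * 2, s.channels,
                                           max(1, s.stride // 2))
        elif l.op_kind == "concat":
            if len({i.spatial() for i in ins}) != 1:
                raise ArchError(
                    f"layer {l.index}: concat operands differ spatially: "
                    + ", ".join(f"{i.height}x{i.width}" for i in ins))
            shapes[l.index] = FeatureShape(ins[0].height, ins[0].width,
                                           sum(i.channels for i in ins),
                                           ins[0].stride)
        elif l.op_kind == "detect_head":
            s = ins[0]
            shapes[l.index] = FeatureShape(
                s.height, s.width, 4 * spec.reg_max + spec.num_classes, s.stride)
        else:
            raise ArchError(f"layer {l.index}: unknown op {l.op_kind!r}")
    return shapes


def build_backbone(spec: ArchSpec) -> list[tuple[LayerSpec, FeatureShape]]:
    """Backbone rows (through SPPF) paired with their traced output shapes."""
    shapes = trace_shapes(spec)
    out = []
    for l in spec.layers:
        out.append((l, shapes[l.index]))
        if l.op_kind == "sppf":
            break
    return out


def build_neck_and_heads(spec: ArchSpec) -> list[tuple[LayerSpec, FeatureShape]]:
    """Neck + head rows with shapes; validates concat compatibility."""
    shapes = trace_shapes(spec)
    past_sppf = False
    out = []
    for l in spec.layers:
        if past_sppf:
            out.append((l, shapes[l.index]))
        if l.op_kind == "sppf":
            past_sppf = True
    head_strides = [s.stride for (l, s) in out if l.op_kind == "detect_head"]
    if head_strides != sorted(spec.detect_strides):
        raise ArchError(f"head strides {head_strides} != declared "
                        f"{spec.detect_strides}")
    return out


# ---------------------------------------------------------------------------
# Cost model
# ---------------------------------------------------------------------------

@dataclass
class _Prim:
    """A primitive convolution: the unit of parameter/FLOP accounting."""
    cin: int
    cout: int
    k: int
    h: int
    w: int
    bias: bool = False
    bn: bool = True

    @property
    def params(self) -> int:
        p = self.k * self.k * self.cin * self.cout
        if self.bias:
            p += self.cout
        if self.bn:
            p += 2 * self.cout
        return p

    @property
    def flops(self) -> float:
        # 2 x multiply-accumulates of the convolution; BN folded, act ignored
        return 2.0 * self.k ** 2 * self.cin * self.cout * self.h * self.w


def expand_primitives(spec: ArchSpec) -> list[_Prim]:
    """Expand composite blocks into their primitive convolutions."""
    shapes = trace_shapes(spec)
    prims: list[_Prim] = []
    for l in spec.layers:
        srcs = l.source if isinstance(l.source, list) else [l.source]
        cin = (sum(shapes[s].channels for s in srcs) if isinstance(l.source, list)
               else shapes[srcs[0]].channels)
        h, w = shapes[l.index].height, shapes[l.index].width
        if l.op_kind == "conv_block":
            prims.append(_Prim(cin, l.out_channels, l.kernel, h, w))
        elif l.op_kind == "c2f":
            c = l.out_channels // 2
            prims.append(_Prim(cin, 2 * c, 1, h, w))
            for _ in range(l.repeats):
                prims.append(_Prim(c, c, 3, h, w))
                prims.append(_Prim(c, c, 3, h, w))
            prims.append(_Prim((2 + l.repeats) * c, l.out_channels, 1, h, w))
        elif l.op_kind == "sppf":
            c = cin // 2
            prims.append(_Prim(cin, c, 1, h, w))
            prims.append(_Prim(4 * c, l.out_channels, 1, h, w))
        elif l.op_kind == "detect_head":
            prims.append(_Prim(cin, cin, 3, h, w))
            prims.append(_Prim(cin, cin, 3, h, w))
            prims.append(_Prim(cin, 4 * spec.reg_max + spec.num_classes, 1,
                               h, w, bias=True, bn=False))
        # upsample / concat carry no parameters or MACs
    return prims


def count_params_and_flops(spec: ArchSpec, input_size: int | None = None
                           ) -> tuple[int, float]:
    """Exact trainable-scalar count and conv GFLOPs at the given input size.

    Convention: FLOPs = 2 x conv multiply-accumulates, batch-norm folded,
    activations and pooling ignored.
    """
    if input_size is not None and input_size != spec.input_size:
        spec = ArchSpec(variant=spec.variant, input_size=input_size,
                        layers=spec.layers, detect_strides=spec.detect_strides,
                        num_classes=spec.num_classes, reg_max=spec.reg_max,
                        width_mult=spec.width_mult)
    prims = expand_primitives(spec)
    return (sum(p.params for p in prims),
            sum(p.flops for p in prims) / 1e9)


# ---------------------------------------------------------------------------
# Summary table
# ---------------------------------------------------------------------------

def arch_summary(spec: ArchSpec) -> dict:
    """Layer table (index, from, op, k/s, HxWxC, stride) plus cost totals."""
    shapes = trace_shapes(spec)
    rows = [{"layer": 0, "from": "-", "op": "Input", "kernel": "-", "stride_conv": "-",
             "output": f"{spec.input_size}x{spec.input_size}x3", "stride": 1,
             "notes": "input"}]
    for l in spec.layers:
        s = shapes[l.index]
        rows.append({
            "layer": l.index,
            "from": str(l.source),
            "op": {"conv_block": "Conv", "c2f": f"C2f x{l.repeats}",
                   "sppf": "SPPF", "upsample": "Upsample", "concat": "Concat",
                   "detect_head": "Detect"}[l.op_kind],
            "kernel": f"{l.kernel}x{l.kernel}" if l.kernel else "-",
            "stride_conv": str(l.stride) if l.op_kind == "conv_block" else "-",
            "output": f"{s.height}x{s.width}x{s.channels}",
            "stride": s.stride,
            "notes": l.notes,
        })
    params, gflops = count_params_and_flops(spec)
    return {"variant": spec.variant, "input_size": spec.input_size,
            "rows": rows, "params": params, "gflops": round(gflops, 2),
            "detect_strides": spec.detect_strides}


def format_summary(summary: dict) -> str:
    cols = ["layer", "from", "op", "kernel", "stride_conv", "output", "stride", "notes"]
    head = ["Layer", "From", "Operation", "Kernel", "S", "Output (HxWxC)", "Stride", "Notes"]
    widths = [max(len(h), max(len(str(r[c])) for r in summary["rows"]))
              for c, h in zip(cols, head)]
    lines = ["  ".join(h.ljust(w) for h, w in zip(head, widths))]
    for r in summary["rows"]:
        lines.append("  ".join(str(r[c]).ljust(w) for c, w in zip(cols, widths)))
    lines.append(f"params: {summary['params']:,}   GFLOPs: {summary['gflops']}   "
                 f"heads at strides {summary['detect_strides']}")
    return "\n".join(lines)
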