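"""The FlowerNet counting network.

Architecture, front to back:

* **Backbone** — the first 13 convolutional layers of VGG16 (3×3 convs,
  2×2 max pooling).  Feature maps are tapped at the end of blocks 2–5,
  just before each pooling step: C2 (128 ch, stride 2), C3 (256 ch,
  stride 4), C4 (512 ch, stride 8), C5 (512 ch, stride 16).
* **Panoptic-pyramid fusion** — each tap is unified to ``fusion_channels``
  by a 1×1 convolution; deeper levels are brought to C2's resolution by
  repeated (3×3 conv → nearest ×2 upsample) stages, one repetition per
  octave; the aligned maps are summed and refined by a 3×3 then a 1×1
  convolution, giving a single fused map at stride 2.
* **DMN head** — two branches share the fused map.  The mask branch
  (plain conv→pool downsampling) emits a per-pixel foreground
  probability through a sigmoid; the density branch (MP-module
  downsampling) emits a non-negative flower density through a ReLU.
  Both land at ``output_stride`` (default 8).
* **Mask gating** — at prediction time the mask probability is
  binarised at ``mask_threshold`` and multiplied elementwise into the
  density map; the gated map's sum is the flower count.  Gating zeroes
  spurious density in background regions.

The MP module is a dual-branch downsampler: 2×2 max pool followed by a
1×1 conv to C/2 channels, in parallel with a 1×1 conv to C/2 followed by
a stride-2 3×3 conv, concatenated back to C channels at half resolution.

All forward passes cache what their backward needs; the ``backward``
methods propagate loss gradients through the same graph by hand.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .data_io import ImageRecord, PanicleInstanceMask, apply_panicle_mask
from .labelgen import BinaryMask, DensityMap
from .nn import Conv2d, MaxPool2, NearestUp2, Param, ReLU, Sigmoid, F32

CONV_POOL = "conv_pool"
MP = "mp"


@dataclass
class FlowerNetConfig:
    """Architecture switches; defaults are the full FlowerNet."""

    fusion_channels: int = 256
    use_multiscale: bool = True
    use_mask_branch: bool = True
    mask_branch_downsampling: str = CONV_POOL
    density_branch_downsampling: str = MP
    output_stride: int = 8
    mask_threshold: float = 0.5
    input_channels: int = 3

    def __post_init__(self):
        if self.fusion_channels not in (128, 256):
            raise ValueError("fusion_channels must be 128 or 256")
        s = self.output_stride
        if s < 2 or (s & (s - 1)) != 0:
            raise ValueError("output_stride must be a power of 2, ≥ 2")
        if not 0.0 < self.mask_threshold < 1.0:
            raise ValueError("mask_threshold must be in (0, 1)")
        for v in (self.mask_branch_downsampling,
                  self.density_branch_downsampling):
            if v not in (CONV_POOL, MP):
                raise ValueError(f"unknown downsampling mode {v!r}")


@dataclass
class FeaturePyramid:
    """Backbone taps; channel counts fixed by the VGG16 block widths."""

    C2: np.ndarray  # 128 ch, stride 2
    C3: np.ndarray  # 256 ch, stride 4
    C4: np.ndarray  # 512 ch, stride 8
    C5: np.ndarray  # 512 ch, stride 16


@dataclass
class PredictionPair:
    """Raw head outputs plus the binarised mask, all at output stride."""

    mask_prob: np.ndarray | None
    density: np.ndarray
    x_mask: np.ndarray


# ---------------------------------------------------------------------------

_VGG_PLAN = (  # (block channel width, number of 3×3 convs), taps after blocks 2-5
    (64, 2), (128, 2), (256, 3), (512, 3), (512, 3))


class Backbone:
    """First 13 VGG16 conv layers with taps before each downsampling."""

    MIN_INPUT = 32

    def __init__(self, input_channels: int = 3):
        self.ops: list = []
        self.tap_at: dict[int, str] = {}
        cin = input_channels
        for bi, (width, n_convs) in enumerate(_VGG_PLAN):
            if bi > 0:
                self.ops.append(MaxPool2())
            for _ in range(n_convs):
                self.ops.append(Conv2d(cin, width, 3))
                self.ops.append(ReLU())
                cin = width
            if bi >= 1:  # C2..C5, taken before the next pool
                self.tap_at[len(self.ops)] = f"C{bi + 1}"

    def params(self):
        out = []
        for i, op in enumerate(self.ops):
            for nm, p in op.params():
                out.append((f"backbone.{i}.{nm}", p))
        return out

    def forward(self, x: np.ndarray) -> FeaturePyramid:
        if x.shape[2] < self.MIN_INPUT or x.shape[3] < self.MIN_INPUT:
            raise ValueError(
                f"input must be at least {self.MIN_INPUT}×{self.MIN_INPUT}")
        taps = {}
        for i, op in enumerate(self.ops):
            x = op.forward(x)
            if i + 1 in self.tap_at:
                taps[self.tap_at[i + 1]] = x
        return FeaturePyramid(**taps)

    def backward(self, dtaps: dict[str, np.ndarray]) -> np.ndarray:
        dy: np.ndarray | None = None
        for i in range(len(self.ops) - 1, -1, -1):
            if i + 1 in self.tap_at:
                g = dtaps.get(self.tap_at[i + 1])
                if g is not None:
                    dy = g if dy is None else dy + g
            if dy is not None:  # ops deeper than the deepest used tap
                dy = self.ops[i].backward(dy)
        return dy


class PyramidFusion:
    """Panoptic-pyramid fusion down to a stride-2 fused map."""

    TAP_CHANNELS = {"C2": 128, "C3": 256, "C4": 512, "C5": 512}

    def __init__(self, cfg: FlowerNetConfig):
        self.cfg = cfg
        fc = cfg.fusion_channels
        self.levels = ["C2", "C3", "C4", "C5"] if cfg.use_multiscale else ["C2"]
        self.lateral = {lv: Conv2d(self.TAP_CHANNELS[lv], fc, 1, pad=0)
                        for lv in self.levels}
        # level C{k} needs k-2 (conv → relu → up) repetitions to reach C2
        self.upstages = {
            lv: [(Conv2d(fc, fc, 3), ReLU(), NearestUp2())
                 for _ in range(int(lv[1]) - 2)]
            for lv in self.levels}
        self.f = Conv2d(fc, fc, 3)
        self.f_relu = ReLU()
        self.f1x1 = Conv2d(fc, fc, 1, pad=0)
        self.out_relu = ReLU()

    def params(self):
        out = []
        for lv in self.levels:
            out += [(f"fusion.lateral.{lv}.{nm}", p)
                    for nm, p in self.lateral[lv].params()]
            for si, (conv, _, _) in enumerate(self.upstages[lv]):
                out += [(f"fusion.up.{lv}.{si}.{nm}", p)
                        for nm, p in conv.params()]
        out += [(f"fusion.f.{nm}", p) for nm, p in self.f.params()]
        out += [(f"fusion.f1x1.{nm}", p) for nm, p in self.f1x1.params()]
        return out

    def forward(self, pyr: FeaturePyramid) -> np.ndarray:
        taps = {"C2": pyr.C2, "C3": pyr.C3, "C4": pyr.C4, "C5": pyr.C5}
        # target sizes for successive doublings: C5→C4's→C3's→C2's
        sizes = {lv: taps[lv].shape[2:] for lv in self.TAP_CHANNELS}
        total = None
        for lv in self.levels:
            x = self.lateral[lv].forward(taps[lv])
            k = int(lv[1])
            for si, (conv, relu, up) in enumerate(self.upstages[lv]):
                x = relu.forward(conv.forward(x))
                x = up.forward(x, target_hw=sizes[f"C{k - 1 - si}"])
            total = x if total is None else total + x
        y = self.f_relu.forward(self.f.forward(total))
        return self.out_relu.forward(self.f1x1.forward(y))

    def backward(self, dy: np.ndarray) -> dict[str, np.ndarray]:
        dy = self.f1x1.backward(self.out_relu.backward(dy))
        dtotal = self.f.backward(self.f_relu.backward(dy))
        dtaps: dict[str, np.ndarray] = {}
        for lv in self.levels:
            d = dtotal
            for conv, relu, up in reversed(self.upstages[lv]):
                d = conv.backward(relu.backward(up.backward(d)))
            dtaps[lv] = self.lateral[lv].backward(d)
        return dtaps


class MPModule:
    """Dual-branch (max-pool ∥ strided-conv) downsampler, channel-preserving."""

    def __init__(self, channels: int):
        if channels % 2:
            raise ValueError("MP module needs an even channel count")
        half = channels // 2
        self.channels = channels
        self.pool = MaxPool2()
        self.conv_a = Conv2d(channels, half, 1, pad=0)
        self.relu_a = ReLU()
        self.conv_b1 = Conv2d(channels, half, 1, pad=0)
        self.relu_b1 = ReLU()
        self.conv_b2 = Conv2d(half, half, 3, stride=2)
        self.relu_b2 = ReLU()

    def params(self):
        out = []
        for nm, sub in (("a", self.conv_a), ("b1", self.conv_b1),
                        ("b2", self.conv_b2)):
            out += [(f"{nm}.{pn}", p) for pn, p in sub.params()]
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[2] < 2 or x.shape[3] < 2:
            raise ValueError("MP module needs spatial dims ≥ 2")
        a = self.relu_a.forward(self.conv_a.forward(self.pool.forward(x)))
        b = self.relu_b1.forward(self.conv_b1.forward(x))
        b = self.relu_b2.forward(self.conv_b2.forward(b))
        if a.shape[2:] != b.shape[2:]:  # both are ceil(H/2); guard regardless
            b = b[:, :, :a.shape[2], :a.shape[3]]
        return np.concatenate([a, b], axis=1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        half = self.channels // 2
        da, db = dy[:, :half], dy[:, half:]
        dx = self.pool.backward(self.conv_a.backward(self.relu_a.backward(da)))
        db = self.conv_b2.backward(self.relu_b2.backward(db))
        dx = dx + self.conv_b1.backward(self.relu_b1.backward(db))
        return dx


class _Stage:
    """One downsampling stage of a head branch (conv-pool or MP flavour)."""

    def __init__(self, mode: str, cin: int, cout: int):
        self.mode = mode
        if mode == CONV_POOL:
            self.conv = Conv2d(cin, cout, 3)
            self.relu = ReLU()
            self.pool = MaxPool2()
        else:
            self.mp = MPModule(cin)
            self.conv = Conv2d(cin, cout, 3)
            self.relu = ReLU()

    def params(self):
        out = [(f"conv.{nm}", p) for nm, p in self.conv.params()]
        if self.mode == MP:
            out += [(f"mp.{nm}", p) for nm, p in self.mp.params()]
        return out

    def forward(self, x):
        if self.mode == CONV_POOL:
            return self.pool.forward(self.relu.forward(self.conv.forward(x)))
        return self.relu.forward(self.conv.forward(self.mp.forward(x)))

    def backward(self, dy):
        if self.mode == CONV_POOL:
            return self.conv.backward(self.relu.backward(self.pool.backward(dy)))
        return self.mp.backward(self.conv.backward(self.relu.backward(dy)))


class Branch:
    """A DMN branch: downsampling stages then a 1×1 projection + squash."""

    WIDTHS = (128, 64, 32, 32)

    def __init__(self, name: str, mode: str, cin: int, n_stages: int,
                 output_activation):
        self.name = name
        self.stages = []
        widths = self.WIDTHS[:n_stages]
        for w in widths:
            self.stages.append(_Stage(mode, cin, w))
            cin = w
        self.out_conv = Conv2d(cin, 1, 1, pad=0)
        self.out_act = output_activation

    def params(self):
        out = []
        for si, st in enumerate(self.stages):
            out += [(f"{self.name}.{si}.{nm}", p) for nm, p in st.params()]
        out += [(f"{self.name}.out.{nm}", p) for nm, p in self.out_conv.params()]
        return out

    def forward(self, x):
        for st in self.stages:
            x = st.forward(x)
        return self.out_act.forward(self.out_conv.forward(x))

    def backward(self, dy):
        dy = self.out_conv.backward(self.out_act.backward(dy))
        for st in reversed(self.stages):
            dy = st.backward(dy)
        return dy


class FlowerNet:
    """Backbone + fusion + DMN; see the module docstring for the wiring."""

    def __init__(self, config: FlowerNetConfig | None = None):
        self.config = config or FlowerNetConfig()
        cfg = self.config
        self.backbone = Backbone(cfg.input_channels)
        self.fusion = PyramidFusion(cfg)
        n_stages = int(np.log2(cfg.output_stride)) - 1  # fused map is stride 2
        fc = cfg.fusion_channels
        self.density_branch = Branch("density", cfg.density_branch_downsampling,
                                     fc, n_stages, ReLU())
        self.mask_branch = (Branch("mask", cfg.mask_branch_downsampling,
                                   fc, n_stages, Sigmoid())
                            if cfg.use_mask_branch else None)

    # -- parameters -------------------------------------------------------
    def parameters(self) -> list[tuple[str, Param]]:
        out = self.backbone.params() + self.fusion.params()
        if self.mask_branch is not None:
            out += self.mask_branch.params()
        out += self.density_branch.params()
        return out

    # -- forward / backward ----------------------------------------------
    def forward(self, x: np.ndarray) -> tuple[np.ndarray | None, np.ndarray]:
        """x: (N, 3, H, W) float32 in [0, 1] → (mask_prob, density)."""
        pyr = self.backbone.forward(np.ascontiguousarray(x, dtype=F32))
        fused = self.fusion.forward(pyr)
        density = self.density_branch.forward(fused)
        mask_prob = (self.mask_branch.forward(fused)
                     if self.mask_branch is not None else None)
        return mask_prob, density

    def backward(self, dmask_prob: np.ndarray | None,
                 ddensity: np.ndarray) -> None:
        dfused = self.density_branch.backward(ddensity)
        if self.mask_branch is not None and dmask_prob is not None:
            dfused = dfused + self.mask_branch.backward(dmask_prob)
        dtaps = self.fusion.backward(dfused)
        self.backbone.backward(dtaps)

    # -- persistence ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        arrays = {name: p.value for name, p in self.parameters()}
        arrays["__config__"] = np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "FlowerNet":
        with np.load(path) as data:
            cfg = FlowerNetConfig(**json.loads(bytes(data["__config__"])))
            model = cls(cfg)
            for name, p in model.parameters():
                p.value[...] = data[name]
        return model


# ---------------------------------------------------------------------------
# prediction

def normalize_image(image: ImageRecord) -> np.ndarray:
    """uint8 H×W×3 → (1, 3, H, W) float32 in [0, 1]."""
    x = image.pixels.astype(F32) / F32(255.0)
    return np.ascontiguousarray(x.transpose(2, 0, 1)[None])


def gate_density(density: np.ndarray, x_mask: np.ndarray) -> np.ndarray:
    """Elementwise mask gating: density where mask is 1, else exactly 0."""
    if density.shape != x_mask.shape:
        raise ValueError("density and mask shapes differ")
    return np.where(x_mask == 1, density, 0.0)


def predict_pair(model: FlowerNet, x: np.ndarray) -> PredictionPair:
    """Forward one normalized batch and binarise the mask output."""
    mask_prob, density = model.forward(x)
    if mask_prob is not None:
        x_mask = (mask_prob >= model.config.mask_threshold).astype(np.uint8)
    else:
        x_mask = np.ones_like(density, dtype=np.uint8)
    return PredictionPair(mask_prob, density, x_mask)


def predict_count(model: FlowerNet, image: ImageRecord,
                  panicle_mask: PanicleInstanceMask | None = None,
                  pad: int = 0) -> tuple[DensityMap, BinaryMask, float]:
    """Count flowers in one image via the mask-gated density map.

    If an externally produced panicle instance mask is supplied, the
    image is first cropped to that panicle (background zeroed), matching
    the two-stage framework.
    """
    if panicle_mask is not None:
        image = apply_panicle_mask(image, panicle_mask, pad=pad)
    pair = predict_pair(model, normalize_image(image))
    final = gate_density(pair.density[0, 0].astype(np.float64),
                         pair.x_mask[0, 0])
    return (DensityMap(final, sigma=0.0), BinaryMask(pair.x_mask[0, 0]),
            float(final.sum()))


def predict_count_tiled(model: FlowerNet, image: ImageRecord,
                        grid: tuple[int, int] = (3, 3)) -> float:
    """Count by tiling the image into grid blocks and summing block counts.

    Mirrors the 9-block protocol used in training, so the network sees
    the same zero-padded context it was optimised on.  At deployment
    scale, whole-image prediction (:func:`predict_count`) is the normal
    path; block-summed prediction matters for small images, where the
    backbone's receptive field exceeds the training-block size and
    whole-image activations drift from the training distribution.
    """
    from .data_io import PointAnnotationSet, split_into_patches

    empty = PointAnnotationSet(image.id, [], image.shape)
    total = 0.0
    for block, _ in split_into_patches(image, empty, grid):
        _, _, count = predict_count(model, block)
        total += count
    return total
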