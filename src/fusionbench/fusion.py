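"""Single-fusion-point UNet family for two-modality segmentation.

Every member of the family is a UNet-style encoder/decoder that combines a
reference-modality volume and a secondary-modality volume at exactly one
point:

* ``baseline_ref`` / ``baseline_sec`` — single-modality networks (no fusion);
* ``input_concat`` — the two images stacked as channels before the network;
* ``block_concat`` at block *i* — two parallel modality streams, merged by
  channel concatenation inside block *i*;
* ``logit_average`` — two complete single-modality networks whose
  pre-activation class scores are averaged.

Blocks are numbered 1..2·depth over the ordered list
``encoder_1 .. encoder_{depth-1}, bottleneck, decoder_1 .. decoder_{depth-1},
head``.  Each non-head block is two 3x3 convolutions, each followed
by instance normalization and LeakyReLU; decoder
blocks upsample and concatenate the matching encoder skip first; the head is
a single 1x1 convolution producing ``out_classes`` score maps.

Fusion inside a block happens between the block's two convolutions: each
stream applies its own copy of the first convolution (with its norm and
activation), the resulting feature maps are concatenated, and the second
convolution (with doubled input
channels) plus all later blocks run as a single stream.  Even the earliest
block-level fusion therefore operates on learned features, which is what
distinguishes it from naive image concatenation.  The head has a single
convolution, so head-level fusion concatenates the two decoder outputs into
a doubled-width head.  After fusion, decoder blocks take their skip
connections from the reference-modality stream by default
(``skip_policy="ref"``); ``"both-concat"`` concatenates both streams' skips
instead.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np

from .nn import autodiff as ad

__all__ = [
    "FusionConfig",
    "FusionNet",
    "enumerate_family",
    "build_model",
    "predict_mask",
]

MODES = ("baseline_ref", "baseline_sec", "input_concat", "block_concat",
         "logit_average")


@dataclass(frozen=True)
class FusionConfig:
    """Declarative description of one family member."""

    mode: str
    block_index: Optional[int] = None
    depth: int = 4
    base_channels: int = 8
    spatial_dims: int = 2
    out_classes: int = 2
    skip_policy: str = "ref"

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown fusion mode {self.mode!r}")
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.spatial_dims not in (2, 3):
            raise ValueError("spatial_dims must be 2 or 3")
        if self.skip_policy not in ("ref", "both-concat"):
            raise ValueError(f"unknown skip_policy {self.skip_policy!r}")
        n_blocks = 2 * self.depth
        if self.mode == "block_concat":
            if self.block_index is None:
                raise ValueError("block_concat requires block_index")
            if not (1 <= self.block_index <= n_blocks):
                raise ValueError(
                    f"block_index {self.block_index} outside [1, {n_blocks}]")
        elif self.block_index is not None:
            raise ValueError(f"block_index is only valid for block_concat")

    @property
    def n_blocks(self) -> int:
        return 2 * self.depth

    def block_label(self, b: int) -> str:
        d = self.depth
        if b <= d - 1:
            return f"enc{b}"
        if b == d:
            return "bottleneck"
        if b <= 2 * d - 1:
            return f"dec{b - d}"
        return "head"

    @property
    def name(self) -> str:
        if self.mode == "block_concat":
            return f"block_concat_{self.block_label(self.block_index)}"
        return self.mode

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FusionConfig":
        return cls(**d)


def enumerate_family(depth: int, spatial_dims: int = 2,
                     base_channels: int = 8, out_classes: int = 2,
                     skip_policy: str = "ref") -> list[FusionConfig]:
    """The complete, duplicate-free family at a given depth.

    Stable order: the two single-modality baselines, input concatenation,
    one block-concatenation variant per block (in block order), and logit
    averaging — ``2 + 1 + 2*depth + 1`` configurations in total.
    """
    if depth < 2:
        raise ValueError("depth must be >= 2")
    kw = dict(depth=depth, spatial_dims=spatial_dims,
              base_channels=base_channels, out_classes=out_classes,
              skip_policy=skip_policy)
    fam = [FusionConfig(mode="baseline_ref", **kw),
           FusionConfig(mode="baseline_sec", **kw),
           FusionConfig(mode="input_concat", **kw)]
    fam += [FusionConfig(mode="block_concat", block_index=b, **kw)
            for b in range(1, 2 * depth + 1)]
    fam.append(FusionConfig(mode="logit_average", **kw))
    return fam


# ---------------------------------------------------------------------------
# block table and parameter specification


def _block_table(cfg: FusionConfig) -> list[dict]:
    """Per-block wiring for a single 1-channel-input stream."""
    d = cfg.depth
    ch = [cfg.base_channels * 2 ** l for l in range(d)]
    blocks = []
    for b in range(1, d):           # encoders, levels 0..d-2
        lvl = b - 1
        blocks.append(dict(b=b, kind="enc", level=lvl,
                           in_ch=1 if b == 1 else ch[lvl - 1],
                           out_ch=ch[lvl], pre="pool" if b > 1 else "none"))
    blocks.append(dict(b=d, kind="bottleneck", level=d - 1,
                       in_ch=ch[d - 2], out_ch=ch[d - 1], pre="pool"))
    for j in range(1, d):           # decoders, levels d-2..0
        lvl = d - 1 - j
        blocks.append(dict(b=d + j, kind="dec", level=lvl,
                           in_ch=ch[lvl + 1], out_ch=ch[lvl], pre="up",
                           skip_level=lvl))
    blocks.append(dict(b=2 * d, kind="head", level=0, in_ch=ch[0],
                       out_ch=cfg.out_classes, pre="none"))
    return blocks


def _skip_is_joint(cfg: FusionConfig, level: int) -> bool:
    """After block-level fusion at index i, is the encoder skip at ``level``
    produced by the joint (post-fusion) stream?  Level l is produced by
    encoder block l+1."""
    assert cfg.mode == "block_concat"
    return (level + 1) >= cfg.block_index


def _param_spec(cfg: FusionConfig) -> dict[str, tuple]:
    """Ordered mapping of parameter name -> array shape.

    Every non-head convolution is conv + instance norm (affine), so each
    ``conv{A,B}`` entry is accompanied by a ``norm{A,B}`` gamma/beta pair.
    """
    nd = cfg.spatial_dims
    blocks = _block_table(cfg)
    spec: dict[str, tuple] = {}

    def add_conv(stem: str, part: str, out_ch: int, in_ch: int) -> None:
        spec[f"{stem}.conv{part}.w"] = (out_ch, in_ch) + (3,) * nd
        spec[f"{stem}.conv{part}.b"] = (out_ch,)
        spec[f"{stem}.norm{part}.g"] = (out_ch,)
        spec[f"{stem}.norm{part}.b"] = (out_ch,)

    def add_head(stem: str, out_ch: int, in_ch: int) -> None:
        spec[f"{stem}.head.w"] = (out_ch, in_ch) + (1,) * nd
        spec[f"{stem}.head.b"] = (out_ch,)

    def stream_in_ch(blk, in_img: int) -> int:
        if blk["b"] == 1:
            return in_img
        if blk["kind"] == "dec":
            return blk["in_ch"] + cfg.base_channels * 2 ** blk["skip_level"]
        return blk["in_ch"]

    def stream_spec(prefix: str, in_img: int) -> None:
        for blk in blocks:
            stem = f"{prefix}b{blk['b']}"
            if blk["kind"] == "head":
                add_head(stem, blk["out_ch"], blk["in_ch"])
            else:
                add_conv(stem, "A", blk["out_ch"], stream_in_ch(blk, in_img))
                add_conv(stem, "B", blk["out_ch"], blk["out_ch"])

    if cfg.mode in ("baseline_ref", "baseline_sec"):
        stream_spec("", 1)
    elif cfg.mode == "input_concat":
        stream_spec("", 2)
    elif cfg.mode == "logit_average":
        stream_spec("ref.", 1)
        stream_spec("sec.", 1)
    else:                                  # block_concat at index i
        i = cfg.block_index
        for blk in blocks:
            b, out_ch = blk["b"], blk["out_ch"]
            if b < i:
                for prefix in ("ref.", "sec."):
                    add_conv(f"{prefix}b{b}", "A", out_ch,
                             stream_in_ch(blk, 1))
                    add_conv(f"{prefix}b{b}", "B", out_ch, out_ch)
            elif b == i:
                if blk["kind"] == "head":
                    add_head(f"b{b}", out_ch, 2 * blk["in_ch"])
                    continue
                for prefix in ("ref.", "sec."):
                    add_conv(f"{prefix}b{b}", "A", out_ch,
                             stream_in_ch(blk, 1))
                add_conv(f"b{b}", "B", out_ch, 2 * out_ch)
            else:
                if blk["kind"] == "head":
                    add_head(f"b{b}", out_ch, blk["in_ch"])
                    continue
                in_ch = blk["in_ch"]
                if blk["kind"] == "dec":
                    lvl = blk["skip_level"]
                    ch = cfg.base_channels * 2 ** lvl
                    double = (not _skip_is_joint(cfg, lvl)
                              and cfg.skip_policy == "both-concat")
                    in_ch += 2 * ch if double else ch
                add_conv(f"b{b}", "A", out_ch, in_ch)
                add_conv(f"b{b}", "B", out_ch, out_ch)
    return spec


# ---------------------------------------------------------------------------
# the model


class FusionNet:
    """A concrete family member: parameters plus the forward contract.

    The forward contract maps ``(image_ref, image_sec)`` batches of shape
    ``(N, *spatial)`` to logits of shape ``(N, out_classes, *spatial)``;
    spatial extents must be divisible by ``2**(depth-1)``.
    """

    def __init__(self, config: FusionConfig, seed: int = 0,
                 dtype=np.float32):
        self.config = config
        self.dtype = dtype
        self._spec = _param_spec(config)
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        for name, shape in self._spec.items():
            if name.endswith(".b"):
                self.params[name] = np.zeros(shape, dtype=dtype)
            elif name.endswith(".g"):       # instance-norm gain
                self.params[name] = np.ones(shape, dtype=dtype)
            else:
                fan_in = int(np.prod(shape[1:]))
                std = np.sqrt(2.0 / fan_in)
                self.params[name] = (std * rng.standard_normal(shape)
                                     ).astype(dtype)

    # -- introspection ------------------------------------------------------

    @property
    def parameter_count(self) -> int:
        return sum(v.size for v in self.params.values())

    def layer_shapes(self) -> list[tuple[str, int, int, int]]:
        """Audit of every convolution as ``(name, in_ch, out_ch, kernel)``,
        traced from the actual parameter arrays."""
        out = []
        for name, arr in self.params.items():
            if name.endswith(".w"):
                out.append((name[:-2], arr.shape[1], arr.shape[0],
                            arr.shape[2]))
        return out

    def get_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = np.asarray(params[k], dtype=self.dtype).copy()

    # -- forward ------------------------------------------------------------

    def _wrap_params(self) -> dict[str, ad.Tensor]:
        return {k: ad.Tensor(v) for k, v in self.params.items()}

    @staticmethod
    def _cnl(p, stem: str, part: str, x: ad.Tensor) -> ad.Tensor:
        """conv -> instance norm -> LeakyReLU."""
        x = ad.conv(x, p[f"{stem}.conv{part}.w"], p[f"{stem}.conv{part}.b"])
        x = ad.instance_norm(x, p[f"{stem}.norm{part}.g"],
                             p[f"{stem}.norm{part}.b"])
        return ad.leaky_relu(x)

    def _two_conv(self, p, stem: str, x: ad.Tensor) -> ad.Tensor:
        return self._cnl(p, stem, "B", self._cnl(p, stem, "A", x))

    def _run_stream(self, p, prefix: str, x: ad.Tensor) -> ad.Tensor:
        """Full single-stream pass (used for baselines, input_concat and
        each half of logit_average)."""
        blocks = _block_table(self.config)
        skips: dict[int, ad.Tensor] = {}
        h = x
        for blk in blocks:
            b = blk["b"]
            if blk["kind"] == "head":
                return ad.conv(h, p[f"{prefix}b{b}.head.w"],
                               p[f"{prefix}b{b}.head.b"])
            if blk["pre"] == "pool":
                h = ad.maxpool2(h)
            elif blk["pre"] == "up":
                h = ad.concat([ad.upsample2(h), skips[blk["skip_level"]]])
            h = self._two_conv(p, f"{prefix}b{b}", h)
            if blk["kind"] == "enc":
                skips[blk["level"]] = h
        raise AssertionError("unreachable")

    def _run_fused(self, p, x_ref: ad.Tensor, x_sec: ad.Tensor) -> ad.Tensor:
        cfg = self.config
        i = cfg.block_index
        blocks = _block_table(cfg)
        skips = {"ref.": {}, "sec.": {}, "": {}}
        h = {"ref.": x_ref, "sec.": x_sec}

        def entry(blk, prefix, hh):
            """Apply the block's spatial pre-op and first convolution."""
            b = blk["b"]
            if blk["pre"] == "pool":
                hh = ad.maxpool2(hh)
            elif blk["pre"] == "up":
                hh = ad.concat([ad.upsample2(hh),
                                skips[prefix][blk["skip_level"]]])
            return self._cnl(p, f"{prefix}b{b}", "A", hh)

        joint: ad.Tensor | None = None
        for blk in blocks:
            b = blk["b"]
            if b < i:
                for prefix in ("ref.", "sec."):
                    a = entry(blk, prefix, h[prefix])
                    out = self._cnl(p, f"{prefix}b{b}", "B", a)
                    h[prefix] = out
                    if blk["kind"] == "enc":
                        skips[prefix][blk["level"]] = out
            elif b == i:
                if blk["kind"] == "head":
                    fused = ad.concat([h["ref."], h["sec."]])
                    return ad.conv(fused, p[f"b{b}.head.w"], p[f"b{b}.head.b"])
                fused = ad.concat([entry(blk, "ref.", h["ref."]),
                                   entry(blk, "sec.", h["sec."])])
                joint = self._cnl(p, f"b{b}", "B", fused)
                if blk["kind"] == "enc":
                    skips[""][blk["level"]] = joint
            else:
                if blk["kind"] == "head":
                    return ad.conv(joint, p[f"b{b}.head.w"], p[f"b{b}.head.b"])
                if blk["pre"] == "pool":
                    joint = ad.maxpool2(joint)
                elif blk["pre"] == "up":
                    lvl = blk["skip_level"]
                    if _skip_is_joint(cfg, lvl):
                        skip = skips[""][lvl]
                    elif cfg.skip_policy == "both-concat":
                        skip = ad.concat([skips["ref."][lvl], skips["sec."][lvl]])
                    else:
                        skip = skips["ref."][lvl]
                    joint = ad.concat([ad.upsample2(joint), skip])
                joint = self._two_conv(p, f"b{b}", joint)
                if blk["kind"] == "enc":
                    skips[""][blk["level"]] = joint
        raise AssertionError("unreachable")

    def forward(self, x_ref: np.ndarray, x_sec: np.ndarray,
                params: dict[str, ad.Tensor] | None = None) -> ad.Tensor:
        """Logits tensor for a batch; builds the autodiff graph."""
        p = params if params is not None else self._wrap_params()
        mode = self.config.mode
        xr = ad.constant(self._add_channel(x_ref))
        xs = ad.constant(self._add_channel(x_sec))
        if mode == "baseline_ref":
            return self._run_stream(p, "", xr)
        if mode == "baseline_sec":
            return self._run_stream(p, "", xs)
        if mode == "input_concat":
            return self._run_stream(p, "", ad.concat([xr, xs]))
        if mode == "logit_average":
            a = self._run_stream(p, "ref.", xr)
            b = self._run_stream(p, "sec.", xs)
            return (a + b) * 0.5
        return self._run_fused(p, xr, xs)

    def _add_channel(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == self.config.spatial_dims:      # single sample
            x = x[None]
        return x[:, None]                           # (N, 1, *spatial)

    def logits(self, x_ref: np.ndarray, x_sec: np.ndarray) -> np.ndarray:
        """Inference-mode forward; deterministic for fixed weights."""
        return self.forward(x_ref, x_sec).value

    # -- training interface -------------------------------------------------

    def loss_and_grads(self, x_ref, x_sec, target,
                       eps: float = 1e-5) -> tuple[float, dict[str, np.ndarray]]:
        """Soft-Dice loss on the foreground channel plus parameter grads."""
        from .training import _soft_dice_loss_graph

        p = self._wrap_params()
        logits = self.forward(x_ref, x_sec, params=p)
        loss = _soft_dice_loss_graph(logits, np.asarray(target), eps=eps)
        ad.backward(loss)
        grads = {k: (t.grad if t.grad is not None else np.zeros_like(t.value))
                 for k, t in p.items()}
        return loss.item(), grads


def build_model(config: FusionConfig, seed: int = 0,
                dtype=np.float32) -> FusionNet:
    """Construct the network a configuration describes."""
    return FusionNet(config, seed=seed, dtype=dtype)


def predict_mask(model: FusionNet, image_ref: np.ndarray,
                 image_sec: np.ndarray) -> np.ndarray:
    """Binary mask for one (preprocessed) volume or slice.

    For 2D models applied to 3D volumes, each axial slice (last axis) is
    segmented independently and the results are restacked.  Class scores are
    arg-maxed with background first, so exactly tied logits yield background.
    """
    cfg = model.config
    image_ref = np.asarray(image_ref)
    image_sec = np.asarray(image_sec)
    if image_ref.shape != image_sec.shape:
        raise ValueError("modality volumes must share one grid")
    if image_ref.ndim == cfg.spatial_dims:
        _check_divisible(image_ref.shape, cfg.depth)
        logits = model.logits(image_ref, image_sec)[0]
        return (np.argmax(logits, axis=0) == 1).astype(np.uint8)
    if cfg.spatial_dims == 2 and image_ref.ndim == 3:
        _check_divisible(image_ref.shape[:2], cfg.depth)
        nz = image_ref.shape[2]
        xr = np.moveaxis(image_ref, 2, 0)
        xs = np.moveaxis(image_sec, 2, 0)
        logits = model.logits(xr, xs)      # (nz, C, H, W)
        mask = (np.argmax(logits, axis=1) == 1).astype(np.uint8)
        return np.moveaxis(mask, 0, 2).reshape(image_ref.shape)
    raise ValueError(
        f"volume of rank {image_ref.ndim} does not match a "
        f"{cfg.spatial_dims}D model")


def _check_divisible(shape, depth):
    f = 2 ** (depth - 1)
    if any(s % f for s in shape):
        raise ValueError(
            f"spatial shape {tuple(shape)} not divisible by {f} "
            f"(depth {depth})")
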