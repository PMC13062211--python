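"""DinoUnet: a frozen patch-feature encoder adapted for lesion segmentation.

The architecture composes five stages:

1. **encode** — a patch-token encoder (by default a small seeded ViT; an
   externally pretrained foundation encoder can be plugged in through the
   same interface) producing a stride-16 feature grid ``f_enc``.
2. **spatial prior** — a lightweight convolutional branch (MaxPool followed
   by four conv blocks) capturing fine spatial detail; its final map is
   spatially aligned with ``f_enc`` and its intermediate maps at strides
   2/4/8 serve as decoder skip connections.
3. **fuse** — channel concatenation of encoder and spatial-prior features.
4. **project** — a learnable 1x1 convolution + normalisation + ReLU mapping
   the fused features to the decoder width.
5. **decode** — a Unet-style decoder: four x2 upsampling stages, the first
   three concatenating the matching-stride spatial-prior skip, ending in a
   per-pixel softmax over classes.

A plain symmetric Unet with the same output contract is provided as the
comparison baseline.  With ``encoder_frozen`` (the default) the encoder
receives no gradient updates; only the adapter and decoder learn.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .autograd import Tensor, concat
from . import nn

__all__ = [
    "ModelConfig", "FeatureGrid", "ProbabilityMap", "DinoUnet", "UnetBaseline",
    "build_dinounet", "build_baseline_unet", "encode", "spatial_prior", "fuse",
    "project", "decode", "forward", "encoder_probe_checksum",
    "save_checkpoint", "load_checkpoint",
]


@dataclass(frozen=True)
class ModelConfig:
    encoder: str = "tiny_vit"          # tiny_vit | unet_encoder | external_pretrained
    patch_size: int = 16
    encoder_dim: int = 64              # C
    spm_channels: int = 32             # C_spm
    target_channels: int = 64          # C_target
    n_classes: int = 3                 # K
    encoder_frozen: bool = True
    encoder_depth: int = 4
    encoder_heads: int = 4
    seed: int = 0

    def validate(self) -> None:
        if self.encoder not in ("tiny_vit", "unet_encoder", "external_pretrained"):
            raise ValueError(f"unknown encoder {self.encoder!r}")
        if self.n_classes < 2:
            raise ValueError(f"n_classes must be >= 2, got {self.n_classes}")
        for name in ("encoder_dim", "spm_channels", "target_channels"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.patch_size < 1:
            raise ValueError("patch_size must be >= 1")


@dataclass
class FeatureGrid:
    """Spatial feature map: (H', W', C) values at a given pixel stride."""

    values: np.ndarray
    stride: int

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"FeatureGrid needs (H', W', C), got {self.values.shape}")
        if not np.isfinite(self.values).all():
            raise ValueError("FeatureGrid contains non-finite values")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.values.shape[:2]

    @property
    def channels(self) -> int:
        return self.values.shape[2]


@dataclass
class ProbabilityMap:
    """Per-pixel class probabilities (H, W, K), normalised per pixel."""

    probs: np.ndarray
    classes: tuple[int, ...]

    def __post_init__(self):
        self.probs = np.asarray(self.probs)
        sums = self.probs.sum(axis=-1)
        if not np.allclose(sums, 1.0, atol=1e-5):
            raise ValueError("probabilities do not sum to 1 per pixel")
        if self.probs.min() < -1e-7 or self.probs.max() > 1 + 1e-7:
            raise ValueError("probabilities outside [0, 1]")

    def argmax_mask(self) -> np.ndarray:
        return self.probs.argmax(axis=-1)


def _check_divisible(h: int, w: int, by: int) -> None:
    for name, dim in (("height", h), ("width", w)):
        if dim % by:
            raise ValueError(f"input {name} {dim} is not divisible by {by}")


def _to_nchw(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=nn.DTYPE)
    if image.ndim == 3 and image.shape[-1] == 3:
        image = image.transpose(2, 0, 1)[None]
    elif image.ndim == 3 and image.shape[0] == 3:
        image = image[None]
    elif image.ndim != 4:
        raise ValueError(f"expected an RGB image, got shape {image.shape}")
    return image


# --------------------------------------------------------------------------
# encoders
# --------------------------------------------------------------------------

class TinyViT(nn.Module):
    """Seeded small vision transformer producing a stride-``patch`` grid."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        p, c = cfg.patch_size, cfg.encoder_dim
        self.patch = p
        self.dim = c
        self.proj = nn.Linear(3 * p * p, c, rng)
        self.blocks = [nn.TransformerBlock(c, cfg.encoder_heads, rng)
                       for _ in range(cfg.encoder_depth)]
        self.norm = nn.LayerNorm(c)

    def __call__(self, x: Tensor) -> Tensor:
        n, ch, h, w = x.shape
        p, c = self.patch, self.dim
        gh, gw = h // p, w // p
        tokens = (x.reshape(n, ch, gh, p, gw, p)
                   .transpose(0, 2, 4, 1, 3, 5)
                   .reshape(n, gh * gw, ch * p * p))
        tokens = self.proj(tokens) + Tensor(nn.sincos_position_grid(gh, gw, c))
        for blk in self.blocks:
            tokens = blk(tokens)
        tokens = self.norm(tokens)
        return tokens.reshape(n, gh, gw, c).transpose(0, 3, 1, 2)


class ConvEncoder(nn.Module):
    """Convolutional alternative encoder with the same stride-16 contract."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        c = cfg.encoder_dim
        self.b1 = nn.ConvBlock(3, 16, rng, stride=2)
        self.b2 = nn.ConvBlock(16, 32, rng, stride=2)
        self.b3 = nn.ConvBlock(32, 48, rng, stride=2)
        self.b4 = nn.ConvBlock(48, c, rng, stride=2)

    def __call__(self, x: Tensor) -> Tensor:
        return self.b4(self.b3(self.b2(self.b1(x))))


class ExternalEncoder(nn.Module):
    """Adapter for externally pretrained patch encoders.

    ``fn`` maps an (N, 3, H, W) array to an (N, C, H/patch, W/patch) array;
    it is treated as frozen (no parameters are exposed to the optimizer).
    """

    def __init__(self, fn, cfg: ModelConfig):
        self.fn = fn
        self.cfg = cfg

    def __call__(self, x: Tensor) -> Tensor:
        out = np.asarray(self.fn(x.data), dtype=nn.DTYPE)
        expect = (x.shape[0], self.cfg.encoder_dim,
                  x.shape[2] // self.cfg.patch_size, x.shape[3] // self.cfg.patch_size)
        if out.shape != expect:
            raise ValueError(f"external encoder returned {out.shape}, expected {expect}")
        return Tensor(out)


# --------------------------------------------------------------------------
# adapter modules
# --------------------------------------------------------------------------

class SpatialPriorModule(nn.Module):
    """MaxPool + four conv blocks; total stride 16, intermediates at 2/4/8."""

    SKIP_CHANNELS = (16, 32, 32)   # at strides 2, 4, 8

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.b1 = nn.ConvBlock(3, 16, rng, stride=1)    # after maxpool: stride 2
        self.b2 = nn.ConvBlock(16, 32, rng, stride=2)   # stride 4
        self.b3 = nn.ConvBlock(32, 32, rng, stride=2)   # stride 8
        self.b4 = nn.ConvBlock(32, cfg.spm_channels, rng, stride=2)  # stride 16

    def __call__(self, x: Tensor) -> tuple[Tensor, list[Tensor]]:
        s2 = self.b1(x.maxpool2x2())
        s4 = self.b2(s2)
        s8 = self.b3(s4)
        s16 = self.b4(s8)
        return s16, [s2, s4, s8]


class ProjectionModule(nn.Module):
    """1x1 conv -> channel norm -> ReLU onto the decoder width."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.conv = nn.Conv2d(cin, cout, 1, rng, padding=0)
        self.norm = nn.ChannelNorm(cout)

    def __call__(self, x: Tensor) -> Tensor:
        return self.norm(self.conv(x)).relu()


class UnetDecoder(nn.Module):
    """Four x2 upsampling stages; the first three concatenate skips at 8/4/2."""

    WIDTHS = (64, 48, 32, 24)

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator,
                 skip_channels=SpatialPriorModule.SKIP_CHANNELS):
        s2, s4, s8 = skip_channels
        w1, w2, w3, w4 = self.WIDTHS
        self.d1 = nn.ConvBlock(cfg.target_channels + s8, w1, rng)
        self.d2 = nn.ConvBlock(w1 + s4, w2, rng)
        self.d3 = nn.ConvBlock(w2 + s2, w3, rng)
        self.d4 = nn.ConvBlock(w3, w4, rng)
        self.head = nn.Conv2d(w4, cfg.n_classes, 1, rng, padding=0)

    def __call__(self, bottleneck: Tensor, skips: list[Tensor]) -> Tensor:
        s2, s4, s8 = skips
        x = self.d1(concat([bottleneck.upsample2x(), s8], axis=1))
        x = self.d2(concat([x.upsample2x(), s4], axis=1))
        x = self.d3(concat([x.upsample2x(), s2], axis=1))
        x = self.d4(x.upsample2x())
        return self.head(x)


# --------------------------------------------------------------------------
# full models
# --------------------------------------------------------------------------

class DinoUnet(nn.Module):
    kind = "dinounet"

    def __init__(self, cfg: ModelConfig, external_fn=None):
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xD1F0]))
        if cfg.encoder == "tiny_vit":
            self.encoder = TinyViT(cfg, rng)
        elif cfg.encoder == "unet_encoder":
            self.encoder = ConvEncoder(cfg, rng)
        else:
            if external_fn is None:
                raise ValueError("encoder='external_pretrained' requires external_fn")
            self.encoder = ExternalEncoder(external_fn, cfg)
        self.spm = SpatialPriorModule(cfg, rng)
        self.proj = ProjectionModule(cfg.encoder_dim + cfg.spm_channels,
                                     cfg.target_channels, rng)
        self.decoder = UnetDecoder(cfg, rng)
        if cfg.encoder_frozen and isinstance(self.encoder, nn.Module):
            self.encoder.freeze()

    def _check_input(self, x: Tensor) -> None:
        _check_divisible(x.shape[2], x.shape[3], self.cfg.patch_size)
        _check_divisible(x.shape[2], x.shape[3], 16)

    def encode_tensor(self, x: Tensor) -> Tensor:
        self._check_input(x)
        return self.encoder(x)

    def forward_logits(self, x: Tensor) -> Tensor:
        self._check_input(x)
        f_enc = self.encoder(x)
        if self.cfg.encoder_frozen:
            f_enc = f_enc.detach()
        f_spm, skips = self.spm(x)
        fused = concat([f_enc, f_spm], axis=1)
        bottleneck = self.proj(fused)
        return self.decoder(bottleneck, skips)

    def trainable_parameters(self) -> list[Tensor]:
        return [p for p in self.parameters() if p.requires_grad]

    def predict(self, image: np.ndarray) -> ProbabilityMap:
        x = Tensor(_to_nchw(image))
        logits = self.forward_logits(x)
        probs = logits.softmax(axis=1).data[0].transpose(1, 2, 0)
        return ProbabilityMap(probs=probs.astype(np.float64),
                              classes=tuple(range(self.cfg.n_classes)))


class UnetBaseline(nn.Module):
    """Symmetric 4-level encoder-decoder with skip connections."""

    kind = "unet"
    WIDTHS = (16, 32, 48, 64)

    def __init__(self, cfg: ModelConfig):
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x0E7]))
        w1, w2, w3, w4 = self.WIDTHS
        self.e1 = nn.ConvBlock(3, w1, rng)
        self.e2 = nn.ConvBlock(w1, w2, rng)
        self.e3 = nn.ConvBlock(w2, w3, rng)
        self.e4 = nn.ConvBlock(w3, w4, rng)
        self.bottleneck = nn.ConvBlock(w4, 96, rng)
        self.d4 = nn.ConvBlock(96 + w4, w4, rng)
        self.d3 = nn.ConvBlock(w4 + w3, w3, rng)
        self.d2 = nn.ConvBlock(w3 + w2, w2, rng)
        self.d1 = nn.ConvBlock(w2 + w1, w1, rng)
        self.head = nn.Conv2d(w1, cfg.n_classes, 1, rng, padding=0)

    def forward_logits(self, x: Tensor) -> Tensor:
        _check_divisible(x.shape[2], x.shape[3], 16)
        e1 = self.e1(x)
        e2 = self.e2(e1.maxpool2x2())
        e3 = self.e3(e2.maxpool2x2())
        e4 = self.e4(e3.maxpool2x2())
        b = self.bottleneck(e4.maxpool2x2())
        d4 = self.d4(concat([b.upsample2x(), e4], axis=1))
        d3 = self.d3(concat([d4.upsample2x(), e3], axis=1))
        d2 = self.d2(concat([d3.upsample2x(), e2], axis=1))
        d1 = self.d1(concat([d2.upsample2x(), e1], axis=1))
        return self.head(d1)

    def trainable_parameters(self) -> list[Tensor]:
        return [p for p in self.parameters() if p.requires_grad]

    def predict(self, image: np.ndarray) -> ProbabilityMap:
        x = Tensor(_to_nchw(image))
        logits = self.forward_logits(x)
        probs = logits.softmax(axis=1).data[0].transpose(1, 2, 0)
        return ProbabilityMap(probs=probs.astype(np.float64),
                              classes=tuple(range(self.cfg.n_classes)))


_MODEL_CACHE: dict[ModelConfig, DinoUnet] = {}


def build_dinounet(cfg: ModelConfig, external_fn=None) -> DinoUnet:
    """Construct (and cache, for deterministic configs) a DinoUnet."""
    if external_fn is not None:
        return DinoUnet(cfg, external_fn=external_fn)
    if cfg not in _MODEL_CACHE:
        _MODEL_CACHE[cfg] = DinoUnet(cfg)
    return _MODEL_CACHE[cfg]


def build_baseline_unet(cfg: ModelConfig) -> UnetBaseline:
    return UnetBaseline(cfg)


# --------------------------------------------------------------------------
# functional stage API (stateless views over a seeded model)
# --------------------------------------------------------------------------

def encode(image: np.ndarray, cfg: ModelConfig, external_fn=None) -> FeatureGrid:
    """Stage 1: dense patch features, (H/patch, W/patch, C) at stride patch."""
    x = Tensor(_to_nchw(image))
    _check_divisible(x.shape[2], x.shape[3], cfg.patch_size)
    model = build_dinounet(cfg, external_fn=external_fn)
    out = model.encode_tensor(x).data[0].transpose(1, 2, 0)
    return FeatureGrid(values=out, stride=cfg.patch_size)


def spatial_prior(image: np.ndarray, cfg: ModelConfig
                  ) -> tuple[FeatureGrid, list[FeatureGrid]]:
    """Stage 2: spatial-prior grid at stride 16 + intermediates at 2/4/8."""
    x = Tensor(_to_nchw(image))
    _check_divisible(x.shape[2], x.shape[3], 16)
    model = build_dinounet(cfg)
    final, skips = model.spm(x)
    grid = FeatureGrid(values=final.data[0].transpose(1, 2, 0), stride=16)
    inter = [FeatureGrid(values=s.data[0].transpose(1, 2, 0), stride=st)
             for s, st in zip(skips, (2, 4, 8))]
    return grid, inter


def fuse(f_enc: FeatureGrid, f_spm: FeatureGrid) -> FeatureGrid:
    """Stage 3: lossless channel concatenation of aligned grids."""
    if f_enc.grid_shape != f_spm.grid_shape or f_enc.stride != f_spm.stride:
        raise ValueError(
            f"cannot fuse grids: {f_enc.grid_shape}@stride{f_enc.stride} vs "
            f"{f_spm.grid_shape}@stride{f_spm.stride}")
    return FeatureGrid(values=np.concatenate([f_enc.values, f_spm.values], axis=-1),
                       stride=f_enc.stride)


def project(f_fuse: FeatureGrid, cfg: ModelConfig) -> FeatureGrid:
    """Stage 4: learnable 1x1 projection to the decoder width."""
    model = build_dinounet(cfg)
    x = Tensor(f_fuse.values.transpose(2, 0, 1)[None].astype(nn.DTYPE))
    out = model.proj(x).data[0].transpose(1, 2, 0)
    return FeatureGrid(values=out, stride=f_fuse.stride)


def decode(f_proj: FeatureGrid, skips: list[FeatureGrid],
           cfg: ModelConfig) -> ProbabilityMap:
    """Stage 5: Unet decoding of the bottleneck with stride-8/4/2 skips."""
    if f_proj.stride != 16:
        raise ValueError(f"decoder bottleneck must be stride 16, got {f_proj.stride}")
    strides = sorted((s.stride for s in skips), reverse=True)
    if strides != [8, 4, 2]:
        raise ValueError(f"decoder needs skips at strides 8, 4, 2; got {strides}")
    by_stride = {s.stride: s for s in skips}
    model = build_dinounet(cfg)
    bottleneck = Tensor(f_proj.values.transpose(2, 0, 1)[None].astype(nn.DTYPE))
    skip_tensors = [Tensor(by_stride[s].values.transpose(2, 0, 1)[None].astype(nn.DTYPE))
                    for s in (2, 4, 8)]
    logits = model.decoder(bottleneck, skip_tensors)
    probs = logits.softmax(axis=1).data[0].transpose(1, 2, 0)
    return ProbabilityMap(probs=probs.astype(np.float64),
                          classes=tuple(range(cfg.n_classes)))


def forward(image: np.ndarray, cfg: ModelConfig, external_fn=None) -> ProbabilityMap:
    """Full composition encode -> spatial prior -> fuse -> project -> decode."""
    return build_dinounet(cfg, external_fn=external_fn).predict(image)


# --------------------------------------------------------------------------
# checkpointing and probes
# --------------------------------------------------------------------------

def encoder_probe_checksum(model: DinoUnet, probe_image: np.ndarray) -> str:
    """SHA-256 of the encoder's output on a fixed probe image."""
    out = model.encode_tensor(Tensor(_to_nchw(probe_image))).data
    return hashlib.sha256(np.ascontiguousarray(out).tobytes()).hexdigest()


def save_checkpoint(model, path: str | Path) -> Path:
    path = Path(path)
    payload = {f"param:{k}": v for k, v in model.state_dict().items()}
    payload["config_json"] = np.array(json.dumps(asdict(model.cfg)))
    payload["kind"] = np.array(model.kind)
    np.savez(path.with_suffix(".npz") if path.suffix != ".npz" else path, **payload)
    return path if path.suffix == ".npz" else path.with_suffix(".npz")


def load_checkpoint(path: str | Path):
    with np.load(Path(path), allow_pickle=False) as data:
        cfg = ModelConfig(**json.loads(str(data["config_json"])))
        kind = str(data["kind"])
        state = {k[len("param:"):]: data[k] for k in data.files if k.startswith("param:")}
    model = DinoUnet(cfg) if kind == "dinounet" else UnetBaseline(cfg)
    model.load_state_dict(state)
    return model
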