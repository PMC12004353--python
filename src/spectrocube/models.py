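"""Declarative builders for the three architectures and an analytic
trainable-parameter counter.

Three networks are supported:

* a 1D CNN baseline classifying single spectra — four conv1d blocks with
  128/64/32/16 kernels of sizes 3/5/7/9, each followed by batch
  normalization, leaky ReLU and spectral max pooling, then flatten → dense →
  softmax;
* a 3D patch CNN classifying w×w×B patches by their central pixel — the same
  four blocks with 3×3×{3,5,7,9} kernels and spectral-only pooling;
* a simplified 3D U-Net segmenting a whole scan — a one-level
  encoder/decoder of 3×3×5 convolutions with a skip concatenation, a
  spectral-to-channel reshape and a 1×1 2D softmax head producing an H×W
  class map.

Every architecture is expressed as a :class:`ModelSpec` — an ordered list of
:class:`LayerSpec` entries through which shapes propagate analytically — so
the trainable-parameter count is computable without allocating any weights.
Unstated architectural details (same padding, floor /2 spectral pooling,
2 parameters per batch-norm channel, the U-Net's internal arrangement) are a
calibrated reconstruction: they are pinned down by reproducing the published
parameter counts of all six reference configurations exactly.

``instantiate`` compiles a spec into a trainable :class:`~spectrocube.nn.Network`
whose allocated-weight count must equal the analytic count.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np
import yaml

from . import nn
from .cube_io import SpectroCubeError

LAYER_KINDS = (
    "conv1d", "conv3d", "conv2d", "batchnorm", "leakyrelu", "maxpool",
    "upsample", "concat_skip", "crop_spectral", "reshape_spectral_to_channels",
    "flatten", "dense", "softmax",
)


class ModelSpecError(SpectroCubeError):
    pass


@dataclass(frozen=True)
class LayerSpec:
    """One layer of a declarative network description."""

    kind: str
    kernels: Optional[int] = None
    kernel_size: Optional[tuple[int, ...]] = None
    pool_size: Optional[tuple[int, ...]] = None
    padding: str = "same"
    source: Optional[str] = None
    tag: Optional[str] = None
    alpha: float = 0.3

    def __post_init__(self) -> None:
        if self.kind not in LAYER_KINDS:
            raise ModelSpecError(f"unknown layer kind {self.kind!r}")
        if self.kind in ("conv1d", "conv3d", "conv2d", "dense"):
            if not self.kernels or self.kernels < 1:
                raise ModelSpecError(f"{self.kind} needs kernels ≥ 1")
            if self.kind != "dense" and (
                not self.kernel_size or any(k < 1 for k in self.kernel_size)
            ):
                raise ModelSpecError(f"{self.kind} needs kernel_size entries ≥ 1")
        if self.kind in ("maxpool", "upsample"):
            if not self.pool_size or any(p < 1 for p in self.pool_size):
                raise ModelSpecError(f"{self.kind} needs pool_size entries ≥ 1")
        if self.kind in ("concat_skip", "crop_spectral") and not self.source:
            raise ModelSpecError(f"{self.kind} needs a source tag")


@dataclass(frozen=True)
class ModelSpec:
    """Input shape, class count and ordered layer list of one network."""

    name: str
    input_shape: tuple[int, ...]
    n_classes: int
    layers: tuple[LayerSpec, ...]

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ModelSpecError("n_classes must be ≥ 2")
        if not self.layers or self.layers[-1].kind != "softmax":
            raise ModelSpecError("last layer must be softmax")

    # --- YAML round trip -------------------------------------------------
    def to_yaml(self) -> str:
        d = {
            "name": self.name,
            "input_shape": list(self.input_shape),
            "n_classes": self.n_classes,
            "layers": [
                {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in asdict(l).items() if v is not None}
                for l in self.layers
            ],
        }
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelSpec":
        d = yaml.safe_load(text)
        layers = []
        for l in d["layers"]:
            l = dict(l)
            for key in ("kernel_size", "pool_size"):
                if l.get(key) is not None:
                    l[key] = tuple(l[key])
            layers.append(LayerSpec(**l))
        return cls(
            name=d["name"],
            input_shape=tuple(d["input_shape"]),
            n_classes=int(d["n_classes"]),
            layers=tuple(layers),
        )


# ---------------------------------------------------------------------------
# shape propagation and parameter counting
# ---------------------------------------------------------------------------

def _initial_shape(input_shape: tuple[int, ...]) -> tuple[int, ...]:
    """Internal channels-last shape (without the batch axis)."""
    if len(input_shape) == 1:  # (B,) spectrum
        return (input_shape[0], 1)
    if len(input_shape) == 3:  # (w, w, B) patch
        return (*input_shape, 1)
    if len(input_shape) == 4:  # (H, W, B, 1) scan
        return input_shape
    raise ModelSpecError(f"unsupported input_shape {input_shape}")


def propagate_shapes(spec: ModelSpec) -> list[tuple[int, ...]]:
    """Shape after each layer (channels last, no batch axis).

    Raises if any dimension collapses to zero or a layer cannot apply.
    """
    shape = _initial_shape(spec.input_shape)
    shapes: list[tuple[int, ...]] = []
    tags: dict[str, tuple[int, ...]] = {}
    crops: dict[str, tuple[int, ...]] = {}
    for l in spec.layers:
        k = l.kind
        if k in ("conv1d", "conv3d"):
            expect = 2 if k == "conv1d" else 4
            if len(shape) != expect:
                raise ModelSpecError(f"{k} applied to shape {shape}")
            if l.padding == "same":
                spatial = shape[:-1]
            else:
                ksz = l.kernel_size
                if k == "conv1d":
                    ksz = (l.kernel_size[0],) if len(l.kernel_size) == 1 else l.kernel_size
                spatial = tuple(s - kk + 1 for s, kk in zip(shape[:-1], ksz))
            shape = (*spatial, l.kernels)
        elif k == "conv2d":
            if len(shape) != 3:
                raise ModelSpecError(f"conv2d applied to shape {shape}")
            shape = (shape[0], shape[1], l.kernels)
        elif k in ("batchnorm", "leakyrelu", "softmax"):
            pass
        elif k == "maxpool":
            pool = l.pool_size
            if len(pool) == 1:
                pool = (1,) * (len(shape) - 2) + pool
            if len(pool) != len(shape) - 1:
                raise ModelSpecError(f"pool_size {l.pool_size} vs shape {shape}")
            shape = tuple(s // p for s, p in zip(shape[:-1], pool)) + (shape[-1],)
        elif k == "upsample":
            pool = l.pool_size
            if len(pool) == 1:
                pool = (1,) * (len(shape) - 2) + pool
            shape = tuple(s * p for s, p in zip(shape[:-1], pool)) + (shape[-1],)
        elif k == "crop_spectral":
            src = tags.get(l.source)
            if src is None:
                raise ModelSpecError(f"crop_spectral: unknown tag {l.source!r}")
            crops[l.source] = src[:-2] + (shape[-2],) + (src[-1],)
        elif k == "concat_skip":
            src = crops.get(l.source, tags.get(l.source))
            if src is None:
                raise ModelSpecError(f"concat_skip: unknown tag {l.source!r}")
            if src[:-1] != shape[:-1]:
                raise ModelSpecError(
                    f"skip shape {src} incompatible with {shape}"
                )
            shape = shape[:-1] + (shape[-1] + src[-1],)
        elif k == "reshape_spectral_to_channels":
            if len(shape) != 4:
                raise ModelSpecError(f"reshape applied to shape {shape}")
            shape = (shape[0], shape[1], shape[2] * shape[3])
        elif k == "flatten":
            shape = (int(np.prod(shape)),)
        elif k == "dense":
            if len(shape) != 1:
                raise ModelSpecError("dense requires flattened input")
            shape = (l.kernels,)
        if any(s <= 0 for s in shape):
            raise ModelSpecError(f"dimension collapsed to 0 at {k}: {shape}")
        if l.tag:
            tags[l.tag] = shape
        shapes.append(shape)
    return shapes


def count_trainable_params(spec: ModelSpec) -> int:
    """Exact analytic trainable-parameter count of a spec.

    conv: (∏kernel_size·c_in + 1)·c_out; batchnorm: 2·channels;
    dense: (n_in + 1)·n_out; 1×1 2D head: (c_in + 1)·c_out; everything else 0.
    Any instantiated network reports the identical number.
    """
    shapes = propagate_shapes(spec)
    shape = _initial_shape(spec.input_shape)
    total = 0
    for l, out in zip(spec.layers, shapes):
        cin = shape[-1]
        if l.kind in ("conv1d", "conv3d"):
            total += (int(np.prod(l.kernel_size)) * cin + 1) * l.kernels
        elif l.kind == "conv2d":
            total += (int(np.prod(l.kernel_size)) * cin + 1) * l.kernels
        elif l.kind == "batchnorm":
            total += 2 * cin
        elif l.kind == "dense":
            total += (shape[0] + 1) * l.kernels
        shape = out
    return total


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

_CNN_KERNELS = (128, 64, 32, 16)
_CNN_SIZES = (3, 5, 7, 9)


def build_cnn1d(input_len: int, n_classes: int) -> ModelSpec:
    """Baseline 1D CNN over single spectra of ``input_len`` bands."""
    if input_len < 16:
        raise ModelSpecError("input_len must be ≥ 16 (four ÷2 poolings)")
    layers: list[LayerSpec] = []
    for kn, ks in zip(_CNN_KERNELS, _CNN_SIZES):
        layers += [
            LayerSpec("conv1d", kernels=kn, kernel_size=(ks,)),
            LayerSpec("batchnorm"),
            LayerSpec("leakyrelu"),
            LayerSpec("maxpool", pool_size=(2,)),
        ]
    layers += [
        LayerSpec("flatten"),
        LayerSpec("dense", kernels=n_classes),
        LayerSpec("softmax"),
    ]
    return ModelSpec("cnn1d", (input_len,), n_classes, tuple(layers))


def build_cnn3d(window: int, input_len: int, n_classes: int) -> ModelSpec:
    """3D patch CNN over window×window×``input_len`` patches (spectral-only
    pooling, spatial extent preserved)."""
    if window < 1 or window % 2 == 0:
        raise ModelSpecError("window must be odd")
    if input_len < 16:
        raise ModelSpecError("input_len must be ≥ 16 (four ÷2 poolings)")
    layers: list[LayerSpec] = []
    for kn, ks in zip(_CNN_KERNELS, _CNN_SIZES):
        layers += [
            LayerSpec("conv3d", kernels=kn, kernel_size=(3, 3, ks)),
            LayerSpec("batchnorm"),
            LayerSpec("leakyrelu"),
            LayerSpec("maxpool", pool_size=(1, 1, 2)),
        ]
    layers += [
        LayerSpec("flatten"),
        LayerSpec("dense", kernels=n_classes),
        LayerSpec("softmax"),
    ]
    return ModelSpec("cnn3d", (window, window, input_len), n_classes, tuple(layers))


def build_unet3d(
    grid: tuple[int, int],
    input_len: int,
    n_classes: int,
    base_kernels: int = 128,
) -> ModelSpec:
    """Simplified 3D U-Net over whole H×W×B scans, emitting an H×W class map.

    One-level encoder/decoder: conv–bn–relu (skip tap) → spectral pool /2 →
    conv–bn–relu → spectral upsample ×2 → crop the skip tensor to the
    upsampled spectral length → concatenate → conv–bn–relu → stack spectral
    bins into channels → 1×1 2D conv to ``n_classes`` → per-pixel softmax.
    """
    if input_len < 4:
        raise ModelSpecError("input_len must be ≥ 4")
    h, w = grid
    if h < 3 or w < 3:
        raise ModelSpecError("grid must be at least 3×3")
    layers = (
        LayerSpec("conv3d", kernels=base_kernels, kernel_size=(3, 3, 5)),
        LayerSpec("batchnorm"),
        LayerSpec("leakyrelu", tag="skip"),
        LayerSpec("maxpool", pool_size=(1, 1, 2)),
        LayerSpec("conv3d", kernels=base_kernels, kernel_size=(3, 3, 5)),
        LayerSpec("batchnorm"),
        LayerSpec("leakyrelu"),
        LayerSpec("upsample", pool_size=(1, 1, 2)),
        LayerSpec("crop_spectral", source="skip"),
        LayerSpec("concat_skip", source="skip"),
        LayerSpec("conv3d", kernels=base_kernels, kernel_size=(3, 3, 5)),
        LayerSpec("batchnorm"),
        LayerSpec("leakyrelu"),
        LayerSpec("reshape_spectral_to_channels"),
        LayerSpec("conv2d", kernels=n_classes, kernel_size=(1, 1)),
        LayerSpec("softmax"),
    )
    return ModelSpec("unet3d", (h, w, input_len, 1), n_classes, layers)


BUILDERS = {
    "cnn1d": build_cnn1d,
    "cnn3d": build_cnn3d,
    "unet3d": build_unet3d,
}


# ---------------------------------------------------------------------------
# instantiation
# ---------------------------------------------------------------------------

def instantiate(spec: ModelSpec, seed: int = 0, dtype=np.float32) -> nn.Network:
    """Compile a spec into a trainable network.

    The network's allocated-weight count equals
    :func:`count_trainable_params` on the same spec.
    """
    rng = np.random.default_rng(seed)
    shapes = propagate_shapes(spec)
    shape = _initial_shape(spec.input_shape)
    layers: list[nn.Layer] = []
    for l, out in zip(spec.layers, shapes):
        cin = shape[-1]
        ly: nn.Layer | None = None
        if l.kind == "conv1d":
            ly = nn.Conv1D(l.kernel_size[0], cin, l.kernels, rng, dtype)
        elif l.kind == "conv3d":
            ly = nn.Conv3D(l.kernel_size, cin, l.kernels, rng, dtype)
        elif l.kind == "conv2d":
            if tuple(l.kernel_size) != (1, 1):
                raise ModelSpecError("only 1×1 2D convolutions are supported")
            ly = nn.Conv2D1x1(cin, l.kernels, rng, dtype)
        elif l.kind == "batchnorm":
            ly = nn.BatchNorm(cin, dtype=dtype)
        elif l.kind == "leakyrelu":
            ly = nn.LeakyReLU(l.alpha)
        elif l.kind == "maxpool":
            pool = l.pool_size if len(l.pool_size) > 1 else (l.pool_size[0],)
            if any(p != 1 for p in pool[:-1]):
                raise ModelSpecError("only spectral-axis pooling is supported")
            ly = nn.MaxPoolSpectral(pool[-1])
        elif l.kind == "upsample":
            pool = l.pool_size
            if any(p != 1 for p in pool[:-1]):
                raise ModelSpecError("only spectral-axis upsampling is supported")
            ly = nn.UpsampleSpectral(pool[-1])
        elif l.kind == "crop_spectral":
            ly = nn.CropSpectralOp(l.source)
        elif l.kind == "concat_skip":
            ly = nn.ConcatSkipOp(l.source)
        elif l.kind == "reshape_spectral_to_channels":
            ly = nn.ReshapeSpectralToChannels()
        elif l.kind == "flatten":
            ly = nn.Flatten()
        elif l.kind == "dense":
            ly = nn.Dense(shape[0], l.kernels, rng, dtype)
        elif l.kind == "softmax":
            shape = out
            continue  # applied by Network.predict_proba / fused in the loss
        if ly is not None:
            ly.tag = l.tag
            layers.append(ly)
        shape = out
    net = nn.Network(layers, name=spec.name)
    net.input_shape = _initial_shape(spec.input_shape)
    net.n_classes = spec.n_classes
    return net
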