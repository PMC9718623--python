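"""Reference CNN backbone specifications and feature extraction.

Two architectures are specified layer-by-layer: DarkNet19 (19 convolutions
interleaved with 5 max-pools, a 1x1 head convolution and a global softmax)
and SqueezeNet (a leading 7x7 convolution, eight fire modules with
interleaved max-pools, a 1x1 head convolution and global average pooling).
``infer_shapes`` walks a spec and computes every intermediate (h, w, c)
purely arithmetically, so the layer tables can be audited without weights.

Feature extraction is defined by a small contract (``FeatureExtractor``):
same image in, same finite vector of length ``out_dim`` out.  The shipped
implementation is a deterministic mock — a fixed-seed random projection of
a 32x32 grayscale downsample — which keeps the whole pipeline exercisable
offline.  Real pretrained weights would require a deep-learning runtime
and are out of scope for this package; requesting them raises.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.transform import resize

__all__ = [
    "LayerSpec",
    "BackboneSpec",
    "FeatureExtractor",
    "MockFeatureExtractor",
    "build_darknet19_spec",
    "build_squeezenet_spec",
    "infer_shapes",
    "swap_head_and_finetune",
    "extract_features",
]


@dataclass(frozen=True)
class LayerSpec:
    """One layer of a backbone.

    ``kind`` is one of conv / maxpool / fire / global_avgpool / softmax.
    Fire modules carry squeeze / expand1 / expand3 channel counts instead
    of a single filter count.
    """

    kind: str
    name: str
    filters: int | None = None
    kernel: tuple[int, int] | None = None
    stride: int = 1
    pad: int = 0
    squeeze: int | None = None
    expand1: int | None = None
    expand3: int | None = None

    def __post_init__(self) -> None:
        if self.kind in ("conv", "maxpool"):
            if self.kernel is None or self.stride <= 0:
                raise ValueError(f"{self.name}: conv/maxpool need kernel and stride > 0")
        if self.kind == "fire":
            if not all(x and x > 0 for x in (self.squeeze, self.expand1, self.expand3)):
                raise ValueError(f"{self.name}: fire needs squeeze/expand1/expand3 > 0")


@dataclass
class BackboneSpec:
    name: str
    layers: list[LayerSpec]
    input_hw: int
    num_classes: int
    tap_layer: int  # index of the exported feature layer

    def __post_init__(self) -> None:
        if not 0 <= self.tap_layer < len(self.layers):
            raise ValueError("tap_layer must index an existing layer")

    @property
    def out_dim(self) -> int:
        """Channel count of the tap layer after global pooling."""
        tap = self.layers[self.tap_layer]
        if tap.kind == "fire":
            return tap.expand1 + tap.expand3
        return tap.filters


def _conv(name: str, filters: int, k: int, stride: int = 1) -> LayerSpec:
    # 3x3 convs pad 1, 1x1 convs pad 0: keeps spatial size constant,
    # matching the reference layer tables
    return LayerSpec(
        kind="conv", name=name, filters=filters, kernel=(k, k), stride=stride,
        pad=1 if k == 3 else (3 if k == 7 else 0),
    )


def build_darknet19_spec(num_classes: int = 5, input_hw: int = 224) -> BackboneSpec:
    """DarkNet19: 19 convolutions, 5 max-pools, global softmax head.

    The head convolution is 1x1 with ``num_classes`` filters; the tap
    layer is the last 1024-filter convolution (the one feeding the head),
    globally average-pooled to 1024 features.
    """
    if num_classes < 2:
        raise ValueError("need num_classes >= 2")
    mp = lambda name: LayerSpec(kind="maxpool", name=name, kernel=(2, 2), stride=2)
    layers = [
        _conv("conv1", 32, 3),  # printed as 34 in some reproductions; 32 is canonical
        mp("maxpool1"),
        _conv("conv2", 64, 3),
        mp("maxpool2"),
        _conv("conv3", 128, 3),
        _conv("conv4", 64, 1),
        _conv("conv5", 128, 3),
        mp("maxpool3"),
        _conv("conv6", 256, 3),
        _conv("conv7", 128, 1),
        _conv("conv8", 256, 3),
        mp("maxpool4"),
        _conv("conv9", 512, 3),
        _conv("conv10", 256, 1),
        _conv("conv11", 512, 3),
        _conv("conv12", 256, 1),
        _conv("conv13", 512, 3),
        mp("maxpool5"),
        _conv("conv14", 1024, 3),
        _conv("conv15", 512, 1),
        _conv("conv16", 1024, 3),
        _conv("conv17", 512, 1),
        _conv("conv18", 1024, 3),
        _conv("head", num_classes, 1),
        LayerSpec(kind="softmax", name="softmax"),
    ]
    tap = next(i for i, l in enumerate(layers) if l.name == "conv18")
    return BackboneSpec(
        name="darknet19", layers=layers, input_hw=input_hw,
        num_classes=num_classes, tap_layer=tap,
    )


def _fire(name: str, s: int, e1: int, e3: int) -> LayerSpec:
    return LayerSpec(kind="fire", name=name, squeeze=s, expand1=e1, expand3=e3)


def build_squeezenet_spec(num_classes: int = 5, input_hw: int = 224) -> BackboneSpec:
    """SqueezeNet: conv1, 8 fire modules, 1x1 head conv, global avg-pool.

    The tap layer is fire9 (512 channels after expand concatenation),
    globally average-pooled.  Note the printed 111x111 conv1 output of
    the reference table is arithmetically consistent with a 227 input;
    ``infer_shapes`` reproduces it when called with ``input_hw=227``.
    """
    if num_classes < 2:
        raise ValueError("need num_classes >= 2")
    mp = lambda name: LayerSpec(kind="maxpool", name=name, kernel=(3, 3), stride=2)
    layers = [
        LayerSpec(kind="conv", name="conv1", filters=96, kernel=(7, 7), stride=2, pad=0),
        mp("maxpool1"),
        _fire("fire2", 16, 64, 64),
        _fire("fire3", 16, 64, 64),
        _fire("fire4", 32, 128, 128),
        mp("maxpool4"),
        _fire("fire5", 32, 128, 128),
        _fire("fire6", 48, 192, 192),
        _fire("fire7", 48, 192, 192),
        _fire("fire8", 64, 256, 256),
        mp("maxpool8"),
        _fire("fire9", 64, 256, 256),
        LayerSpec(kind="conv", name="conv10", filters=num_classes, kernel=(1, 1), stride=1),
        LayerSpec(kind="global_avgpool", name="avgpool10"),
    ]
    tap = next(i for i, l in enumerate(layers) if l.name == "fire9")
    return BackboneSpec(
        name="squeezenet", layers=layers, input_hw=input_hw,
        num_classes=num_classes, tap_layer=tap,
    )


def infer_shapes(spec: BackboneSpec, input_hw: int | None = None) -> list[tuple[int, int, int]]:
    """Per-layer output shapes (h, w, c) from pure arithmetic.

    conv / maxpool: out = floor((in + 2*pad - k) / stride) + 1; fire keeps
    the spatial size and concatenates expand1 + expand3 channels; global
    pools collapse to 1x1.
    """
    hw = spec.input_hw if input_hw is None else input_hw
    if hw <= 0:
        raise ValueError("input_hw must be positive")
    h = w = hw
    c = 3
    shapes: list[tuple[int, int, int]] = []
    for layer in spec.layers:
        if layer.kind in ("conv", "maxpool"):
            kh, kw = layer.kernel
            h = (h + 2 * layer.pad - kh) // layer.stride + 1
            w = (w + 2 * layer.pad - kw) // layer.stride + 1
            if h <= 0 or w <= 0:
                raise ValueError(f"layer {layer.name}: nonpositive spatial size")
            if layer.kind == "conv":
                c = layer.filters
        elif layer.kind == "fire":
            c = layer.expand1 + layer.expand3
        elif layer.kind in ("global_avgpool", "softmax"):
            h = w = 1
        else:  # pragma: no cover - LayerSpec validates kinds
            raise ValueError(f"unknown layer kind {layer.kind}")
        shapes.append((h, w, c))
    return shapes


class FeatureExtractor:
    """Deterministic image -> feature-vector contract.

    Subclasses implement ``_features(image) -> 1-D float array`` of length
    ``out_dim``; extraction must be a pure function of the image and the
    extractor's fixed weights/seed.
    """

    descriptor: str = "abstract"
    out_dim: int = 0
    deterministic: bool = True
    trainable: bool = False

    def _features(self, image: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, image: np.ndarray) -> np.ndarray:
        out = np.asarray(self._features(image), dtype=float)
        if out.shape != (self.out_dim,) or not np.all(np.isfinite(out)):
            raise ValueError(f"{self.descriptor}: non-finite or mis-sized activation")
        return out


class MockFeatureExtractor(FeatureExtractor):
    """Fixed random projection of a 32x32 grayscale downsample's order
    statistics.

    The downsample is sorted before projection: the intensity
    distribution is invariant to where the grain sits in the frame
    (object area and texture survive; position does not), mimicking the
    translation robustness of pooled convolutional features.  The
    projection matrix is drawn once from ``seed`` and never changes,
    which makes extraction bit-reproducible.
    """

    def __init__(self, out_dim: int = 64, seed: int = 0, descriptor: str = "mock"):
        rng = np.random.default_rng(seed)
        self.descriptor = descriptor
        self.out_dim = out_dim
        self._side = 32
        d = self._side * self._side
        self._projection = rng.standard_normal((d, out_dim)) / np.sqrt(d)
        self._head: np.ndarray | None = None
        self.trainable = True  # supports the head-swap contract below

    def _features(self, image: np.ndarray) -> np.ndarray:
        gray = image.astype(float).mean(axis=-1) / 255.0
        small = resize(gray, (self._side, self._side), anti_aliasing=True)
        return np.tanh(np.sort(small.ravel()) @ self._projection)

    def predict_head(self, image: np.ndarray) -> np.ndarray:
        if self._head is None:
            raise ValueError("no trained head; call swap_head_and_finetune first")
        return self(image) @ self._head


def extract_features(
    extractor: FeatureExtractor, images: list[np.ndarray]
) -> pd.DataFrame:
    """Stack per-image feature vectors into an N x out_dim frame.

    Column ids are ``{name}:{tap}:{k}`` so downstream stages can trace
    every fused/selected column back to its view.
    """
    if not images:
        raise ValueError("images must be nonempty")
    rows = np.stack([extractor(img) for img in images])
    columns = [f"{extractor.descriptor}:tap:{k}" for k in range(extractor.out_dim)]
    index = pd.Index([f"s_{i:05d}" for i in range(len(images))], name="sample_id")
    return pd.DataFrame(rows, index=index, columns=columns)


@dataclass
class TrainConfig:
    epochs: int = 1
    num_classes: int = 5
    l2: float = 1e-3


def swap_head_and_finetune(
    extractor: FeatureExtractor,
    images: list[np.ndarray],
    labels: np.ndarray,
    train_config: TrainConfig | None = None,
) -> FeatureExtractor:
    """Replace the classification head and fit it on the given images.

    The tap/feature contract of the returned extractor is identical to
    the input's; only the head changes.  For the mock extractor the head
    is a ridge-regularized least-squares readout on the tapped features
    ("train head only"); ``epochs=0`` is a strict no-op.  Extractors
    without trainable weights are rejected.
    """
    if not getattr(extractor, "trainable", False):
        raise NotImplementedError(
            f"{extractor.descriptor}: extractor has no trainable weights"
        )
    cfg = train_config or TrainConfig()
    if cfg.epochs == 0:
        return extractor
    feats = np.stack([extractor(img) for img in images])
    labels = np.asarray(labels)
    onehot = np.eye(cfg.num_classes)[labels]
    gram = feats.T @ feats + cfg.l2 * np.eye(feats.shape[1])
    extractor._head = np.linalg.solve(gram, feats.T @ onehot)
    return extractor


def load_real_backbone(name: str):  # pragma: no cover - documented unsupported mode
    """Real pretrained weights require a deep-learning runtime; not shipped."""
    raise NotImplementedError(
        f"loading real {name} weights requires a deep-learning runtime; "
        "use MockFeatureExtractor for offline work"
    )
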