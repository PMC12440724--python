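"""VGG16-family convolutional backbone, deep-feature extraction and Grad-CAM.

The backbone is a 16-layer-style stack of 3x3 convolution blocks with 2x2
max-pooling, implemented directly on NumPy (im2col + GEMM) so that runs are
bit-reproducible on CPU and need no weight downloads: ``weight_source`` is
``seeded-random`` by default, with He-initialized convolution filters fully
determined by a seed. Transfer learning follows the freeze-and-head recipe: the
convolutional features stay frozen and a 2-unit softmax head on globally
averaged final-block activations is trained with cross-entropy.

Deep features come from the *first* pooling layer (the fifth-to-last pooling
layer of the 5-block stack), which preserves low-level spatial detail. Its
64-channel activation map is reduced to 8 channels by averaging 8 consecutive
channel groups and flattened in (row, col, channel) order; for the full
``vgg16`` configuration at 224x224 input this yields 112 x 112 x 8 = 100,352
features per crop.

Three registered configurations trade fidelity for speed:

============  ==========  =======================  =====================
id            input size  block channels           block1 feature length
============  ==========  =======================  =====================
vgg16         224         64,128,256,512,512       100,352
vgg16-small   112         16,32,64,128,128         25,088
vgg16-tiny    32          8,16,32,64,64            2,048
============  ==========  =======================  =====================
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import numpy as np
from PIL import Image

from .errors import ParameterError
from .crops import RegionCrop

#: Input normalization constants of the ImageNet pretraining convention,
#: applied identically for both weight sources.
INPUT_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
INPUT_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)

#: Number of channel groups the first-pooling-layer map is averaged into.
N_CHANNEL_GROUPS = 8

#: Rough cap on the size of one im2col buffer, to bound peak memory.
_IM2COL_BUDGET_BYTES = 200 * 1024 * 1024


@dataclass(frozen=True)
class Architecture:
    architecture_id: str
    input_size: int
    block_channels: tuple[int, ...]
    convs_per_block: tuple[int, ...]


ARCHITECTURES = {
    "vgg16": Architecture("vgg16", 224, (64, 128, 256, 512, 512), (2, 2, 3, 3, 3)),
    "vgg16-small": Architecture("vgg16-small", 112, (16, 32, 64, 128, 128), (2, 2, 3, 3, 3)),
    "vgg16-tiny": Architecture("vgg16-tiny", 32, (8, 16, 32, 64, 64), (2, 2, 3, 3, 3)),
}


@dataclass(frozen=True)
class BackboneConfig:
    """Training configuration for :func:`fine_tune_backbone`."""

    architecture_id: str = "vgg16-tiny"
    weight_source: str = "seeded-random"
    epochs: int = 5
    learning_rate: float = 1e-3
    batch_size: int = 16

    def __post_init__(self):
        if self.architecture_id not in ARCHITECTURES:
            raise ParameterError(
                f"unknown architecture_id {self.architecture_id!r}; "
                f"available: {sorted(ARCHITECTURES)}"
            )
        if self.weight_source not in ("seeded-random", "pretrained"):
            raise ParameterError("weight_source must be 'seeded-random' or 'pretrained'")
        if self.epochs < 0:
            raise ParameterError("epochs must be nonnegative")


@dataclass
class FeatureVector:
    """Flattened first-pooling-layer deep features for one crop."""

    values: np.ndarray
    case_id: str
    region_tag: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("feature vector contains non-finite values")


@dataclass
class BackboneState:
    """Frozen convolution weights plus the trainable classification head."""

    config: BackboneConfig
    seed: int
    conv_weights: list[tuple[np.ndarray, np.ndarray]]
    head_weight: np.ndarray
    head_bias: np.ndarray
    head_mean: np.ndarray | None = None
    head_scale: np.ndarray | None = None
    trained: bool = False
    loss_trace: list[float] = field(default_factory=list)

    @property
    def architecture(self) -> Architecture:
        return ARCHITECTURES[self.config.architecture_id]

    @property
    def feature_length(self) -> int:
        arch = self.architecture
        half = arch.input_size // 2
        return half * half * min(N_CHANNEL_GROUPS, arch.block_channels[0])


def set_single_threaded() -> None:
    """Force single-threaded BLAS execution for bit-level determinism.

    Must be called before the first linear-algebra operation of the process
    to be fully effective; the CLI and the acceptance script call it first.
    """
    for var in ("OMP_NUM_THREADS", "OPENBLAS_NUM_THREADS", "MKL_NUM_THREADS",
                "VECLIB_MAXIMUM_THREADS", "NUMEXPR_NUM_THREADS"):
        os.environ[var] = "1"


def make_backbone(config: BackboneConfig, seed: int) -> BackboneState:
    """Initialize a backbone; weights are a pure function of (config, seed)."""
    if config.weight_source == "pretrained":
        raise ParameterError(
            "weight_source='pretrained' requires an external VGG16 checkpoint, "
            "which this installation does not ship; use 'seeded-random'"
        )
    arch = ARCHITECTURES[config.architecture_id]
    rng = np.random.default_rng(np.random.SeedSequence([0x5EED, seed]))
    weights = []
    c_in = 3
    for c_out, n_convs in zip(arch.block_channels, arch.convs_per_block):
        for _ in range(n_convs):
            fan_in = c_in * 9
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, 3, 3))
            weights.append((w.astype(np.float32), np.zeros(c_out, dtype=np.float32)))
            c_in = c_out
    c_last = arch.block_channels[-1]
    return BackboneState(
        config=config,
        seed=seed,
        conv_weights=weights,
        head_weight=np.zeros((c_last, 2), dtype=np.float64),
        head_bias=np.zeros(2, dtype=np.float64),
    )


# ---------------------------------------------------------------------------
# forward pass


def _conv3x3(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Same-padded 3x3 convolution on a (N, C, H, W) batch via im2col."""
    n, c, h, wd = x.shape
    c_out = w.shape[0]
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
    col = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n * h * wd, c * 9)
    out = col @ w.reshape(c_out, -1).T
    out += b
    return out.reshape(n, h, wd, c_out).transpose(0, 3, 1, 2)


def _maxpool2(x: np.ndarray) -> np.ndarray:
    n, c, h, w = x.shape
    x = x[:, :, : h // 2 * 2, : w // 2 * 2]
    return x.reshape(n, c, h // 2, 2, w // 2, 2).max(axis=(3, 5))


def _conv_chunk_size(c_in: int, h: int, w: int) -> int:
    bytes_per_sample = h * w * c_in * 9 * 4
    return max(1, _IM2COL_BUDGET_BYTES // max(bytes_per_sample, 1))


def _forward(
    state: BackboneState, x: np.ndarray, upto_block: int | None = None
) -> dict[str, np.ndarray]:
    """Run the conv stack on a preprocessed (N, 3, H, W) batch.

    Returns ``block1_pool`` always and, when the full stack is run,
    ``last_conv`` (final block's last ReLU map, pre-pool) and ``gap``
    (globally averaged final pooled activations).
    """
    arch = state.architecture
    out: dict[str, np.ndarray] = {}
    layer = 0
    n_blocks = len(arch.block_channels) if upto_block is None else upto_block
    for block, (c_out, n_convs) in enumerate(zip(arch.block_channels, arch.convs_per_block)):
        if block >= n_blocks:
            break
        for _ in range(n_convs):
            w, b = state.conv_weights[layer]
            chunks = []
            step = _conv_chunk_size(x.shape[1], x.shape[2], x.shape[3])
            for start in range(0, x.shape[0], step):
                chunks.append(_conv3x3(x[start : start + step], w, b))
            x = np.concatenate(chunks) if len(chunks) > 1 else chunks[0]
            np.maximum(x, 0.0, out=x)
            layer += 1
        if block == len(arch.block_channels) - 1:
            out["last_conv"] = x
        x = _maxpool2(x)
        if block == 0:
            out["block1_pool"] = x
    if n_blocks == len(arch.block_channels):
        out["gap"] = x.mean(axis=(2, 3)).astype(np.float64)
    return out


# ---------------------------------------------------------------------------
# preprocessing


def _resize_bilinear(pixels: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    """Bilinear resize of a (H, W) or (H, W, C) float array via Pillow."""
    if pixels.shape[:2] == size:
        return pixels
    if pixels.ndim == 2:
        im = Image.fromarray(pixels.astype(np.float32), mode="F")
        return np.asarray(im.resize((size[1], size[0]), Image.BILINEAR))
    channels = [
        np.asarray(
            Image.fromarray(pixels[:, :, c].astype(np.float32), mode="F").resize(
                (size[1], size[0]), Image.BILINEAR
            )
        )
        for c in range(pixels.shape[2])
    ]
    return np.stack(channels, axis=2)


def preprocess_crop(crop: RegionCrop, input_size: int) -> np.ndarray:
    """Resize to the network input, replicate gray to 3 channels, normalize.

    Pixel values are treated on a [0, 1] scale; integer arrays are divided by
    255 first. Returns a (3, S, S) float32 tensor.
    """
    pixels = np.asarray(crop.pixels)
    if pixels.size == 0:
        raise ParameterError("empty crop")
    pixels = pixels.astype(np.float32)
    if np.issubdtype(np.asarray(crop.pixels).dtype, np.integer):
        pixels = pixels / 255.0
    resized = _resize_bilinear(pixels, (input_size, input_size))
    if resized.ndim == 2:
        resized = np.repeat(resized[:, :, None], 3, axis=2)
    resized = (resized - INPUT_MEAN) / INPUT_STD
    return np.ascontiguousarray(resized.transpose(2, 0, 1))


def _preprocess_batch(crops: list[RegionCrop], input_size: int) -> np.ndarray:
    return np.stack([preprocess_crop(c, input_size) for c in crops])


# ---------------------------------------------------------------------------
# feature extraction


def _group_average(block1_pool: np.ndarray) -> np.ndarray:
    """Average consecutive channel groups: (N, C, H, W) -> (N, G, H, W).

    G = min(8, C); averaging preserves constants by construction.
    """
    n, c, h, w = block1_pool.shape
    groups = min(N_CHANNEL_GROUPS, c)
    if c % groups:
        raise ParameterError(f"channel count {c} not divisible into {groups} groups")
    return block1_pool.reshape(n, groups, c // groups, h, w).mean(axis=2)


def _flatten_features(reduced: np.ndarray) -> np.ndarray:
    """(N, G, H, W) -> (N, H*W*G) in fixed (row, col, channel) order."""
    n = reduced.shape[0]
    return np.ascontiguousarray(reduced.transpose(0, 2, 3, 1)).reshape(n, -1)


def extract_features_batch(
    state: BackboneState, crops: list[RegionCrop], want_gap: bool = False
) -> tuple[np.ndarray, np.ndarray | None]:
    """Block1-pool deep features for a batch of crops, optionally with the
    final-block GAP features used by the classification head (one shared
    forward pass)."""
    if not crops:
        raise ParameterError("no crops to extract")
    x = _preprocess_batch(crops, state.architecture.input_size)
    result = _forward(state, x, upto_block=None if want_gap else 1)
    feats = _flatten_features(_group_average(result["block1_pool"]))
    return feats.astype(np.float32), (result["gap"] if want_gap else None)


def extract_deep_features(state: BackboneState, crop: RegionCrop) -> FeatureVector:
    """Deep features of one crop from the first pooling layer.

    The crop is resized to the architecture's input size (bilinear, grayscale
    replicated to 3 channels) and normalized; the first-pooling-layer
    activation map is reduced by consecutive-channel-group averaging and
    flattened in (row, col, channel) order. For ``vgg16`` the result has
    112 x 112 x 8 = 100,352 values.
    """
    feats, _ = extract_features_batch(state, [crop])
    return FeatureVector(values=feats[0], case_id=crop.source_case_id, region_tag=crop.region_tag)


# ---------------------------------------------------------------------------
# head training (transfer learning with frozen features)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    return float(-np.log(np.clip(probs[np.arange(len(labels)), labels], 1e-12, None)).mean())


def fine_tune_backbone(
    crops: list[RegionCrop],
    labels,
    config: BackboneConfig,
    seed: int,
    _gap_features: np.ndarray | None = None,
) -> BackboneState:
    """Transfer-learn the backbone on labeled crops.

    Convolutional features stay frozen; a 2-unit softmax head on standardized
    GAP features is trained with cross-entropy by minibatch SGD
    (``config.batch_size``, ``config.learning_rate``) for ``config.epochs``
    epochs. ``loss_trace[e]`` is the full-sample loss after ``e`` epochs, so
    ``loss_trace[0]`` is the untrained loss. Deterministic given ``seed``.
    With ``epochs=0`` the returned weights equal the initial weights.
    """
    labels = np.asarray(labels, dtype=int)
    if len(labels) != len(crops):
        raise ParameterError("labels and crops length mismatch")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ParameterError("fine-tuning requires both classes present")
    if counts.min() < 2:
        raise ParameterError("fine-tuning requires >= 2 cases per class")

    state = make_backbone(config, seed)
    if _gap_features is None:
        _, gap = extract_features_batch(state, crops, want_gap=True)
    else:
        gap = np.asarray(_gap_features, dtype=np.float64)
    mean = gap.mean(axis=0)
    scale = np.maximum(gap.std(axis=0), 1e-8)
    feats = (gap - mean) / scale

    rng = np.random.default_rng(np.random.SeedSequence([0x7EAD, seed]))
    w = state.head_weight.copy()
    b = state.head_bias.copy()
    n = len(labels)
    trace = [_cross_entropy(_softmax(feats @ w + b), labels)]
    onehot = np.eye(2)[labels]
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            fb = feats[idx]
            probs = _softmax(fb @ w + b)
            grad_logits = (probs - onehot[idx]) / len(idx)
            w -= config.learning_rate * (fb.T @ grad_logits)
            b -= config.learning_rate * grad_logits.sum(axis=0)
        trace.append(_cross_entropy(_softmax(feats @ w + b), labels))

    return replace(
        state,
        head_weight=w,
        head_bias=b,
        head_mean=mean,
        head_scale=scale,
        trained=True,
        loss_trace=trace,
    )


# ---------------------------------------------------------------------------
# Grad-CAM


def grad_cam(state: BackboneState, crop: RegionCrop) -> np.ndarray:
    """Gradient-weighted class activation map for the predicted class.

    Computed at the last convolutional block: channel weights are the
    spatially averaged gradient of the predicted-class score with respect to
    the final ReLU activation map; with the linear head on standardized GAP
    features this gradient is ``head_weight[k, c] / (head_scale[k] * h * w)``
    per channel. The ReLU-rectified weighted sum is upsampled bilinearly to
    the crop's spatial size and min-max normalized to [0, 1]; an all-zero map
    stays all-zero.
    """
    if not state.trained:
        raise ParameterError("grad_cam requires a fine-tuned head; call fine_tune_backbone")
    x = _preprocess_batch([crop], state.architecture.input_size)
    result = _forward(state, x)
    feats = (result["gap"] - state.head_mean) / state.head_scale
    logits = feats @ state.head_weight + state.head_bias
    predicted = int(np.argmax(logits[0]))

    activations = result["last_conv"][0]  # (C, h, w)
    h, w = activations.shape[1:]
    alpha = state.head_weight[:, predicted] / (state.head_scale * h * w)
    cam = np.maximum((alpha[:, None, None] * activations).sum(axis=0), 0.0)
    cam = _resize_bilinear(cam, crop.pixels.shape[:2])
    lo, hi = float(cam.min()), float(cam.max())
    if hi - lo < 1e-12:
        return np.zeros_like(cam) if hi < 1e-12 else np.ones_like(cam)
    return (cam - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# checkpointing


def save_checkpoint(state: BackboneState, path: str) -> None:
    """Serialize weights to ``<path>.npz`` with a JSON provenance sidecar."""
    arrays = {}
    for i, (w, b) in enumerate(state.conv_weights):
        arrays[f"conv_{i}_w"] = w
        arrays[f"conv_{i}_b"] = b
    arrays["head_weight"] = state.head_weight
    arrays["head_bias"] = state.head_bias
    if state.head_mean is not None:
        arrays["head_mean"] = state.head_mean
        arrays["head_scale"] = state.head_scale
    np.savez_compressed(path + ".npz", **arrays)
    sidecar = {
        "architecture_id": state.config.architecture_id,
        "weight_source": state.config.weight_source,
        "seed": state.seed,
        "epochs": state.config.epochs,
        "trained": state.trained,
        "channel_groups": N_CHANNEL_GROUPS,
        "loss_trace": state.loss_trace,
    }
    with open(path + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_checkpoint(path: str) -> BackboneState:
    with open(path + ".json") as fh:
        sidecar = json.load(fh)
    data = np.load(path + ".npz")
    config = BackboneConfig(
        architecture_id=sidecar["architecture_id"],
        weight_source=sidecar["weight_source"],
        epochs=sidecar["epochs"],
    )
    n_layers = sum(ARCHITECTURES[config.architecture_id].convs_per_block)
    conv_weights = [(data[f"conv_{i}_w"], data[f"conv_{i}_b"]) for i in range(n_layers)]
    return BackboneState(
        config=config,
        seed=sidecar["seed"],
        conv_weights=conv_weights,
        head_weight=data["head_weight"],
        head_bias=data["head_bias"],
        head_mean=data["head_mean"] if "head_mean" in data else None,
        head_scale=data["head_scale"] if "head_scale" in data else None,
        trained=sidecar["trained"],
        loss_trace=list(sidecar["loss_trace"]),
    )
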