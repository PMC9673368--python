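"""A zoo of small trainable CNN classifiers with softmax confidence outputs.

These are desk-scale surrogates for the large ImageNet architectures a
clinical system would fine-tune: each preset fixes its own input size and
mixes the structural ingredient of its namesake family — plain residual
blocks ("tiny-residual-18-like"), a deeper/wider residual stack
("tiny-residual-50-like"), and depthwise-separable convolutions
("tiny-separable-xception-like"). Training follows a fixed-epoch Adam
recipe (defaults: 30 epochs, batch 32, lr 1e-4) minimizing cross-entropy,
with no early stopping or schedule. The class order is (benign, malignant)
everywhere; index 1 (malignant) is the positive class.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from . import _nn
from .synthgen import CLASSES, LabeledDataset, PhantomImage

CLASS_TO_INDEX = {c: i for i, c in enumerate(CLASSES)}


@dataclass(frozen=True)
class BackboneSpec:
    name: str
    input_size: tuple[int, int, int]     # (H, W, C) with C = 3
    block_widths: tuple[int, ...]
    use_residual: bool = True
    use_separable: bool = False
    target_layer: str = "features"

    def validate(self) -> None:
        h, w, c = self.input_size
        if h < 32 or w < 32:
            raise ValueError(f"input_size {self.input_size} below 32x32")
        if c != 3:
            raise ValueError("input channel count must be 3")
        if len(self.block_widths) == 0:
            raise ValueError("block_widths must be non-empty")
        if any(b < 1 for b in self.block_widths):
            raise ValueError("block_widths must be positive")


@dataclass(frozen=True)
class TrainingConfig:
    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 1e-4
    optimizer: str = "adam"
    seed: int = 0

    def validate(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be non-negative")
        if self.batch_size < 1:
            raise ValueError("batch_size must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")


PRESETS: dict[str, BackboneSpec] = {
    "tiny-residual-18-like": BackboneSpec(
        name="tiny-residual-18-like", input_size=(64, 64, 3),
        block_widths=(8, 16, 32), use_residual=True),
    "tiny-residual-50-like": BackboneSpec(
        name="tiny-residual-50-like", input_size=(64, 64, 3),
        block_widths=(8, 16, 24, 40), use_residual=True),
    "tiny-separable-xception-like": BackboneSpec(
        name="tiny-separable-xception-like", input_size=(96, 96, 3),
        block_widths=(8, 16, 32), use_residual=False, use_separable=True),
}


def _build_network(spec: BackboneSpec, seed: int) -> _nn.Network:
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xB0B]))
    widths = spec.block_widths
    stages: list[tuple[str, object]] = [
        ("stem", _nn.ConvStage(3, widths[0], 3, 2, rng))]
    in_ch = widths[0]
    for i, w in enumerate(widths[1:], start=1):
        name = "features" if i == len(widths) - 1 else f"block{i}"
        if spec.use_separable:
            stages.append((name, _nn.SepBlock(in_ch, w, 2, rng)))
        elif spec.use_residual:
            stages.append((name, _nn.ResBlock(in_ch, w, 2, rng)))
        else:
            stages.append((name, _nn.ConvStage(in_ch, w, 3, 2, rng)))
        in_ch = w
    head = _nn.Head(in_ch, len(CLASSES), rng)
    return _nn.Network(stages, head)


@dataclass
class TrainedModel:
    spec: BackboneSpec
    network: _nn.Network
    class_order: tuple[str, ...] = CLASSES
    trained: bool = False

    @property
    def name(self) -> str:
        return self.spec.name


def build_backbone(spec: BackboneSpec, seed: int) -> TrainedModel:
    """Construct a model in its deterministic initialized state."""
    spec.validate()
    return TrainedModel(spec=spec, network=_build_network(spec, seed))


def resize_to_input(image: PhantomImage | np.ndarray,
                    spec: BackboneSpec) -> np.ndarray:
    """Bilinear stretch to the backbone's (H, W), grayscale replicated to
    3 channels; returns a float32 (3, H, W) tensor in [0, 1]."""
    pixels = image.pixels if isinstance(image, PhantomImage) else image
    h, w, _ = spec.input_size
    if pixels.shape != (h, w):
        pixels = _sk_resize(pixels, (h, w), order=1, mode="edge",
                            anti_aliasing=False, preserve_range=True)
    pixels = np.clip(pixels, 0.0, 1.0).astype(np.float32)
    return np.broadcast_to(pixels, (3, h, w)).copy()


def _as_tensor(dataset: LabeledDataset, spec: BackboneSpec):
    x = np.stack([resize_to_input(item, spec) for item in dataset.items])
    y = np.array([CLASS_TO_INDEX[item.label] for item in dataset.items])
    return x, y


def train_model(model: TrainedModel, train_set: LabeledDataset,
                config: TrainingConfig) -> TrainedModel:
    """Fixed-epoch Adam minimization of cross-entropy; deterministic per seed.

    Inputs are mapped from [0,1] to [-1,1] before the stem for conditioning.
    """
    config.validate()
    counts = train_set.class_counts
    if any(v == 0 for v in counts.values()):
        raise ValueError("training set must contain both classes")
    x, y = _as_tensor(train_set, model.spec)
    x = x * 2.0 - 1.0
    net = model.network
    opt = _nn.Adam(net, lr=config.learning_rate)
    shuffle_rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed), 0xDA7A]))
    n = len(y)
    model.last_epoch_losses = []
    for _epoch in range(config.epochs):
        order = shuffle_rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            logits = net.forward(x[idx])
            loss, glogits = _nn.cross_entropy_grad(logits, y[idx])
            net.backward(glogits)
            opt.step()
            losses.append(loss)
        model.last_epoch_losses.append(float(np.mean(losses)))
    model.trained = True
    return model


def _forward_image(model: TrainedModel, image, capture: str | None = None):
    x = resize_to_input(image, model.spec)[None] * 2.0 - 1.0
    return model.network.forward(x, capture=capture)


def predict(model: TrainedModel, image: PhantomImage | np.ndarray):
    """Softmax confidence scores over (benign, malignant) for one image."""
    from .ensemble import ConfidenceVector
    logits = _forward_image(model, image)
    probs = _nn.softmax(logits.astype(np.float64))[0]
    return ConfidenceVector(scores=(float(probs[0]), float(probs[1])),
                            model_id=model.name)


def predict_batch(model: TrainedModel, dataset: LabeledDataset,
                  batch_size: int = 64):
    """Confidence vectors for every image in a dataset (vectorized)."""
    from .ensemble import ConfidenceVector
    x, _ = _as_tensor(dataset, model.spec)
    x = x * 2.0 - 1.0
    out = []
    for start in range(0, len(x), batch_size):
        logits = model.network.forward(x[start:start + batch_size])
        probs = _nn.softmax(logits.astype(np.float64))
        out.extend(ConfidenceVector(scores=(float(p[0]), float(p[1])),
                                    model_id=model.name) for p in probs)
    return out


def measure_inference_time(model: TrainedModel, image, repeats: int = 11) -> float:
    """Median wall-clock seconds per single-image prediction.

    Hardware-dependent; reported for model selection, never asserted
    against published timings.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    times = []
    for _ in range(repeats):
        t0 = time.perf_counter()
        predict(model, image)
        times.append(time.perf_counter() - t0)
    return float(np.median(times))


# --- persistence -----------------------------------------------------------

def save_model(model: TrainedModel, path) -> None:
    """Single-file .npz archive with the BackboneSpec embedded as JSON."""
    meta = {"name": model.spec.name,
            "input_size": list(model.spec.input_size),
            "block_widths": list(model.spec.block_widths),
            "use_residual": model.spec.use_residual,
            "use_separable": model.spec.use_separable,
            "target_layer": model.spec.target_layer,
            "trained": model.trained}
    state = model.network.get_state()
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_model(path) -> TrainedModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"].tobytes()).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    spec = BackboneSpec(name=meta["name"],
                        input_size=tuple(meta["input_size"]),
                        block_widths=tuple(meta["block_widths"]),
                        use_residual=meta["use_residual"],
                        use_separable=meta["use_separable"],
                        target_layer=meta["target_layer"])
    model = build_backbone(spec, seed=0)
    model.network.set_state(state)
    model.trained = meta["trained"]
    return model
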