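"""Training-set augmentation: horizontal flip, +-30 deg rotation, speckle copies.

The augmentation recipe doubles the training set: each original image is
kept once with a randomized flip/rotation applied in place, and exactly one
speckle-noised copy of the un-noised image is appended, so 1327 training
images become 2654. Speckle is multiplicative: out = clip(I + n*I, 0, 1)
with n zero-mean i.i.d. of the configured variance (uniform by default,
Gaussian selectable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .synthgen import LabeledDataset, PhantomImage


@dataclass(frozen=True)
class AugmentationConfig:
    rotation_angles: tuple[float, ...] = (30.0, -30.0)
    enable_flip: bool = True
    speckle_variance: float = 0.05
    noise_model: str = "uniform"         # or "gaussian"
    seed: int = 0

    def validate(self) -> None:
        if self.speckle_variance < 0:
            raise ValueError("speckle_variance must be non-negative")
        if any(not math.isfinite(a) for a in self.rotation_angles):
            raise ValueError("rotation_angles must be finite")
        if self.noise_model not in ("uniform", "gaussian"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")


def _with_pixels(image: PhantomImage, pixels: np.ndarray) -> PhantomImage:
    return PhantomImage(pixels=pixels, label=image.label,
                        subject_id=image.subject_id, spec=image.spec)


def rotate(image: PhantomImage, angle: float) -> PhantomImage:
    """Rotate about the image center (bilinear, same canvas, zero fill)."""
    if not math.isfinite(angle):
        raise ValueError("angle must be finite")
    if angle == 0:
        return _with_pixels(image, image.pixels.copy())
    out = ndimage.rotate(image.pixels, angle, reshape=False, order=1,
                         mode="constant", cval=0.0)
    return _with_pixels(image, np.clip(out, 0.0, 1.0))


def hflip(image: PhantomImage) -> PhantomImage:
    """Mirror horizontally (reverse column order)."""
    return _with_pixels(image, image.pixels[:, ::-1].copy())


def sample_speckle_multiplier(shape, variance: float, rng: np.random.Generator,
                              noise_model: str = "uniform") -> np.ndarray:
    """Zero-mean noise n with Var(n) = variance.

    Uniform on [-sqrt(3v), +sqrt(3v)] by default; Gaussian optionally.
    """
    if variance < 0:
        raise ValueError("variance must be non-negative")
    if variance == 0:
        return np.zeros(shape)
    if noise_model == "uniform":
        half = math.sqrt(3.0 * variance)
        return rng.uniform(-half, half, size=shape)
    if noise_model == "gaussian":
        return rng.normal(0.0, math.sqrt(variance), size=shape)
    raise ValueError(f"unknown noise_model {noise_model!r}")


def add_speckle(image: PhantomImage, variance: float, seed: int,
                noise_model: str = "uniform") -> PhantomImage:
    """out = clip(I + n * I, 0, 1), n i.i.d. zero-mean with Var(n)=variance."""
    rng = np.random.default_rng(seed)
    n = sample_speckle_multiplier(image.pixels.shape, variance, rng, noise_model)
    out = np.clip(image.pixels + n * image.pixels, 0.0, 1.0)
    return _with_pixels(image, out)


def randomize_in_place(image: PhantomImage, config: AugmentationConfig,
                       rng: np.random.Generator) -> tuple[PhantomImage, str]:
    """Apply the in-place randomization: flip w.p. 1/2, then one rotation
    angle (chosen uniformly from the configured set) w.p. 1/2."""
    tags = []
    out = image
    if config.enable_flip and rng.random() < 0.5:
        out = hflip(out)
        tags.append("flip")
    if len(config.rotation_angles) > 0 and rng.random() < 0.5:
        angle = float(rng.choice(np.asarray(config.rotation_angles, dtype=float)))
        out = rotate(out, angle)
        tags.append(f"rot{angle:+g}")
    if out is image:
        out = _with_pixels(image, image.pixels.copy())
    return out, "+".join(tags) if tags else "none"


def build_augmented_training_set(train: LabeledDataset,
                                 config: AugmentationConfig
                                 ) -> tuple[LabeledDataset, list[str]]:
    """Double the training set per the augmentation recipe.

    Returns the augmented dataset (size exactly 2x the input, labels
    preserved) and a parallel list of augmentation tags, one per output
    image ('none', 'flip', 'rot+30', 'speckle', ...).
    """
    if len(train) == 0:
        raise ValueError("training set is empty")
    config.validate()
    rng = np.random.default_rng(config.seed)
    items: list[PhantomImage] = []
    tags: list[str] = []
    for image in train.items:
        randomized, tag = randomize_in_place(image, config, rng)
        items.append(randomized)
        tags.append(tag)
    for image in train.items:
        noise_seed = int(rng.integers(0, 2**31 - 1))
        items.append(add_speckle(image, config.speckle_variance, noise_seed,
                                 config.noise_model))
        tags.append("speckle")
    return LabeledDataset(items), tags
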