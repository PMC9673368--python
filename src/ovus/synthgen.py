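"""Synthetic ovarian-ultrasound-like phantom generation and dataset splitting.

Real adnexal-mass ultrasound archives are rarely shareable, so this module
renders labeled phantoms that carry the morphological cues sonographers use:
a benign lesion is a smooth, unilocular, hypoechoic (dark) cyst on a
speckle-textured background, while a malignant lesion has an irregular
boundary and internal structure — septations dividing multiple locules,
bright papillary projections, and/or an echogenic solid component. The
intensity model is deliberately schematic (background = base level x
(1 + multiplicative speckle); lesion interior = lower base level); no wave
physics is simulated.

Coordinates are row-major, origin top-left, 0-based; image sizes are (H, W).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

BENIGN = "benign"
MALIGNANT = "malignant"
CLASSES = (BENIGN, MALIGNANT)

# Echogenicity levels on the [0, 1] grayscale, chosen to order
# interior < solid < background < septum < papilla.
_BACKGROUND_LEVEL = 0.55
_INTERIOR_LEVEL = 0.15
_SEPTUM_LEVEL = 0.70
_PAPILLA_LEVEL = 0.80
_SOLID_LEVEL = 0.45
#: variance of the multiplicative speckle texture applied at render time
DEFAULT_SPECKLE_VARIANCE = 0.05

_IRREG_HARMONICS = (3, 4, 5, 6, 7)


@dataclass(frozen=True)
class LesionSpec:
    """Geometry and composition of one lesion, in fractional image units."""

    center: tuple[float, float]          # (row, col) in [0, 1]^2
    semi_axes: tuple[float, float]       # fractions of (H, W), in (0, 0.5]
    boundary_irregularity: float = 0.0   # radial perturbation amplitude
    n_locules: int = 1
    n_papillae: int = 0
    solid_fraction: float = 0.0
    label: str = BENIGN

    def validate(self) -> None:
        cy, cx = self.center
        if not (0.0 <= cy <= 1.0 and 0.0 <= cx <= 1.0):
            raise ValueError(f"center {self.center} outside [0,1]^2")
        for ax in self.semi_axes:
            if not (0.0 < ax <= 0.5):
                raise ValueError(f"semi_axes {self.semi_axes} outside (0, 0.5]")
        if self.boundary_irregularity < 0:
            raise ValueError("boundary_irregularity must be non-negative")
        if self.n_locules < 1:
            raise ValueError("n_locules must be >= 1")
        if self.n_papillae < 0:
            raise ValueError("n_papillae must be non-negative")
        if not (0.0 <= self.solid_fraction <= 1.0):
            raise ValueError(f"solid_fraction {self.solid_fraction} outside [0,1]")
        if self.label not in CLASSES:
            raise ValueError(f"label must be one of {CLASSES}, got {self.label!r}")


@dataclass
class PhantomImage:
    pixels: np.ndarray                   # H x W float in [0, 1]
    label: str
    subject_id: str
    spec: LesionSpec | None = None

    def __post_init__(self):
        h, w = self.pixels.shape
        if h < 32 or w < 32:
            raise ValueError(f"image size {h}x{w} below the 32x32 minimum")


@dataclass
class LabeledDataset:
    items: list[PhantomImage]

    @property
    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CLASSES}
        for it in self.items:
            counts[it.label] += 1
        return counts

    def __len__(self) -> int:
        return len(self.items)

    def subset(self, indices) -> "LabeledDataset":
        return LabeledDataset([self.items[i] for i in indices])


@dataclass(frozen=True)
class SplitPlan:
    train_indices: tuple[int, ...]
    validation_indices: tuple[int, ...]
    train_fraction: float
    seed: int


def _boundary_radius(theta: np.ndarray, spec: LesionSpec,
                     rng: np.random.Generator) -> np.ndarray:
    """Angular boundary profile: 1 plus a normalized harmonic perturbation."""
    if spec.boundary_irregularity == 0:
        return np.ones_like(theta)
    amps = rng.uniform(0.3, 1.0, size=len(_IRREG_HARMONICS))
    phases = rng.uniform(0, 2 * math.pi, size=len(_IRREG_HARMONICS))
    f = np.zeros_like(theta)
    for a, k, ph in zip(amps, _IRREG_HARMONICS, phases):
        f += a * np.cos(k * theta + ph)
    f /= np.abs(f).max()
    return 1.0 + spec.boundary_irregularity * f


def _geometry_rng(seed: int) -> np.random.Generator:
    # Sub-stream shared by render_phantom and lesion_mask so the mask can be
    # recomputed without re-rendering.
    return np.random.default_rng(np.random.SeedSequence([int(seed), 0xC0FFEE]))


def lesion_mask(spec: LesionSpec, size: tuple[int, int], seed: int) -> np.ndarray:
    """Boolean interior mask of the (possibly perturbed) lesion outline."""
    spec.validate()
    h, w = size
    rng = _geometry_rng(seed)
    cy, cx = spec.center[0] * h, spec.center[1] * w
    ay, ax = spec.semi_axes[0] * h, spec.semi_axes[1] * w
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = (yy - cy) / ay, (xx - cx) / ax
    rho = np.sqrt(dy * dy + dx * dx)
    theta = np.arctan2(dy, dx)
    return rho <= _boundary_radius(theta, spec, rng)


def render_phantom(spec: LesionSpec, size: tuple[int, int], seed: int,
                   speckle_variance: float = DEFAULT_SPECKLE_VARIANCE
                   ) -> PhantomImage:
    """Render one phantom. Deterministic in (spec, size, seed).

    The lesion interior (before papillae/solid components) is strictly
    darker than the background; papillae and septa are brighter than the
    interior; multiplicative speckle texture covers the frame.
    """
    spec.validate()
    h, w = size
    if h < 32 or w < 32:
        raise ValueError(f"size {size} below the 32x32 minimum")
    if speckle_variance < 0:
        raise ValueError("speckle_variance must be non-negative")

    geo_rng = _geometry_rng(seed)
    tex_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5EED]))

    cy, cx = spec.center[0] * h, spec.center[1] * w
    ay, ax = spec.semi_axes[0] * h, spec.semi_axes[1] * w
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = (yy - cy) / ay, (xx - cx) / ax
    rho = np.sqrt(dy * dy + dx * dx)
    theta = np.arctan2(dy, dx)
    interior = rho <= _boundary_radius(theta, spec, geo_rng)

    img = np.full((h, w), _BACKGROUND_LEVEL)
    img[interior] = _INTERIOR_LEVEL

    # Septations: Voronoi walls between locule seed points.
    if spec.n_locules > 1:
        pts_y, pts_x = np.nonzero(interior)
        idx = geo_rng.choice(len(pts_y), size=spec.n_locules, replace=False)
        seeds = np.stack([pts_y[idx], pts_x[idx]], axis=1).astype(float)
        d = np.sqrt((yy[..., None] - seeds[:, 0]) ** 2
                    + (xx[..., None] - seeds[:, 1]) ** 2)
        d.sort(axis=-1)
        wall = interior & (d[..., 1] - d[..., 0] < 1.2)
        img[wall] = _SEPTUM_LEVEL

    # Solid component: a contiguous echogenic cap of the requested area share.
    if spec.solid_fraction > 0:
        ang = geo_rng.uniform(0, 2 * math.pi)
        proj = np.cos(ang) * dy + np.sin(ang) * dx
        vals = proj[interior]
        cut = np.quantile(vals, 1.0 - spec.solid_fraction)
        img[interior & (proj >= cut)] = _SOLID_LEVEL

    # Papillary projections: disjoint bright blobs fully inside the
    # interior. The radius shrinks for small lesions/canvases; if a
    # configuration leaves no room, the radius is reduced (never below one
    # pixel) before giving up, keeping the exact blob count guaranteed.
    if spec.n_papillae > 0:
        r_pap = max(2.0, 0.06 * min(ay, ax))
        placed: list[tuple[float, float]] = []
        while r_pap >= 1.0 and len(placed) < spec.n_papillae:
            margin = int(math.ceil(r_pap)) + 1
            eroded = ndimage.binary_erosion(interior, iterations=margin)
            cand_y, cand_x = np.nonzero(eroded)
            placed = []
            if len(cand_y) == 0:
                r_pap -= 0.5
                continue
            min_sep_sq = (2 * r_pap + 2) ** 2
            for _ in range(3000):
                j = geo_rng.integers(len(cand_y))
                py, px = float(cand_y[j]), float(cand_x[j])
                if all((py - q) ** 2 + (px - r) ** 2 > min_sep_sq
                       for q, r in placed):
                    placed.append((py, px))
                    if len(placed) == spec.n_papillae:
                        break
            if len(placed) < spec.n_papillae:
                r_pap -= 0.5
        if len(placed) < spec.n_papillae:
            raise ValueError("could not place disjoint papillae; "
                             "reduce n_papillae or enlarge semi_axes")
        for py, px in placed:
            blob = (yy - py) ** 2 + (xx - px) ** 2 <= r_pap ** 2
            img[blob & interior] = _PAPILLA_LEVEL

    if speckle_variance > 0:
        half = math.sqrt(3.0 * speckle_variance)
        noise = tex_rng.uniform(-half, half, size=(h, w))
        img = img * (1.0 + noise)

    img = np.clip(img, 0.0, 1.0)
    return PhantomImage(pixels=img, label=spec.label,
                        subject_id=f"synthetic-{spec.label}-{seed}", spec=spec)


def _draw_spec(label: str, rng: np.random.Generator) -> LesionSpec:
    center = (rng.uniform(0.42, 0.58), rng.uniform(0.42, 0.58))
    semi = (rng.uniform(0.18, 0.32), rng.uniform(0.18, 0.32))
    if label == BENIGN:
        return LesionSpec(center=center, semi_axes=semi, label=BENIGN)
    spec = LesionSpec(
        center=center,
        semi_axes=semi,
        boundary_irregularity=rng.uniform(0.08, 0.22),
        n_locules=int(rng.integers(1, 4)),
        n_papillae=int(rng.integers(0, 4)),
        solid_fraction=float(rng.choice([0.0, rng.uniform(0.1, 0.35)])),
        label=MALIGNANT,
    )
    if spec.n_locules == 1 and spec.n_papillae == 0 and spec.solid_fraction == 0:
        spec = replace(spec, n_papillae=1)
    return spec


def generate_dataset(n_per_class: int, size: tuple[int, int] = (96, 128),
                     seed: int = 0,
                     speckle_variance: float = DEFAULT_SPECKLE_VARIANCE
                     ) -> LabeledDataset:
    """Generate a balanced dataset of 2 x n_per_class phantoms."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    items = []
    for i in range(n_per_class):
        for label in CLASSES:
            spec = _draw_spec(label, rng)
            img_seed = int(rng.integers(0, 2**31 - 1))
            img = render_phantom(spec, size, img_seed,
                                 speckle_variance=speckle_variance)
            img.subject_id = f"{label}-{i:05d}"
            items.append(img)
    return LabeledDataset(items)


def split_dataset(dataset: LabeledDataset, train_fraction: float, seed: int,
                  mode: str = "pooled") -> SplitPlan:
    """Seeded random train/validation partition of a dataset.

    ``pooled`` shuffles all indices together and takes
    floor(train_fraction * N) for training; ``per_class`` applies the floor
    within each class separately.
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    if not (0.0 < train_fraction < 1.0):
        raise ValueError(f"train_fraction {train_fraction} outside (0, 1)")
    if mode not in ("pooled", "per_class"):
        raise ValueError(f"unknown split mode {mode!r}")
    rng = np.random.default_rng(seed)
    if mode == "pooled":
        order = rng.permutation(len(dataset))
        n_train = int(math.floor(train_fraction * len(dataset)))
        train, val = order[:n_train], order[n_train:]
    else:
        train_parts, val_parts = [], []
        for label in CLASSES:
            idx = np.array([i for i, it in enumerate(dataset.items)
                            if it.label == label], dtype=int)
            order = idx[rng.permutation(len(idx))]
            k = int(math.floor(train_fraction * len(idx)))
            train_parts.append(order[:k])
            val_parts.append(order[k:])
        train = np.concatenate(train_parts)
        val = np.concatenate(val_parts)
    return SplitPlan(train_indices=tuple(int(i) for i in train),
                     validation_indices=tuple(int(i) for i in val),
                     train_fraction=train_fraction, seed=seed)


def boundary_roughness(mask: np.ndarray) -> float:
    """Harmonic-residual roughness of a lesion outline.

    The boundary radius r(theta) about the centroid is fit with low-order
    harmonics (0, 1, 2 plus the even ellipse overtones 4 and 6); the
    relative RMS residual captures the irregular components a smooth
    (possibly eccentric) ellipse cannot produce. Near zero for smooth
    lesions, clearly positive for perturbed ones — so a simple threshold on
    this statistic separates the two classes on noise-free masks without
    any learning.
    """
    if not mask.any():
        raise ValueError("empty mask")
    cy, cx = ndimage.center_of_mass(mask)
    boundary = mask & ~ndimage.binary_erosion(mask)
    by, bx = np.nonzero(boundary)
    dy, dx = by - cy, bx - cx
    r = np.sqrt(dy * dy + dx * dx)
    theta = np.arctan2(dy, dx)
    cols = [np.ones_like(theta)]
    for k in (1, 2, 4, 6):
        cols += [np.cos(k * theta), np.sin(k * theta)]
    design = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(design, r, rcond=None)
    resid = r - design @ coef
    return float(np.sqrt(np.mean(resid**2)) / r.mean())


# ---------------------------------------------------------------------------
# Manifest I/O: 8-bit grayscale PNGs plus a CSV (filename, label, subject_id,
# seed). External datasets are read through the same schema.
# ---------------------------------------------------------------------------

def save_dataset(dataset: LabeledDataset, out_dir, seed: int = 0) -> "str":
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, item in enumerate(dataset.items):
        fname = f"{item.subject_id}_{i:05d}.png"
        arr = np.round(np.clip(item.pixels, 0, 1) * 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(out / fname)
        rows.append({"filename": fname, "label": item.label,
                     "subject_id": item.subject_id, "seed": seed})
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return str(manifest)


def load_dataset(manifest_path) -> LabeledDataset:
    from pathlib import Path
    manifest = Path(manifest_path)
    df = pd.read_csv(manifest)
    required = {"filename", "label", "subject_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest missing columns {required - set(df.columns)}")
    bad = set(df["label"]) - set(CLASSES)
    if bad:
        raise ValueError(f"labels must be 'benign' or 'malignant'; got {bad}")
    items = []
    for _, row in df.iterrows():
        with Image.open(manifest.parent / row["filename"]) as im:
            arr = np.asarray(im.convert("L"), dtype=np.float64) / 255.0
        items.append(PhantomImage(pixels=arr, label=row["label"],
                                  subject_id=str(row["subject_id"])))
    return LabeledDataset(items)
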