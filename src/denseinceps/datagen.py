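"""Image I/O, augmentation/balancing, and a synthetic brain-phantom generator.

Real studies consume class-per-subdirectory folders of 2-D brain MRI
slices.  The phantom generator emulates that layout in memory: each
image is a dark background with a bright skull ellipse, a cortical
ribbon whose thickness shrinks across classes, and a central dark
"ventricle" ellipse whose area grows across classes — a crude proxy for
the ventricular enlargement and cortical atrophy that distinguish
dementia stages.  The strictly ordered per-class morphology guarantees
the staging task is learnable, so the whole pipeline can be exercised
without any external download.

Augmentation follows the flip/rotation scheme used for class balancing:
horizontal flip, vertical flip and rotations of +/-{5,10,15} degrees,
sampled uniformly over random originals until each class reaches the
target count.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "ImageDataset",
    "PhantomConfig",
    "load_image_folder",
    "augment",
    "generate_phantoms",
    "split",
    "save_image_folder",
    "ventricle_mask",
]

INPUT_SIZE = 227


@dataclass
class ImageDataset:
    images: list                      # H x W x 3 float arrays in [0,1]
    labels: list                      # class-name strings, parallel to images
    provenance: str = "synthetic"     # real | synthetic | augmented

    def __post_init__(self):
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels must be parallel")

    def __len__(self):
        return len(self.images)

    @property
    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for lab in self.labels:
            counts[lab] = counts.get(lab, 0) + 1
        return counts

    @property
    def class_names(self) -> list[str]:
        return sorted(set(self.labels))

    def as_arrays(self):
        """(n, H, W, 3) float32 stack and integer labels (sorted class order)."""
        names = self.class_names
        lut = {c: i for i, c in enumerate(names)}
        X = np.stack(self.images).astype(np.float32)
        y = np.array([lut[lab] for lab in self.labels], dtype=int)
        return X, y, names

    def subset(self, idx) -> "ImageDataset":
        return ImageDataset([self.images[i] for i in idx],
                            [self.labels[i] for i in idx], self.provenance)


@dataclass
class PhantomConfig:
    n_classes: int = 5
    per_class: int = 40
    # per-class ventricle area factor (atrophy proxy), strictly increasing
    ventricle_scale: tuple = (0.6, 0.9, 1.2, 1.5, 1.8)
    # per-class cortical ribbon thickness in pixels, strictly decreasing
    cortical_thickness: tuple = (22, 19, 16, 13, 10)
    noise_sd: float = 0.05
    size: int = INPUT_SIZE
    seed: int = 0

    def __post_init__(self):
        if self.n_classes not in (4, 5):
            raise ValueError("n_classes must be 4 or 5")
        vs = self.ventricle_scale[:self.n_classes]
        if any(b <= a for a, b in zip(vs, vs[1:])):
            raise ValueError("ventricle_scale must be strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def class_names(self) -> list[str]:
        # stage index increases with disease severity (larger ventricles,
        # thinner cortex); names sort in severity order by construction
        return [f"stage{i}" for i in range(self.n_classes)]


# ---------------------------------------------------------------------------
# phantom synthesis

def _ellipse_mask(size, cy, cx, ry, rx, yy=None, xx=None):
    if yy is None:
        yy, xx = np.mgrid[0:size, 0:size]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def ventricle_mask(cfg: PhantomConfig, class_index: int) -> np.ndarray:
    """Nominal central ventricle region of a class (no jitter), for probes."""
    s = cfg.size
    scale = cfg.ventricle_scale[class_index]
    return _ellipse_mask(s, s / 2, s / 2, 16 * scale, 10 * scale)


def _render_phantom(cfg: PhantomConfig, class_index: int,
                    rng: np.random.Generator) -> np.ndarray:
    s = cfg.size
    yy, xx = np.mgrid[0:s, 0:s]
    img = np.zeros((s, s), dtype=np.float64)
    cy = s / 2 + rng.uniform(-4, 4)
    cx = s / 2 + rng.uniform(-4, 4)
    ry = s * 0.42 * (1 + rng.uniform(-0.03, 0.03))
    rx = s * 0.34 * (1 + rng.uniform(-0.03, 0.03))
    skull = _ellipse_mask(s, cy, cx, ry, rx, yy, xx)
    brain = _ellipse_mask(s, cy, cx, ry - 6, rx - 6, yy, xx)
    img[skull] = 0.9                           # bright skull shell
    img[brain] = 0.35                          # white/gray matter base
    th = cfg.cortical_thickness[class_index]
    cortex = brain & ~_ellipse_mask(s, cy, cx, ry - 6 - th, rx - 6 - th, yy, xx)
    img[cortex] = 0.65                         # cortical ribbon
    vscale = cfg.ventricle_scale[class_index] * (1 + rng.uniform(-0.08, 0.08))
    vent = _ellipse_mask(s, cy, cx, 16 * vscale, 10 * vscale, yy, xx)
    img[vent] = 0.05                           # dark CSF-filled ventricles
    img += rng.normal(0.0, cfg.noise_sd, size=img.shape)
    np.clip(img, 0.0, 1.0, out=img)
    return np.repeat(img[:, :, None], 3, axis=2).astype(np.float32)


def generate_phantoms(cfg: PhantomConfig) -> ImageDataset:
    """Deterministic (per seed) balanced synthetic dataset."""
    rng = np.random.default_rng(cfg.seed)
    images, labels = [], []
    for ci, name in enumerate(cfg.class_names):
        for _ in range(cfg.per_class):
            images.append(_render_phantom(cfg, ci, rng))
            labels.append(name)
    return ImageDataset(images, labels, provenance="synthetic")


# ---------------------------------------------------------------------------
# folder I/O

def load_image_folder(path) -> ImageDataset:
    """Class-per-subdirectory PNG/JPEG folder -> 227x227x3 arrays in [0,1].

    Images are decoded as grayscale, bilinearly resized, and replicated
    to three channels.
    """
    classes = sorted(d for d in os.listdir(path)
                     if os.path.isdir(os.path.join(path, d)))
    if not classes:
        raise ValueError(f"no class subdirectories under {path!r}")
    images, labels = [], []
    for cls in classes:
        cdir = os.path.join(path, cls)
        files = sorted(f for f in os.listdir(cdir)
                       if f.lower().endswith((".png", ".jpg", ".jpeg")))
        if not files:
            raise ValueError(f"class directory {cdir!r} contains no images")
        for fname in files:
            fpath = os.path.join(cdir, fname)
            try:
                with Image.open(fpath) as im:
                    gray = im.convert("L").resize(
                        (INPUT_SIZE, INPUT_SIZE), Image.BILINEAR)
            except Exception as exc:
                raise ValueError(f"cannot decode image {fpath!r}: {exc}") from exc
            arr = np.asarray(gray, dtype=np.float32) / 255.0
            images.append(np.repeat(arr[:, :, None], 3, axis=2))
            labels.append(cls)
    return ImageDataset(images, labels, provenance="real")


def save_image_folder(ds: ImageDataset, path):
    """Write the dataset back out in the same class-per-subdirectory layout."""
    counters: dict[str, int] = {}
    for img, lab in zip(ds.images, ds.labels):
        cdir = os.path.join(path, lab)
        os.makedirs(cdir, exist_ok=True)
        counters[lab] = counters.get(lab, 0) + 1
        gray = (np.clip(img[:, :, 0], 0, 1) * 255).astype(np.uint8)
        Image.fromarray(gray).save(os.path.join(cdir, f"{counters[lab]:05d}.png"))


# ---------------------------------------------------------------------------
# augmentation and splitting

_ANGLES = (-15, -10, -5, 5, 10, 15)


def _augment_one(img: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    op = rng.integers(3)
    if op == 0:
        return img[:, ::-1].copy()             # horizontal flip
    if op == 1:
        return img[::-1, :].copy()             # vertical flip
    angle = _ANGLES[rng.integers(len(_ANGLES))]
    out = ndimage.rotate(img, angle, axes=(0, 1), reshape=False,
                         order=1, mode="constant", cval=0.0)
    return np.clip(out, 0.0, 1.0).astype(img.dtype)


def augment(ds: ImageDataset, target_per_class: int, seed: int = 0) -> ImageDataset:
    """Balance every class to exactly ``target_per_class`` samples.

    Originals are retained; new samples are flips/rotations of randomly
    chosen originals of the same class.
    """
    counts = ds.class_counts
    if any(c == 0 for c in counts.values()):
        raise ValueError("cannot augment an empty class")
    if target_per_class < max(counts.values()):
        raise ValueError("target below an existing class count")
    rng = np.random.default_rng(seed)
    images = list(ds.images)
    labels = list(ds.labels)
    for cls in sorted(counts):
        idx = [i for i, lab in enumerate(ds.labels) if lab == cls]
        for _ in range(target_per_class - len(idx)):
            src = idx[rng.integers(len(idx))]
            images.append(_augment_one(ds.images[src], rng))
            labels.append(cls)
    return ImageDataset(images, labels, provenance="augmented")


def split(ds: ImageDataset, train_fraction: float = 0.7,
          seed: int = 0) -> tuple[ImageDataset, ImageDataset]:
    """Seeded stratified train/test split (disjoint, exhaustive)."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for cls, count in sorted(ds.class_counts.items()):
        if count < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")
        idx = np.array([i for i, lab in enumerate(ds.labels) if lab == cls])
        rng.shuffle(idx)
        n_train = int(round(train_fraction * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train_idx.extend(idx[:n_train])
        test_idx.extend(idx[n_train:])
    return ds.subset(sorted(train_idx)), ds.subset(sorted(test_idx))
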