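"""Synthetic wireless-capsule-endoscopy-like image generator.

Produces labelled RGB frames that mimic the gross statistics of WCE data —
a smooth pink/tan mucosa texture under radial illumination with vignetting —
plus class-specific lesion features and exact ground-truth lesion masks:

* ``bleeding``  — an irregular, saturated bright-red blob;
* ``ulcer``     — a pale crater disc with a darker rim;
* ``polyp``     — a raised circular bump with directional shading;
* ``avm``       — thin dark-red dendritic streaks (arteriovenous
  malformation);
* any label containing ``normal`` or starting with ``non`` — background only.

All colour and shape constants are fixed module-level values so any contrast
statistic (e.g. mean red-channel excess inside the bleeding mask) can be
recomputed exactly from the emitted images and masks.  Generation is fully
deterministic under the spec seed.  Images live in [0, 1]; 8-bit
quantization happens only when writing PNGs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .nn import ConfigurationError
from .routing import InputError

GENERATOR_VERSION = "1.0"

# mucosa palette and lesion colours (RGB, [0,1])
MUCOSA_BASE = np.array([0.78, 0.46, 0.40])
MUCOSA_VARIATION = np.array([0.10, 0.08, 0.06])
BLEEDING_COLOR = np.array([0.86, 0.05, 0.06])
ULCER_CORE_COLOR = np.array([0.92, 0.88, 0.72])
ULCER_RIM_COLOR = np.array([0.48, 0.20, 0.16])
POLYP_COLOR = np.array([0.88, 0.58, 0.50])
AVM_COLOR = np.array([0.60, 0.06, 0.08])

LESION_FEATURES = ("bleeding", "ulcer", "polyp", "avm")


@dataclass
class SyntheticSpec:
    """Generator parameters.

    ``lesion_contrast`` in (0, 1] scales how strongly lesion colour replaces
    the background (1 = full replacement); ``texture_scale`` is the spatial
    correlation length of the mucosa field in pixels; ``noise_sd`` is the
    per-pixel Gaussian noise level.
    """

    classes: tuple[str, ...] = ("non-bleeding", "bleeding")
    n_per_class: int = 100
    image_size: int = 224
    lesion_radius_range: tuple[float, float] | None = None
    lesion_contrast: float = 0.5
    texture_scale: float = 16.0
    noise_sd: float = 0.02
    illumination_gradient: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_per_class < 1:
            raise ConfigurationError("n_per_class must be >= 1")
        if not 0 < self.lesion_contrast <= 1:
            raise ConfigurationError("lesion_contrast must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")
        if self.lesion_radius_range is None:
            # default: lesions span roughly 1/10 to 1/4 of the frame
            self.lesion_radius_range = (self.image_size / 10, self.image_size / 4)
        lo, hi = self.lesion_radius_range
        if hi > self.image_size / 2:
            raise ConfigurationError("lesion radius must fit inside the image")
        for cls in self.classes:
            _feature_for_class(cls)  # raises on unknown class names


@dataclass
class LabeledImageSet:
    """In-memory dataset: images (n, H, W, 3) in [0,1], integer labels,
    binary lesion masks (n, H, W) and the ordered class-name list."""

    images: np.ndarray
    labels: np.ndarray
    masks: np.ndarray
    classes: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.images)

    def subset(self, idx: np.ndarray) -> "LabeledImageSet":
        return LabeledImageSet(
            self.images[idx], self.labels[idx], self.masks[idx], self.classes
        )


def _feature_for_class(name: str) -> str | None:
    """Map a class label to its lesion feature, or None for lesion-free."""
    low = name.lower().replace("_", "-")
    if "normal" in low or low.startswith("non"):
        return None
    for feat in LESION_FEATURES:
        if feat in low:
            return feat
    raise ConfigurationError(
        f"unknown class feature {name!r}; supported features are "
        f"{LESION_FEATURES} or labels containing 'normal'/'non-'"
    )


# -- scene pieces ------------------------------------------------------------


def _mucosa_background(size: int, texture_scale: float, illumination: bool,
                       rng: np.random.Generator) -> np.ndarray:
    field_ = rng.normal(size=(size, size, 3))
    smooth = ndimage.gaussian_filter(field_, sigma=(texture_scale, texture_scale, 0))
    smooth /= np.abs(smooth).max() + 1e-9
    img = MUCOSA_BASE + smooth * MUCOSA_VARIATION
    if illumination:
        yy, xx = np.mgrid[0:size, 0:size]
        cy = size / 2 + rng.uniform(-size / 8, size / 8)
        cx = size / 2 + rng.uniform(-size / 8, size / 8)
        r = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2) / (size / np.sqrt(2))
        img *= (1.0 - 0.45 * r**2)[..., None]
    return np.clip(img, 0.0, 1.0)


def _irregular_blob(size: int, radius: float, rng: np.random.Generator
                    ) -> np.ndarray:
    """Soft [0,1] membership of a harmonically perturbed disc."""
    margin = radius * 1.4
    cy = rng.uniform(margin, size - margin)
    cx = rng.uniform(margin, size - margin)
    yy, xx = np.mgrid[0:size, 0:size]
    theta = np.arctan2(yy - cy, xx - cx)
    rr = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    wobble = np.zeros_like(theta)
    for k in range(2, 6):
        wobble += rng.uniform(0, 0.25 / k) * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
    local_r = radius * (1.0 + wobble)
    return np.clip((local_r - rr) / (0.15 * radius) + 0.5, 0.0, 1.0)


def _disc(size: int, radius: float, rng: np.random.Generator
          ) -> tuple[np.ndarray, np.ndarray, float, float]:
    margin = radius * 1.3
    cy = rng.uniform(margin, size - margin)
    cx = rng.uniform(margin, size - margin)
    yy, xx = np.mgrid[0:size, 0:size]
    rr = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    return rr, np.clip((radius - rr) / (0.1 * radius) + 0.5, 0, 1), cy, cx


def _dendrite(size: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    """Thin branching streaks drawn by biased random walks from a centre."""
    canvas = np.zeros((size, size))
    margin = radius * 1.2
    cy = rng.uniform(margin, size - margin)
    cx = rng.uniform(margin, size - margin)
    n_branches = rng.integers(4, 7)
    for _ in range(n_branches):
        y, x = cy, cx
        ang = rng.uniform(0, 2 * np.pi)
        for _ in range(int(radius * 2)):
            ang += rng.normal(0, 0.35)
            y += np.sin(ang)
            x += np.cos(ang)
            iy, ix = int(round(y)), int(round(x))
            if 0 <= iy < size and 0 <= ix < size:
                canvas[iy, ix] = 1.0
            else:
                break
    return np.clip(ndimage.gaussian_filter(canvas, 0.8) * 2.5, 0, 1)


def _render_lesion(feature: str, size: int, spec: SyntheticSpec,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Return (soft alpha map (H,W), colour image (H,W,3)) for one lesion."""
    lo, hi = spec.lesion_radius_range
    radius = rng.uniform(lo, hi)
    colour = np.zeros((size, size, 3))
    if feature == "bleeding":
        alpha = _irregular_blob(size, radius, rng)
        colour[:] = BLEEDING_COLOR
    elif feature == "ulcer":
        rr, core, _, _ = _disc(size, radius, rng)
        rim = np.clip(1 - np.abs(rr - radius) / (0.25 * radius), 0, 1)
        alpha = np.clip(core + rim, 0, 1)
        w = np.clip(core, 0, 1)[..., None]
        colour = w * ULCER_CORE_COLOR + (1 - w) * ULCER_RIM_COLOR
    elif feature == "polyp":
        rr, alpha, cy, cx = _disc(size, radius, rng)
        yy, xx = np.mgrid[0:size, 0:size]
        # directional shading: brighter toward the upper-left of the bump
        shade = 1.0 + 0.35 * ((cx - xx) + (cy - yy)) / (radius + 1e-9)
        dome = np.sqrt(np.clip(1 - (rr / (radius + 1e-9)) ** 2, 0, 1))
        shade = np.clip(shade * (0.6 + 0.4 * dome), 0.4, 1.4)
        colour = np.clip(POLYP_COLOR * shade[..., None], 0, 1)
    elif feature == "avm":
        alpha = _dendrite(size, radius, rng)
        colour[:] = AVM_COLOR
    else:  # pragma: no cover - guarded by _feature_for_class
        raise ConfigurationError(f"unknown feature {feature!r}")
    return alpha, colour


def generate_image(cls: str, spec: SyntheticSpec, rng: np.random.Generator
                   ) -> tuple[np.ndarray, np.ndarray]:
    """One (image, mask) pair for class ``cls``."""
    size = spec.image_size
    img = _mucosa_background(size, spec.texture_scale,
                             spec.illumination_gradient, rng)
    feature = _feature_for_class(cls)
    mask = np.zeros((size, size), dtype=bool)
    if feature is not None:
        alpha, colour = _render_lesion(feature, size, spec, rng)
        blend = (alpha * spec.lesion_contrast)[..., None]
        img = (1 - blend) * img + blend * colour
        mask = alpha > 0.5
    if spec.noise_sd > 0:
        img = img + rng.normal(0, spec.noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0), mask


def generate_dataset(spec: SyntheticSpec) -> LabeledImageSet:
    """Deterministically generate ``n_per_class`` images for every class."""
    ss = np.random.SeedSequence(spec.seed)
    child_seeds = ss.spawn(len(spec.classes) * spec.n_per_class)
    n = len(spec.classes) * spec.n_per_class
    size = spec.image_size
    images = np.empty((n, size, size, 3))
    labels = np.empty(n, dtype=np.int64)
    masks = np.zeros((n, size, size), dtype=bool)
    i = 0
    for ci, cls in enumerate(spec.classes):
        for _ in range(spec.n_per_class):
            rng = np.random.default_rng(child_seeds[i])
            images[i], masks[i] = generate_image(cls, spec, rng)
            labels[i] = ci
            i += 1
    return LabeledImageSet(images, labels, masks, tuple(spec.classes))


# -- splitting ---------------------------------------------------------------


def train_val_split(dataset: LabeledImageSet, train_fraction: float = 0.8,
                    seed: int = 0) -> tuple[LabeledImageSet, LabeledImageSet]:
    """Stratified split: per class, a seeded permutation is cut at
    ``round(train_fraction * n_class)``.  Partitions are disjoint and their
    union is the dataset."""
    if not 0 < train_fraction < 1:
        raise ConfigurationError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx, val_idx = [], []
    for ci in np.unique(dataset.labels):
        idx = np.flatnonzero(dataset.labels == ci)
        if len(idx) < 2:
            raise InputError(
                f"class {dataset.classes[ci]!r} has {len(idx)} sample(s); "
                "need at least 2 to split"
            )
        perm = rng.permutation(idx)
        k = int(round(train_fraction * len(idx)))
        k = min(max(k, 1), len(idx) - 1)
        train_idx.append(perm[:k])
        val_idx.append(perm[k:])
    return (
        dataset.subset(np.sort(np.concatenate(train_idx))),
        dataset.subset(np.sort(np.concatenate(val_idx))),
    )


# -- image-folder IO ---------------------------------------------------------


def write_image_folder(dataset: LabeledImageSet, path: str | Path) -> None:
    """Class-per-directory PNG layout with masks in a parallel ``_masks``
    tree and a ``dataset.json`` manifest."""
    root = Path(path)
    for ci, cls in enumerate(dataset.classes):
        (root / cls).mkdir(parents=True, exist_ok=True)
        (root / "_masks" / cls).mkdir(parents=True, exist_ok=True)
    counters = {cls: 0 for cls in dataset.classes}
    for img, label, mask in zip(dataset.images, dataset.labels, dataset.masks):
        cls = dataset.classes[label]
        idx = counters[cls]
        counters[cls] += 1
        Image.fromarray(
            (np.clip(img, 0, 1) * 255).round().astype(np.uint8)
        ).save(root / cls / f"{idx}.png")
        Image.fromarray((mask.astype(np.uint8)) * 255).save(
            root / "_masks" / cls / f"{idx}.png"
        )
    manifest = {
        "classes": list(dataset.classes),
        "counts": {cls: int(n) for cls, n in counters.items()},
        "generator_version": GENERATOR_VERSION,
    }
    (root / "dataset.json").write_text(json.dumps(manifest, indent=2))


def read_image_folder(path: str | Path) -> LabeledImageSet:
    """Read a class-per-directory PNG layout written by
    :func:`write_image_folder` (or any folder of class subdirectories)."""
    root = Path(path)
    manifest_path = root / "dataset.json"
    if manifest_path.exists():
        classes = tuple(json.loads(manifest_path.read_text())["classes"])
    else:
        classes = tuple(sorted(
            p.name for p in root.iterdir()
            if p.is_dir() and not p.name.startswith("_")
        ))
    if not classes:
        raise InputError(f"no class directories found under {root}")
    images, labels, masks = [], [], []
    for ci, cls in enumerate(classes):
        cdir = root / cls
        files = sorted(cdir.glob("*.png"), key=lambda p: int(p.stem))
        if not files:
            raise InputError(f"class directory {cdir} is empty")
        for f in files:
            img = np.asarray(Image.open(f).convert("RGB"), dtype=np.float64) / 255.0
            images.append(img)
            labels.append(ci)
            mask_file = root / "_masks" / cls / f.name
            if mask_file.exists():
                masks.append(np.asarray(Image.open(mask_file)) > 127)
            else:
                masks.append(np.zeros(img.shape[:2], dtype=bool))
    return LabeledImageSet(
        np.stack(images), np.array(labels, dtype=np.int64), np.stack(masks), classes
    )
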