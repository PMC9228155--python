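"""Deterministic generator of fruit-like synthetic image datasets.

Emulates the statistical structure of turntable fruit captures: a single
object per 100x100 RGB frame on a white background, the object slowly
rotating across frames, and a roughly 70/30 train/test split per class.  The
object model is a lobed ellipse (radius ``r(theta) = r0 * (1 + lobedness *
cos(n_lobes * theta))``) filled with a class-specific hue and an optional
stripe or spot texture, plus small per-pixel noise; the silhouette boundary
is antialiased with a 1-px soft edge.  The appearance model makes no claim
to fruit photometry — it reproduces the properties the downstream pipeline
relies on (one object, white background, pose sweep, class-separable colour
and texture).

Everything is reproducible bit-exactly from ``(class specs, seed)``.
"""

from __future__ import annotations

import colorsys
import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

__all__ = [
    "ClassSpec",
    "SynthDataset",
    "make_class_specs",
    "render",
    "generate",
]

FRAME = 100  # default frame side, px
_TEXTURES = ("plain", "stripes", "spots")


@dataclass(frozen=True)
class ClassSpec:
    """Appearance parameters for one synthetic class."""

    class_id: int
    base_hue: float            # degrees in [0, 360)
    hue_jitter: float = 4.0    # per-image jitter amplitude, degrees
    semi_axis_a: float = 28.0  # px
    semi_axis_b: float = 22.0  # px
    lobedness: float = 0.08    # radial perturbation amplitude
    n_lobes: int = 4
    texture: str = "plain"
    texture_freq: float = 0.25  # cycles per px
    texture_contrast: float = 0.25
    size_jitter: float = 0.05   # fractional per-image size variation

    def __post_init__(self) -> None:
        if not (0 <= self.base_hue < 360):
            raise ValueError("base_hue must lie in [0, 360)")
        if self.texture not in _TEXTURES:
            raise ValueError(f"texture must be one of {_TEXTURES}")
        margin = max(self.semi_axis_a, self.semi_axis_b) * (
            1 + abs(self.lobedness)
        ) * (1 + self.size_jitter)
        if margin > FRAME / 2 - 4:
            raise ValueError("object does not fit the frame with 4 px margin")


def make_class_specs(n_classes: int, seed: int = 0,
                     separability: float = 1.0) -> list[ClassSpec]:
    """Draw class specs with hue spacing controlled by ``separability``.

    Class hues sit on an evenly spaced wheel (minimum pairwise distance
    ``360/n_classes`` at ``separability = 1``); lower separability adds hue
    jitter that makes neighbouring classes overlap.  Shape and texture
    parameters vary freely per class.
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if not (0 < separability <= 1):
        raise ValueError("separability must lie in (0, 1]")
    slot = 360.0 / n_classes
    jitter = (1 - separability) * slot / 2 + 2.0
    if slot < 3.0:
        raise ValueError(
            f"{n_classes} classes exceed the distinguishable hue slots at "
            f"separability {separability} (slot width {slot:.2f} deg < 3 deg)"
        )
    rng = np.random.default_rng(seed)
    hue0 = float(rng.uniform(0, slot))
    specs = []
    for c in range(n_classes):
        a = float(rng.uniform(20, 30))
        specs.append(ClassSpec(
            class_id=c,
            base_hue=(hue0 + c * slot) % 360.0,
            hue_jitter=jitter,
            semi_axis_a=a,
            semi_axis_b=a * float(rng.uniform(0.7, 1.0)),
            lobedness=float(rng.uniform(0.0, 0.12)),
            n_lobes=int(rng.integers(3, 7)),
            texture=_TEXTURES[int(rng.integers(0, len(_TEXTURES)))],
            texture_freq=float(rng.uniform(0.1, 0.4)),
            texture_contrast=float(rng.uniform(0.1, 0.3)),
            size_jitter=0.05,
        ))
    return specs


def render(spec: ClassSpec, pose_angle: float, noise_seed: int,
           size: int = FRAME) -> np.ndarray:
    """Render one frame: the class object rotated to ``pose_angle`` degrees.

    Returns a ``(size, size, 3)`` uint8 array; background is pure white,
    the silhouette edge gets a 1-px antialiased blend.
    """
    rng = np.random.default_rng(noise_seed)
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    cx = cy = (size - 1) / 2.0
    x, y = xx - cx, yy - cy
    phi = np.deg2rad(pose_angle)
    # rotate the object frame by the pose angle
    xr = np.cos(phi) * x + np.sin(phi) * y
    yr = -np.sin(phi) * x + np.cos(phi) * y
    scale = 1.0 + spec.size_jitter * float(rng.uniform(-1, 1))
    a, b = spec.semi_axis_a * scale, spec.semi_axis_b * scale
    theta = np.arctan2(yr, xr)
    rho = np.hypot(xr, yr)
    base_r = 1.0 / np.sqrt((np.cos(theta) / a) ** 2
                           + (np.sin(theta) / b) ** 2)
    boundary = base_r * (1.0 + spec.lobedness * np.cos(spec.n_lobes * theta))
    alpha = np.clip(boundary - rho + 0.5, 0.0, 1.0)  # 1-px soft edge

    hue = (spec.base_hue + spec.hue_jitter * float(rng.uniform(-1, 1))) % 360
    sat, val = 0.85, 0.85
    if spec.texture == "stripes":
        mod = spec.texture_contrast * np.sin(
            2 * np.pi * spec.texture_freq * xr
        )
        val_map = np.clip(val * (1 + mod), 0, 1)
    elif spec.texture == "spots":
        mod = (np.sin(2 * np.pi * spec.texture_freq * xr)
               * np.sin(2 * np.pi * spec.texture_freq * yr))
        val_map = np.clip(val * (1 + spec.texture_contrast * mod), 0, 1)
    else:
        val_map = np.full_like(alpha, val)
    r0, g0, b0 = colorsys.hsv_to_rgb(hue / 360.0, sat, 1.0)
    obj = np.stack([r0 * val_map, g0 * val_map, b0 * val_map], axis=-1)
    obj = obj * 255.0 + rng.normal(0.0, 3.0, obj.shape)  # pixel noise
    obj = np.clip(obj, 0, 255)
    white = np.full((size, size, 3), 255.0)
    img = alpha[..., None] * obj + (1 - alpha[..., None]) * white
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def _split_mask(per_class: int, n_test: int) -> np.ndarray:
    """Evenly interleave ``n_test`` test frames over the pose sweep."""
    mask = np.zeros(per_class, dtype=bool)  # True = test
    for i in range(per_class):
        if (i + 1) * n_test // per_class > i * n_test // per_class:
            mask[i] = True
    return mask


@dataclass
class SynthDataset:
    """In-memory synthetic dataset with its provenance."""

    images: np.ndarray          # (n, H, W, 3) uint8
    labels: np.ndarray          # (n,) int class ids
    split: np.ndarray           # (n,) "train" / "test"
    seed: int
    specs: list[ClassSpec]
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.class_names:
            width = len(str(len(self.specs) - 1))
            self.class_names = [
                f"class_{s.class_id:0{width}d}" for s in self.specs
            ]

    def subset(self, which: str):
        """(images, labels) of the ``"train"`` or ``"test"`` split."""
        m = self.split == which
        return self.images[m], self.labels[m]

    def export_folder(self, root) -> Path:
        """Write the standard image-folder layout:
        ``Training/<class>/r_<i>.png`` and ``Test/<class>/r_<i>.png``."""
        from PIL import Image

        root = Path(root)
        for split_name, folder in (("train", "Training"), ("test", "Test")):
            for c, name in enumerate(self.class_names):
                d = root / folder / name
                d.mkdir(parents=True, exist_ok=True)
                idx = np.flatnonzero((self.labels == c)
                                     & (self.split == split_name))
                for k, i in enumerate(idx):
                    Image.fromarray(self.images[i]).save(d / f"r_{k}.png")
        manifest = {
            "seed": self.seed,
            "class_names": self.class_names,
            "specs": [asdict(s) for s in self.specs],
            "n_images": int(len(self.labels)),
        }
        with open(root / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        return root


def generate(n_classes: int, per_class: int, train_fraction: float = 0.7,
             seed: int = 0, separability: float = 1.0,
             specs: list[ClassSpec] | None = None) -> SynthDataset:
    """Generate a full dataset: ``per_class`` pose-swept frames per class.

    Pose angles are evenly spaced over 360 degrees; the per-class split is
    ``round(train_fraction * per_class)`` training frames with the test
    frames interleaved across the rotation, so both splits cover all poses.
    """
    if per_class < 4:
        raise ValueError("per_class must be >= 4")
    if not (0 < train_fraction < 1):
        raise ValueError("train_fraction must lie in (0, 1)")
    if specs is None:
        specs = make_class_specs(n_classes, seed=seed,
                                 separability=separability)
    elif len(specs) != n_classes:
        raise ValueError("len(specs) must equal n_classes")
    n_train = round(train_fraction * per_class)
    test_mask = _split_mask(per_class, per_class - n_train)
    ss = np.random.SeedSequence(entropy=seed)
    noise_seeds = ss.generate_state(n_classes * per_class)
    images = np.empty((n_classes * per_class, FRAME, FRAME, 3),
                      dtype=np.uint8)
    labels = np.empty(n_classes * per_class, dtype=int)
    split = np.empty(n_classes * per_class, dtype=object)
    i = 0
    for c, spec in enumerate(specs):
        for k in range(per_class):
            angle = 360.0 * k / per_class
            images[i] = render(spec, angle, int(noise_seeds[i]))
            labels[i] = c
            split[i] = "test" if test_mask[k] else "train"
            i += 1
    return SynthDataset(images=images, labels=labels,
                        split=np.asarray(split, dtype=object),
                        seed=seed, specs=list(specs))
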