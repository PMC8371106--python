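"""Image augmentation recipe and train/validation split.

Each original image is expanded into exactly ten derived sub-images:
salt-and-pepper noise (density 0.3), additive Gaussian noise, a horizontal
flip, a brightness gain (1.5), a darkness gain (0.9), and five rotations
(60°, 120°, 180°, 240°, 300°). 3,600 originals therefore become 36,000
sub-images, which are then split 80/20 into training and validation pools.

All stochastic operations are deterministic under their seed, and every
operation maps uint8 rasters to uint8 rasters in [0, 255].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, List, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .sample import ImageSample


@dataclass
class AugmentationConfig:
    salt_pepper_density: float = 0.3
    gaussian_mean: float = 0.0
    gaussian_sigma: float = 10.0  # on the 0-255 scale; visible but non-destructive
    brightness_factor: float = 1.5
    darkness_factor: float = 0.9
    rotation_angles_deg: Tuple[float, ...] = (60.0, 120.0, 180.0, 240.0, 300.0)
    do_horizontal_flip: bool = True
    rotation_fill: int = 0
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.salt_pepper_density <= 1.0:
            raise ValueError("salt_pepper_density must be in [0, 1]")
        if self.gaussian_sigma < 0:
            raise ValueError("gaussian_sigma must be >= 0")
        if self.brightness_factor <= 0 or self.darkness_factor <= 0:
            raise ValueError("brightness/darkness factors must be > 0")
        for a in self.rotation_angles_deg:
            if not 0.0 < a < 360.0:
                raise ValueError(f"rotation angle {a} outside (0, 360)")


@dataclass
class SplitSpec:
    train_fraction: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


def downscale_quarter(image: ImageSample) -> ImageSample:
    """Area-average the raster down to a quarter of each dimension.

    3120x4160 originals become 780x1040. Dimensions not divisible by 4 are
    first resized to the nearest multiple of 4; each output pixel is then the
    mean of its 4x4 source block.
    """
    px = image.pixels
    h, w = px.shape[:2]
    if h == 0 or w == 0:
        raise ValueError("empty image")
    h4, w4 = 4 * max(1, round(h / 4)), 4 * max(1, round(w / 4))
    fpx = px.astype(np.float64)
    if (h4, w4) != (h, w):
        fpx = resize(fpx, (h4, w4, 3), order=1, anti_aliasing=False,
                     preserve_range=True)
    blocks = fpx.reshape(h4 // 4, 4, w4 // 4, 4, 3).mean(axis=(1, 3))
    out = np.clip(np.rint(blocks), 0, 255).astype(np.uint8)
    return image.with_pixels(out, provenance="quarter")


def salt_pepper(image: ImageSample, density: float, seed: int) -> ImageSample:
    """Corrupt exactly round(density * H * W) distinct pixel locations.

    Each chosen location is set, in all three channels, to 0 or 255 with
    equal probability. Sampling without replacement makes the corrupted
    fraction exact rather than Bernoulli-approximate.
    """
    if not 0.0 <= density <= 1.0:
        raise ValueError("density must be in [0, 1]")
    px = image.pixels.copy()
    h, w = px.shape[:2]
    n = round(density * h * w)
    if n > 0:
        rng = np.random.default_rng(seed)
        flat = rng.choice(h * w, size=n, replace=False)
        values = rng.integers(0, 2, size=n) * 255
        px.reshape(-1, 3)[flat] = values[:, None].astype(np.uint8)
    return image.with_pixels(px, provenance="sp")


def gaussian_noise(image: ImageSample, mean: float = 0.0, sigma: float = 10.0,
                   seed: int = 0) -> ImageSample:
    """Add iid N(mean, sigma^2) per pixel per channel, clipped to [0, 255]."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    noise = rng.normal(mean, sigma, size=image.pixels.shape)
    out = np.clip(np.rint(image.pixels.astype(np.float64) + noise), 0, 255)
    return image.with_pixels(out.astype(np.uint8), provenance="gauss")


def flip_horizontal(image: ImageSample) -> ImageSample:
    """Reverse the column order (mirror about the vertical axis)."""
    return image.with_pixels(image.pixels[:, ::-1].copy(), provenance="flip")


def adjust_brightness(image: ImageSample, factor: float) -> ImageSample:
    """Multiplicative gain: out = clip(round(factor * in), 0, 255)."""
    if factor <= 0:
        raise ValueError("factor must be > 0")
    out = np.clip(np.rint(factor * image.pixels.astype(np.float64)), 0, 255)
    tag = "bright" if factor >= 1.0 else "dark"
    return image.with_pixels(out.astype(np.uint8), provenance=tag)


def rotate(image: ImageSample, angle_deg: float, fill: int = 0) -> ImageSample:
    """Rotate about the image centre onto a same-size canvas.

    Exposed corners are filled with ``fill``. 180° is a pure index reversal
    (exact, no interpolation); other angles use bilinear interpolation.
    """
    if not 0.0 < angle_deg < 360.0:
        raise ValueError("angle must be in (0, 360)")
    tag = f"rot{int(angle_deg) if float(angle_deg).is_integer() else angle_deg}"
    if angle_deg == 180.0:
        return image.with_pixels(image.pixels[::-1, ::-1].copy(), provenance=tag)
    out = ndimage.rotate(
        image.pixels.astype(np.float64),
        # ndimage rotates row/col axes counter-clockwise in array coordinates
        angle=angle_deg,
        axes=(0, 1),
        reshape=False,
        order=1,
        mode="constant",
        cval=float(fill),
    )
    return image.with_pixels(
        np.clip(np.rint(out), 0, 255).astype(np.uint8), provenance=tag
    )


#: provenance tags of the ten derived images, in generation order
AUGMENTATION_TAGS = ("sp", "gauss", "flip", "bright", "dark",
                     "rot60", "rot120", "rot180", "rot240", "rot300")


def augment_one(image: ImageSample, config: AugmentationConfig,
                sub_seed: int) -> List[ImageSample]:
    """The ten derived sub-images of one original (original not included)."""
    config.validate()
    out = [
        salt_pepper(image, config.salt_pepper_density, seed=sub_seed),
        gaussian_noise(image, config.gaussian_mean, config.gaussian_sigma,
                       seed=sub_seed + 1),
        flip_horizontal(image),
        adjust_brightness(image, config.brightness_factor),
        adjust_brightness(image, config.darkness_factor),
    ]
    for angle in config.rotation_angles_deg:
        out.append(rotate(image, angle, fill=config.rotation_fill))
    return out


def iter_augmented(originals: Iterable[ImageSample],
                   config: AugmentationConfig) -> Iterator[ImageSample]:
    """Stream the augmented pool one sub-image at a time (bounded memory)."""
    config.validate()
    for idx, image in enumerate(originals):
        # distinct noise stream per original, derived from the global seed
        for sub in augment_one(image, config, sub_seed=(config.seed << 20) + idx * 2):
            yield sub


def augment_all(originals: Sequence[ImageSample],
                config: AugmentationConfig) -> List[ImageSample]:
    """Expand every original into its ten sub-images (10x cardinality)."""
    if len(originals) == 0:
        raise ValueError("originals must be non-empty")
    return list(iter_augmented(originals, config))


def split_dataset(samples: Sequence[ImageSample], spec: SplitSpec
                  ) -> Tuple[List[ImageSample], List[ImageSample]]:
    """Disjoint, exhaustive random train/validation partition.

    |train| = round(train_fraction * N). Performed on whatever pool it is
    given — in the reference pipeline the post-augmentation pool, which
    places augmented siblings of one fruit on both sides; use
    split_by_fruit for the leakage-free alternative.
    """
    if len(samples) == 0:
        raise ValueError("samples must be non-empty")
    spec.validate()
    n = len(samples)
    n_train = round(spec.train_fraction * n)
    perm = np.random.default_rng(spec.seed).permutation(n)
    train = [samples[i] for i in perm[:n_train]]
    val = [samples[i] for i in perm[n_train:]]
    return train, val


def split_by_fruit(samples: Sequence[ImageSample], spec: SplitSpec
                   ) -> Tuple[List[ImageSample], List[ImageSample]]:
    """Leakage-free split: all images of one fruit land on the same side."""
    if len(samples) == 0:
        raise ValueError("samples must be non-empty")
    spec.validate()
    fruit_ids = sorted({s.fruit_id for s in samples})
    n_train_fruits = round(spec.train_fraction * len(fruit_ids))
    perm = np.random.default_rng(spec.seed).permutation(len(fruit_ids))
    train_ids = {fruit_ids[i] for i in perm[:n_train_fruits]}
    train = [s for s in samples if s.fruit_id in train_ids]
    val = [s for s in samples if s.fruit_id not in train_ids]
    return train, val
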