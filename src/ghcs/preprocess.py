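"""Stain normalization, geometric augmentation and grid tiling.

H&E-stained slides vary in color with staining batch and scanner.  The
normalization implemented here is Reinhard-style statistical color
transfer: images are mapped into the Ruderman lαβ log-opponent space
(where natural-image channels are approximately decorrelated), each
channel is shifted and scaled so its mean and standard deviation match a
reference, and the result is mapped back to RGB.

The augmentation produces the fixed ten-member family used throughout
the pipeline — identity, seven rotations in 45° steps, and the two axis
flips — and large slides are cut into disjoint 256-px tiles on a regular
grid (a 2048×2048 slide yields 64 tiles, so one slide expands to
10 × 64 = 640 training images).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
from skimage.transform import rotate as _sk_rotate

logger = logging.getLogger("ghcs.preprocess")

#: Offset added before log transforms and floor applied to channel
#: standard deviations, guarding zero pixels and constant channels.
EPSILON = 1e-6

#: Fixed augmentation order; file naming and bookkeeping depend on it.
AUGMENTATION_ORDER = (
    "identity",
    "rot45",
    "rot90",
    "rot135",
    "rot180",
    "rot225",
    "rot270",
    "rot315",
    "hflip",
    "vflip",
)

# RGB -> LMS cone response and its inverse (Ruderman/Reinhard matrices).
_RGB2LMS = np.array(
    [
        [0.3811, 0.5783, 0.0402],
        [0.1967, 0.7244, 0.0782],
        [0.0241, 0.1288, 0.8444],
    ]
)
# Exact inverse (the published 4-decimal inverse is too coarse for a
# lossless round trip at 8-bit quantization).
_LMS2RGB = np.linalg.inv(_RGB2LMS)
# log-LMS -> lαβ decorrelating rotation and its inverse.
_LMS2LAB = np.diag([1 / np.sqrt(3), 1 / np.sqrt(6), 1 / np.sqrt(2)]) @ np.array(
    [
        [1, 1, 1],
        [1, 1, -2],
        [1, -1, 0],
    ]
)
_LAB2LMS = np.linalg.inv(_LMS2LAB)


@dataclass(frozen=True)
class ColorStats:
    """Per-channel mean and standard deviation in lαβ space."""

    mean_l: float
    mean_a: float
    mean_b: float
    std_l: float
    std_a: float
    std_b: float

    def means(self) -> np.ndarray:
        return np.array([self.mean_l, self.mean_a, self.mean_b])

    def stds(self) -> np.ndarray:
        return np.array([self.std_l, self.std_a, self.std_b])


@dataclass(frozen=True)
class TileGrid:
    """Row-major grid of disjoint square tiles anchored at the top-left."""

    tile_size: int
    rows: int
    cols: int

    def __len__(self) -> int:
        return self.rows * self.cols


def _check_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(
            f"expected an H×W×3 RGB image, got array of shape {image.shape}"
        )
    if image.size == 0:
        raise ValueError("empty image")
    return image


def rgb_to_perceptual(image: np.ndarray) -> np.ndarray:
    """Map an 8-bit RGB image into the Ruderman lαβ log-opponent space.

    RGB is scaled to [0, 1], projected onto LMS cone responses,
    log10-transformed with an ``EPSILON`` offset (so black pixels stay
    finite), and rotated into the decorrelated lαβ axes.
    """
    image = _check_rgb(image)
    rgb = image.astype(np.float64) / 255.0
    lms = rgb @ _RGB2LMS.T
    log_lms = np.log10(lms + EPSILON)
    return log_lms @ _LMS2LAB.T


def perceptual_to_rgb(lab: np.ndarray) -> np.ndarray:
    """Invert :func:`rgb_to_perceptual`, clipping to valid 8-bit RGB."""
    lab = np.asarray(lab, dtype=np.float64)
    if lab.ndim != 3 or lab.shape[2] != 3:
        raise ValueError(f"expected an H×W×3 lαβ raster, got shape {lab.shape}")
    log_lms = lab @ _LAB2LMS.T
    lms = np.power(10.0, log_lms) - EPSILON
    rgb = lms @ _LMS2RGB.T
    return np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8)


def compute_color_stats(image: np.ndarray) -> ColorStats:
    """Channel-wise mean/std of an RGB image in lαβ space.

    Standard deviations are floored at ``EPSILON`` so that constant
    channels never produce a degenerate scale factor.
    """
    lab = rgb_to_perceptual(image)
    means = lab.reshape(-1, 3).mean(axis=0)
    stds = np.maximum(lab.reshape(-1, 3).std(axis=0), EPSILON)
    return ColorStats(*means, *stds)


def reinhard_transfer(source: np.ndarray, target: ColorStats) -> np.ndarray:
    """Transfer the target's lαβ color statistics onto *source*.

    Each lαβ channel is standardized with the source's own statistics
    and re-expressed with the target's:
    ``out = (src − mean_src) · std_tgt / std_src + mean_tgt``.
    """
    if np.any(target.stds() <= 0):
        raise ValueError("target standard deviations must be strictly positive")
    lab = rgb_to_perceptual(source)
    flat = lab.reshape(-1, 3)
    src_mean = flat.mean(axis=0)
    src_std = flat.std(axis=0)
    if np.any(src_std < EPSILON):
        logger.warning(
            "degenerate source channel(s) %s: std below epsilon, flooring",
            np.nonzero(src_std < EPSILON)[0].tolist(),
        )
        src_std = np.maximum(src_std, EPSILON)
    out = (lab - src_mean) * (target.stds() / src_std) + target.means()
    return perceptual_to_rgb(out)


def _rotate_interp(image: np.ndarray, angle: float) -> np.ndarray:
    """Rotate about the center keeping canvas size.

    Bilinear interpolation with reflection padding of the exposed
    corners; computed in float32 (sub-quantization error) and rounded
    back to uint8.
    """
    out = _sk_rotate(
        image.astype(np.float32) / 255.0,
        angle,
        resize=False,
        mode="reflect",
        order=1,
    )
    return np.clip(np.rint(out * 255.0), 0, 255).astype(np.uint8)


def augment_ten(image: np.ndarray) -> List[np.ndarray]:
    """The ten-member augmentation family of a square tile.

    Order is fixed by :data:`AUGMENTATION_ORDER`: identity, rotations by
    45°..315° in 45° steps (counter-clockwise), horizontal flip,
    vertical flip.  The 90°-multiple rotations and the flips are exact
    pixel permutations; the 45° family is interpolated on the original
    canvas with reflection-padded corners, which requires a square
    input.  225° and 315° are exact 180° grid rotations of the 45° and
    135° results (the 180° rotation commutes with the bilinear
    sampling grid, so this equals direct warping).
    """
    image = _check_rgb(image)
    h, w = image.shape[:2]
    if h != w:
        raise ValueError(
            f"45-degree rotations require a square image, got {h}×{w}"
        )
    rot45 = _rotate_interp(image, 45)
    rot135 = _rotate_interp(image, 135)
    rot180 = np.rot90(image, 2)
    return [
        image.copy(),
        rot45,
        np.rot90(image, 1),
        rot135,
        rot180,
        np.rot90(rot45, 2),
        np.rot90(image, 3),
        np.rot90(rot135, 2),
        image[:, ::-1].copy(),
        image[::-1, :].copy(),
    ]


def tile(
    image: np.ndarray, tile_size: int = 256
) -> Tuple[List[np.ndarray], TileGrid]:
    """Cut an image into disjoint ``tile_size``-px tiles, row-major.

    Remainder strips at the right/bottom borders are dropped (the
    canonical 2048-px slides divide evenly, so this only affects odd
    sizes); pass a smaller ``tile_size`` to retain more area.
    """
    image = _check_rgb(image)
    h, w = image.shape[:2]
    if tile_size > min(h, w):
        raise ValueError(
            f"tile_size {tile_size} exceeds image extent {min(h, w)}"
        )
    rows, cols = h // tile_size, w // tile_size
    tiles = [
        image[
            r * tile_size : (r + 1) * tile_size,
            c * tile_size : (c + 1) * tile_size,
        ].copy()
        for r in range(rows)
        for c in range(cols)
    ]
    return tiles, TileGrid(tile_size=tile_size, rows=rows, cols=cols)


def assemble(tiles: List[np.ndarray], grid: TileGrid) -> np.ndarray:
    """Inverse of :func:`tile` for evenly divisible inputs."""
    if len(tiles) != len(grid):
        raise ValueError("tile count does not match grid")
    rows = [
        np.concatenate(tiles[r * grid.cols : (r + 1) * grid.cols], axis=1)
        for r in range(grid.rows)
    ]
    return np.concatenate(rows, axis=0)
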