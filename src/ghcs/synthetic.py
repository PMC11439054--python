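"""Seeded generators of H&E-like tiles, feature datasets and phantoms.

Real gastric histopathology cannot ship with a code repository, so
every stage of the pipeline is exercised on synthetic material that
reproduces the *statistical contrasts* the methods rely on:

* ``make_tile`` renders an eosin-pink textured background scattered
  with blue-purple elliptical "nuclei".  Abnormal tiles carry a
  contiguous lesion in which nuclei are denser, larger and more
  pleomorphic (eccentric, size-variable) — the cues a pathologist reads
  — and return the lesion footprint as a ground-truth mask.
* ``make_feature_dataset`` draws labeled vectors from known per-class
  Gaussian mixtures in the 10-D descriptor space, with component
  assignments returned so EM recovery can be verified; the default
  specification keeps the two classes' Bayes error below 2%.
* ``make_phantom`` builds piecewise-constant images (stripes, disk in
  field, checkerboard) with exact label maps and optional Gaussian and
  salt-and-pepper noise, for the segmenter.

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

from .gmm_nb import ABNORMAL, NORMAL


# ---------------------------------------------------------------------------
# H&E-like tiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TissueSpec:
    """Parameters of the synthetic tile generator.

    Densities are expected nucleus counts per tile (Poisson); the
    abnormal lesion multiplies the local density by
    ``lesion_density_boost`` inside a contiguous elliptical footprint.
    """

    tile_size: int = 256
    normal_density: float = 40.0
    abnormal_density: float = 90.0
    normal_radius: Tuple[float, float] = (3.0, 6.0)
    abnormal_radius: Tuple[float, float] = (4.0, 10.0)
    normal_eccentricity: Tuple[float, float] = (1.0, 1.4)
    abnormal_eccentricity: Tuple[float, float] = (1.0, 2.5)
    background_color: Tuple[int, int, int] = (232, 180, 198)   # eosin pink
    nucleus_color: Tuple[int, int, int] = (92, 64, 150)        # hematoxylin
    color_jitter_std: float = 8.0
    texture_std: float = 6.0
    gaussian_noise_std: float = 3.0
    salt_pepper_frac: float = 0.0
    lesion_radius_frac: Tuple[float, float] = (0.25, 0.4)
    lesion_density_boost: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.normal_density <= 0 or self.abnormal_density <= 0:
            raise ValueError("densities must be positive")
        if min(self.normal_radius) <= 0 or min(self.abnormal_radius) <= 0:
            raise ValueError("radius ranges must be positive")


def _render_ellipse(canvas: np.ndarray, cy, cx, ry, rx, theta, color, softness=0.8):
    """Draw one anti-aliased filled ellipse (soft-edged coverage blend)."""
    h, w = canvas.shape[:2]
    r_lo = max(int(cy - ry - rx - 2), 0)
    r_hi = min(int(cy + ry + rx + 3), h)
    c_lo = max(int(cx - ry - rx - 2), 0)
    c_hi = min(int(cx + ry + rx + 3), w)
    if r_hi <= r_lo or c_hi <= c_lo:
        return
    yy, xx = np.mgrid[r_lo:r_hi, c_lo:c_hi]
    dy, dx = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = (ct * dx + st * dy) / rx
    v = (-st * dx + ct * dy) / ry
    # implicit radius: 1 on the boundary; smooth step over ~softness px
    rad = np.sqrt(u**2 + v**2)
    edge = min(softness / rx, softness / ry, 0.5)
    cover = np.clip((1.0 - rad) / edge + 0.5, 0.0, 1.0)
    patch = canvas[r_lo:r_hi, c_lo:c_hi]
    patch[:] = (1 - cover[..., None]) * patch + cover[..., None] * color


def make_tile(
    spec: TissueSpec, class_label: str, seed: int | None = None
) -> Tuple[np.ndarray, np.ndarray, int]:
    """Render one tile; returns ``(rgb, gt_mask, n_nuclei)``.

    Normal tiles get an empty ground-truth mask; abnormal tiles return
    the lesion footprint.  ``seed`` overrides ``spec.seed`` so batches
    can reuse one spec.
    """
    if class_label not in (NORMAL, ABNORMAL):
        raise ValueError(f"class_label must be {NORMAL!r} or {ABNORMAL!r}")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    ts = spec.tile_size
    base = np.array(spec.background_color, dtype=np.float64)
    canvas = base[None, None, :] + rng.normal(0, spec.texture_std, (ts, ts, 3))

    gt = np.zeros((ts, ts), dtype=bool)
    abnormal = class_label == ABNORMAL
    if abnormal:
        lr = rng.uniform(*spec.lesion_radius_frac) * ts
        lry = lr * rng.uniform(0.7, 1.3)
        cy = rng.uniform(lr, ts - lr)
        cx = rng.uniform(lr, ts - lr)
        yy, xx = np.mgrid[0:ts, 0:ts]
        gt = ((xx - cx) / lr) ** 2 + ((yy - cy) / lry) ** 2 <= 1.0

    density = spec.abnormal_density if abnormal else spec.normal_density
    n_nuclei = int(rng.poisson(density))
    radius_rng = spec.abnormal_radius if abnormal else spec.normal_radius
    ecc_rng = spec.abnormal_eccentricity if abnormal else spec.normal_eccentricity
    lesion_frac = float(gt.mean())

    placed = 0
    for _ in range(n_nuclei):
        if abnormal and lesion_frac > 0:
            # lesion is denser: bias placement into the footprint
            p_in = min(
                1.0,
                spec.lesion_density_boost
                * lesion_frac
                / (1 + (spec.lesion_density_boost - 1) * lesion_frac),
            )
            inside = rng.random() < p_in
            for _try in range(50):
                cy = rng.uniform(0, spec.tile_size)
                cx = rng.uniform(0, spec.tile_size)
                if gt[min(int(cy), ts - 1), min(int(cx), ts - 1)] == inside:
                    break
        else:
            cy = rng.uniform(0, ts)
            cx = rng.uniform(0, ts)
        r = rng.uniform(*radius_rng)
        ecc = rng.uniform(*ecc_rng)
        theta = rng.uniform(0, np.pi)
        color = np.array(spec.nucleus_color) + rng.normal(
            0, spec.color_jitter_std, 3
        )
        _render_ellipse(canvas, cy, cx, r, r * ecc, theta, np.clip(color, 0, 255))
        placed += 1

    canvas += rng.normal(0, spec.gaussian_noise_std, canvas.shape)
    img = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    if spec.salt_pepper_frac > 0:
        m = rng.random((ts, ts)) < spec.salt_pepper_frac
        salt = rng.random((ts, ts)) < 0.5
        img[m & salt] = 255
        img[m & ~salt] = 0
    return img, gt, placed


def make_tile_batch(
    spec: TissueSpec, class_label: str, n: int, seed: int | None = None
) -> List[Tuple[np.ndarray, np.ndarray, int]]:
    """n tiles with per-tile seeds derived from one master seed."""
    master = np.random.default_rng(spec.seed if seed is None else seed)
    seeds = master.integers(0, 2**31 - 1, size=n)
    return [make_tile(spec, class_label, int(s)) for s in seeds]


# ---------------------------------------------------------------------------
# feature-space datasets
# ---------------------------------------------------------------------------

def _default_class_mixture(dim: int, shift: float):
    """Two equal components per class, split along axis 1, class offset
    along axis 0.  Component spread 1, so a class shift of 5σ keeps the
    Bayes error well under 2% while EM still has multi-modality to find."""
    m1 = np.zeros(dim)
    m2 = np.zeros(dim)
    m1[1], m2[1] = -2.5, 2.5
    m1[0] += shift
    m2[0] += shift
    cov = np.eye(dim)
    return [(0.5, m1, cov), (0.5, m2, cov)]


@dataclass(frozen=True)
class FeatureSimSpec:
    """Known per-class mixtures in descriptor space.

    ``components[label]`` is a list of ``(weight, mean, cov)`` triples.
    The defaults put the two classes 5 component-σ apart on one axis
    (Bayes error ≈ 0.6%) with two modes per class on another.
    """

    dim: int = 10
    n_per_class: Tuple[int, int] = (1000, 1000)   # (normal, abnormal)
    seed: int = 0
    class_shift: float = 5.0

    def components(self, label: str):
        if label == NORMAL:
            return _default_class_mixture(self.dim, 0.0)
        if label == ABNORMAL:
            return _default_class_mixture(self.dim, self.class_shift)
        raise ValueError(f"unknown label {label!r}")


def make_feature_dataset(
    spec: FeatureSimSpec,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw ``(X, labels, component_ids)`` from the spec's mixtures."""
    if min(spec.n_per_class) <= 0:
        raise ValueError("n_per_class entries must be positive")
    rng = np.random.default_rng(spec.seed)
    xs, ys, comps = [], [], []
    for label, n in zip((NORMAL, ABNORMAL), spec.n_per_class):
        mixture = spec.components(label)
        weights = np.array([w for w, _, _ in mixture])
        which = rng.choice(len(mixture), size=n, p=weights / weights.sum())
        for i, (w, mean, cov) in enumerate(mixture):
            k = int((which == i).sum())
            if k:
                xs.append(rng.multivariate_normal(mean, cov, size=k))
                ys.extend([label] * k)
                comps.extend([i] * k)
    X = np.concatenate(xs, axis=0)
    labels = np.array(ys)
    comp_ids = np.array(comps)
    perm = rng.permutation(len(labels))
    return X[perm], labels[perm], comp_ids[perm]


def mixture_logpdf(X: np.ndarray, mixture) -> np.ndarray:
    """Log-density of rows of X under a (weight, mean, cov) mixture."""
    from scipy.special import logsumexp
    from scipy.stats import multivariate_normal

    parts = np.stack(
        [np.log(w) + multivariate_normal.logpdf(X, mean, cov) for w, mean, cov in mixture]
    )
    return logsumexp(parts, axis=0)


def bayes_error_mc(spec: FeatureSimSpec, n_draws: int = 400_000, seed: int = 0) -> float:
    """Monte-Carlo estimate of the two-class Bayes error under the spec
    (equal priors): draw from each class, classify by true densities."""
    rng = np.random.default_rng(seed)
    err = 0
    per = n_draws // 2
    mixtures = {lab: spec.components(lab) for lab in (NORMAL, ABNORMAL)}
    for lab, other in ((NORMAL, ABNORMAL), (ABNORMAL, NORMAL)):
        mixture = mixtures[lab]
        weights = np.array([w for w, _, _ in mixture])
        which = rng.choice(len(mixture), size=per, p=weights / weights.sum())
        draws = np.concatenate(
            [
                rng.multivariate_normal(mixture[i][1], mixture[i][2], size=int((which == i).sum()))
                for i in range(len(mixture))
                if (which == i).any()
            ]
        )
        wrong = mixture_logpdf(draws, mixtures[other]) > mixture_logpdf(draws, mixture)
        err += int(wrong.sum())
    return err / (2 * per)


# ---------------------------------------------------------------------------
# segmentation phantoms
# ---------------------------------------------------------------------------

_LAYOUTS = ("stripes", "disk", "checkerboard")


def make_phantom(
    levels: Sequence[float],
    geometry: str = "disk",
    size: int = 128,
    gaussian_noise: float = 0.0,
    salt_pepper: float = 0.0,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Piecewise-constant test image plus its exact label map.

    ``stripes``: horizontal bands cycling through the levels;
    ``disk``: level-1 disk (radius size/4, centered) on a level-0
    field — only two levels used; ``checkerboard``: size/8 squares
    cycling through levels.  Noise (Gaussian then salt-and-pepper) is
    applied after the ground truth is captured.
    """
    levels = list(levels)
    if len(levels) < 2:
        raise ValueError("need at least two intensity levels")
    if geometry not in _LAYOUTS:
        raise ValueError(f"unknown layout {geometry!r}; expected one of {_LAYOUTS}")
    rng = np.random.default_rng(seed)
    if geometry == "stripes":
        band = max(size // (2 * len(levels)), 1)
        gt = (np.arange(size)[:, None] // band % len(levels)) * np.ones(
            (1, size), dtype=int
        )
    elif geometry == "disk":
        yy, xx = np.mgrid[0:size, 0:size]
        c = (size - 1) / 2.0
        gt = ((yy - c) ** 2 + (xx - c) ** 2 <= (size / 4.0) ** 2).astype(int)
    else:
        cell = max(size // 8, 1)
        gt = ((np.arange(size)[:, None] // cell) + (np.arange(size)[None, :] // cell)) % len(levels)
    img = np.asarray(levels, dtype=np.float64)[gt]
    if gaussian_noise > 0:
        img = img + rng.normal(0, gaussian_noise, img.shape)
    if salt_pepper > 0:
        m = rng.random(img.shape) < salt_pepper
        salt = rng.random(img.shape) < 0.5
        img[m & salt] = max(levels)
        img[m & ~salt] = min(levels)
    return np.clip(img, 0, 255), gt
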