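"""Synthetic phantoms for exercising every pipeline stage without downloads.

Two generators:

* :func:`make_volume` builds 3D ellipsoid phantoms whose boundary slices are
  exactly empty and whose central slices carry structure — the situation the
  edge-trimming (k1/k2) of the slice extractor is designed for.

* :func:`make_class_pair` builds two-class 2D image sets whose inter-class
  difference is controlled by a similarity gap ``delta``: both classes share
  a large central blob, and a smaller secondary blob is displaced (and
  brightened) by ``delta`` between the classes.  ``delta = 0`` makes the two
  class distributions identical — the regime in which gradient-based
  training of the hybrid model stagnates near chance — while large ``delta``
  (about 20 px) gives an easily separable, benchmark-like problem.

Both generators are pure functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Tuple

import nibabel as nib
import numpy as np

from .slicing import Volume3D

#: displacement (px) at which the two classes are trivially separable
SEPARABLE_DELTA = 20.0


class SynthesisError(ValueError):
    """Impossible phantom request (margins, sizes)."""


@dataclass
class VolumeRecipe:
    """Ellipsoid phantom: foreground fills [margin, extent - margin) on every
    axis; slices outside that band are all-zero."""

    extents: Tuple[int, int, int] = (41, 31, 31)
    margin: int = 1
    intensity: float = 1.0
    noise_sd: float = 0.05
    seed: int = 0


def make_volume(recipe: VolumeRecipe) -> Volume3D:
    ext = tuple(int(e) for e in recipe.extents)
    if any(2 * recipe.margin >= e for e in ext):
        raise SynthesisError(
            f"margin {recipe.margin} leaves no interior for extents {ext}")
    rng = np.random.default_rng(recipe.seed)
    centers = [(e - 1) / 2.0 for e in ext]
    # semi-axis chosen so slice `margin` intersects the ellipsoid but
    # slice `margin - 1` does not
    semi = [c - recipe.margin + 0.5 for c in centers]
    grids = np.meshgrid(*[np.arange(e) for e in ext], indexing="ij")
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, centers, semi))
    mask = r2 <= 1.0
    noise = rng.normal(0.0, recipe.noise_sd, size=ext)
    voxels = np.where(mask,
                      np.clip(recipe.intensity + noise, 0.05 * recipe.intensity, None),
                      0.0)
    return Volume3D(voxels=voxels, source_path=f"synthetic:seed={recipe.seed}")


def write_volume(vol: Volume3D, path) -> Path:
    """Write a phantom as NIfTI-1 with an identity affine."""
    img = nib.Nifti1Image(vol.voxels.astype(np.float32), affine=np.eye(4))
    nib.save(img, str(path))
    return Path(path)


@dataclass
class ClassPairRecipe:
    """Two-class 2D image generator with tunable inter-class similarity."""

    n_per_class: int = 100
    side: int = 128
    delta: float = SEPARABLE_DELTA
    noise_sd: float = 0.05
    seed: int = 0
    test_fraction: float = 0.10


@dataclass
class ClassPairData:
    X_train: np.ndarray
    y_train: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray
    recipe: ClassPairRecipe = None


def _blob(side: int, cy: float, cx: float, sigma: float, amp: float) -> np.ndarray:
    yy, xx = np.mgrid[0:side, 0:side]
    return amp * np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma ** 2)))


def _render_image(rng: np.random.Generator, side: int, label: int,
                  delta: float, noise_sd: float) -> np.ndarray:
    # per-sample anatomy-like variation (size, brightness, position) is the
    # same for both classes; only the secondary blob differs between them
    c = (side - 1) / 2.0
    jitter = rng.uniform(-0.03 * side, 0.03 * side, size=4)
    amp1 = rng.uniform(0.6, 0.9)
    sigma1 = side / 4.0 * rng.uniform(0.85, 1.15)
    img = _blob(side, c + jitter[0], c + jitter[1], sigma=sigma1, amp=amp1)
    # secondary blob: classes differ by a `delta`-pixel displacement and a
    # small intensity offset; at delta = 0 the classes coincide
    sign = -0.5 if label == 0 else 0.5
    off = sign * delta
    amp2 = rng.uniform(0.4, 0.6) + (0.01 * delta) * sign
    sigma2 = side / 10.0 * rng.uniform(0.85, 1.15)
    img += _blob(side, c + jitter[2], c + side / 8.0 + off + jitter[3],
                 sigma=sigma2, amp=amp2)
    img += rng.normal(0.0, noise_sd, size=(side, side))
    return np.clip(img, 0.0, 1.0)


def make_class_pair(recipe: ClassPairRecipe) -> ClassPairData:
    """Balanced two-class image sets with a 90:10 train/test split per class."""
    if recipe.n_per_class < 20:
        raise SynthesisError(f"need n_per_class >= 20, got {recipe.n_per_class}")
    rng = np.random.default_rng(recipe.seed)
    n = recipe.n_per_class
    n_test = max(1, int(round(n * recipe.test_fraction)))
    xs_tr, ys_tr, xs_te, ys_te = [], [], [], []
    for label in (0, 1):
        imgs = np.stack([
            _render_image(rng, recipe.side, label, recipe.delta, recipe.noise_sd)
            for _ in range(n)
        ])
        xs_te.append(imgs[:n_test])
        ys_te.append(np.full(n_test, label))
        xs_tr.append(imgs[n_test:])
        ys_tr.append(np.full(n - n_test, label))
    X_train = np.concatenate(xs_tr)
    y_train = np.concatenate(ys_tr)
    X_test = np.concatenate(xs_te)
    y_test = np.concatenate(ys_te)
    # interleave classes deterministically so minibatches stay mixed
    order = rng.permutation(X_train.shape[0])
    return ClassPairData(X_train=X_train[order], y_train=y_train[order],
                         X_test=X_test, y_test=y_test, recipe=recipe)


def centroid_accuracy(data: ClassPairData) -> float:
    """Test accuracy of a nearest-class-centroid classifier (separability probe)."""
    cent = [data.X_train[data.y_train == c].mean(axis=0) for c in (0, 1)]
    d = np.stack([
        ((data.X_test - cent[c]) ** 2).sum(axis=(1, 2)) for c in (0, 1)
    ])
    pred = d.argmin(axis=0)
    return float(np.mean(pred == data.y_test))


def write_images(data: ClassPairData, out_dir, prefix: str = "img") -> list:
    """Export the split as 8-bit PNGs under class-labelled directories."""
    from PIL import Image

    out_dir = Path(out_dir)
    paths = []
    for split, X, y in (("train", data.X_train, data.y_train),
                        ("test", data.X_test, data.y_test)):
        for i, (img, label) in enumerate(zip(X, y)):
            d = out_dir / split / f"class{label}"
            d.mkdir(parents=True, exist_ok=True)
            p = d / f"{prefix}_{i:04d}.png"
            Image.fromarray((img * 255).round().astype(np.uint8), mode="L").save(p)
            paths.append(p)
    return paths
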