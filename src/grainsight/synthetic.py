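"""Seeded synthetic grain images and labeled feature matrices.

Emulates a one-directory-per-class rice-grain image collection at desk
scale: each sample is a single bright, convex grain (a rotated ellipse
with sinusoidal texture along its major axis) on a dark noisy background,
with classes separated by shape, size and texture-frequency parameter
ranges.  Feature matrices carry planted informative, redundant and noise
columns with the ground-truth informative set returned alongside, so the
fusion and selection stages can be scored against known structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GrainImageSample",
    "SyntheticFeatureSpec",
    "ellipse_mask",
    "gen_grain_images",
    "gen_feature_matrix",
]


@dataclass
class GrainImageSample:
    """One synthetic grain image with its ground-truth mask.

    Attributes
    ----------
    image : uint8 array, shape (H, W, 3)
    mask : uint8 array, shape (H, W), 1 = grain
    label : class id in {0..K-1}
    params : ellipse semi-axes (px), orientation (rad), texture frequency
    """

    image: np.ndarray
    mask: np.ndarray
    label: int
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError("image and mask must share H x W")
        area = int(self.mask.sum())
        if area == 0 or area >= self.mask.size:
            raise ValueError("mask must be nonempty and smaller than the frame")


@dataclass(frozen=True)
class SyntheticFeatureSpec:
    """Recipe for a labeled feature matrix with planted structure.

    ``delta`` is the class-mean separation (feature units) of informative
    columns, ``sigma`` the within-class noise s.d., ``rho`` the target
    sample correlation of each redundant column with its informative
    source.  Total columns = k_informative + k_redundant + k_noise.
    """

    n_samples: int = 30
    n_classes: int = 5
    k_informative: int = 10
    k_redundant: int = 20
    k_noise: int = 30
    delta: float = 3.0
    sigma: float = 1.0
    sigma_noise: float = 3.0
    rho: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_classes < 2:
            raise ValueError("need n_samples >= 1 and n_classes >= 2")
        if min(self.k_informative, self.k_redundant, self.k_noise) < 0:
            raise ValueError("column counts must be nonnegative")
        if self.k_informative < 1:
            raise ValueError("need at least one informative column")
        if self.delta < 0 or self.sigma <= 0 or not 0 <= self.rho <= 1:
            raise ValueError("require delta >= 0, sigma > 0, 0 <= rho <= 1")
        if self.sigma_noise <= 0:
            raise ValueError("sigma_noise must be positive")

    @property
    def n_features(self) -> int:
        return self.k_informative + self.k_redundant + self.k_noise


def ellipse_mask(
    hw: int, center: tuple[float, float], a: float, b: float, theta: float
) -> np.ndarray:
    """Rasterize a rotated filled ellipse (semi-axes ``a``, ``b`` in px).

    Pixel (r, c) is inside when its center satisfies the implicit ellipse
    inequality; orientation ``theta`` is the major-axis angle in radians,
    measured from the column axis.
    """
    rr, cc = np.mgrid[0:hw, 0:hw].astype(float)
    dr, dc = rr - center[0], cc - center[1]
    # rotate into the ellipse frame
    u = dc * np.cos(theta) + dr * np.sin(theta)
    v = -dc * np.sin(theta) + dr * np.cos(theta)
    return ((u / a) ** 2 + (v / b) ** 2 <= 1.0).astype(np.uint8)


def _class_params(label: int, hw: int, rng: np.random.Generator) -> dict:
    # Disjoint-enough per-class ranges: semi-major axis grows with the
    # class id, aspect ratio and texture frequency alternate, so a trivial
    # area/aspect feature already separates classes.
    # single grain spans ~40-65% of the frame length, as in macro shots of
    # individual rice kernels on a dark stage
    base = hw * (0.20 + 0.03 * label)
    a = base * rng.uniform(0.95, 1.05)
    aspect = 0.30 + 0.06 * label
    b = a * aspect * rng.uniform(0.95, 1.05)
    theta = rng.uniform(0, np.pi)
    freq = 2.0 + 1.5 * label + rng.uniform(-0.2, 0.2)  # cycles per grain length
    return {"a": a, "b": b, "theta": theta, "freq": freq}


def _render(params: dict, hw: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    a, b, theta, freq = params["a"], params["b"], params["theta"], params["freq"]
    # keep the whole ellipse inside the frame
    margin = a + 2
    lo, hi = margin, hw - margin
    center = (rng.uniform(lo, hi), rng.uniform(lo, hi))
    mask = ellipse_mask(hw, center, a, b, theta)

    rr, cc = np.mgrid[0:hw, 0:hw].astype(float)
    u = (cc - center[1]) * np.cos(theta) + (rr - center[0]) * np.sin(theta)
    # sinusoidal luminance modulation along the major axis
    texture = 0.5 * (1 + np.sin(2 * np.pi * freq * u / (2 * a)))
    grain = 170 + 60 * texture  # bright grain body, 170..230
    background = rng.normal(28.0, 8.0, size=(hw, hw))  # dark noisy background

    lum = np.where(mask.astype(bool), grain, background)
    lum += rng.normal(0.0, 3.0, size=(hw, hw))  # sensor noise everywhere
    lum = np.clip(lum, 0, 255)

    # mild per-class tint so color carries a little information too
    tint = np.array([1.0, 0.97, 0.92])
    image = np.clip(lum[..., None] * tint[None, None, :], 0, 255).astype(np.uint8)
    return image, mask


def gen_grain_images(
    n_per_class: int, n_classes: int = 5, hw: int = 128, seed: int = 0
) -> list[GrainImageSample]:
    """Generate a class-balanced, fully seeded list of grain samples."""
    if n_per_class < 1 or n_classes < 2:
        raise ValueError("need n_per_class >= 1 and n_classes >= 2")
    if hw < 64:
        raise ValueError("need hw >= 64")
    rng = np.random.default_rng(seed)
    samples: list[GrainImageSample] = []
    for label in range(n_classes):
        for _ in range(n_per_class):
            params = _class_params(label, hw, rng)
            image, mask = _render(params, hw, rng)
            samples.append(GrainImageSample(image=image, mask=mask, label=label, params=params))
    return samples


def gen_feature_matrix(
    spec: SyntheticFeatureSpec,
) -> tuple[pd.DataFrame, pd.Series, set[str]]:
    """Labeled feature matrix with planted informative / redundant / noise columns.

    Informative columns are class-conditional Gaussians with s.d.
    ``sigma``.  Each is the *dominant discriminator of one class pair*:
    column j is assigned pair (a, b) (cycling through all pairs in
    order) and carries class means ``+-0.675 * delta`` for a and b, zero
    for the other classes.  Every column is therefore individually
    load-bearing — removing it collapses the margin of its pair — while
    the full informative block separates all classes comfortably.

    Each redundant column copies an informative source (cycling in
    column order) plus Gaussian noise whose s.d. is solved analytically
    so the sample correlation with the source is ~``rho``: for source
    variance v, corr(x, x+e) = sqrt(v/(v+s^2)) gives
    s^2 = v (1/rho^2 - 1).  Noise columns are label-independent draws of
    s.d. ``sigma_noise`` — deliberately larger than ``sigma``, emulating
    the heterogeneous scales of raw network activations.

    Returns (features, labels, informative column-id set); the feature
    frame is indexed by ``sample_id`` with columns ``f_0001..``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples * spec.n_classes
    labels = np.repeat(np.arange(spec.n_classes), spec.n_samples)

    pairs = [
        (a, b)
        for a in range(spec.n_classes)
        for b in range(a + 1, spec.n_classes)
    ]
    mu = np.zeros((spec.n_classes, spec.k_informative))
    # 1.35*delta between the assigned pair's means: calibrated so the
    # weakest single-column margin is needed for error-free separation
    offset = 0.675 * spec.delta
    for j in range(spec.k_informative):
        a, b = pairs[j % len(pairs)]
        mu[a, j] = +offset
        mu[b, j] = -offset
    informative = mu[labels] + rng.normal(0.0, spec.sigma, size=(n, spec.k_informative))

    redundant = np.empty((n, spec.k_redundant))
    for j in range(spec.k_redundant):
        src = informative[:, j % spec.k_informative]
        if spec.rho == 0:
            redundant[:, j] = rng.normal(0.0, spec.sigma, size=n)
            continue
        v = src.var()
        s2 = v * (1.0 / spec.rho**2 - 1.0)
        redundant[:, j] = src + rng.normal(0.0, np.sqrt(s2), size=n)

    noise = rng.normal(0.0, spec.sigma_noise, size=(n, spec.k_noise))

    values = np.hstack([informative, redundant, noise])
    columns = [f"f_{j + 1:04d}" for j in range(spec.n_features)]
    index = pd.Index([f"s_{i:05d}" for i in range(n)], name="sample_id")
    features = pd.DataFrame(values, index=index, columns=columns)
    informative_ids = set(columns[: spec.k_informative])
    return features, pd.Series(labels, index=index, name="label"), informative_ids


def write_image_dataset(samples: list[GrainImageSample], out_dir) -> pd.DataFrame:
    """Write samples as per-class PNG directories plus masks and a label CSV."""
    import imageio.v3 as iio
    from pathlib import Path

    out = Path(out_dir)
    rows = []
    for i, s in enumerate(samples):
        cls_dir = out / f"class_{s.label}"
        cls_dir.mkdir(parents=True, exist_ok=True)
        img_path = cls_dir / f"grain_{i:05d}.png"
        mask_path = cls_dir / f"grain_{i:05d}_mask.png"
        iio.imwrite(img_path, s.image)
        iio.imwrite(mask_path, (s.mask * 255).astype(np.uint8))
        rows.append({"sample_id": img_path.stem, "label": s.label, "path": str(img_path)})
    frame = pd.DataFrame(rows).set_index("sample_id")
    frame.to_csv(out / "labels.csv")
    return frame
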