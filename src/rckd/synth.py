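"""Synthetic H&E-like image generation.

The generator emulates hematoxylin-and-eosin stained tissue patches at the
level needed to exercise the pipeline: an eosin-pink background with Gaussian
pixel noise and hematoxylin-purple elliptical nucleus-like blobs at random
positions, sizes and orientations.  The binary nuclei mask is exactly the
rendered blob support, so a mock teacher that looks the mask up is a perfect
oracle.  Downstream datasets encode class through generator statistics
(nucleus density, size, stain shift), making the default configuration
Bayes-separable.

Everything is reproducible bitwise from ``(params, seed)``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = ["SlideParams", "SyntheticSlide", "generate_slide",
           "make_downstream_dataset", "default_class_params"]


@dataclass
class SlideParams:
    """Generator statistics for one synthetic slide.

    ``nuclei_density`` is the expected number of nuclei per pixel; at the
    default density and radius range the foreground occupies roughly 15% of
    the slide, a plausible nuclear area fraction for cellular H&E tissue.
    Radii are in pixels (nuclei of ~10-20 px diameter, i.e. ~5-10 um at
    20x magnification).
    """

    height: int = 128
    width: int = 128
    nuclei_density: float = 1.1e-3
    min_nuclei: int = 0                         # guaranteed lower bound on blob count
    radius_range: tuple = (4.0, 9.0)
    background_color: tuple = (231, 180, 200)   # eosin-like pink
    nucleus_color: tuple = (92, 64, 150)        # hematoxylin-like purple
    color_jitter: float = 12.0
    noise_sd: float = 8.0
    n_regions: int = 0                          # >0: partition into labeled regions
    region_density_scale: tuple = (0.2, 2.0)    # density multiplier per region class

    def __post_init__(self):
        rmin, rmax = self.radius_range
        if rmin <= 0 or rmax < rmin:
            raise ValueError("invalid radius range")
        if rmax * 2 > min(self.height, self.width):
            raise ValueError("blob radius exceeds slide size")


@dataclass
class SyntheticSlide:
    image: np.ndarray                 # (H, W, 3) uint8
    nuclei_mask: np.ndarray           # (H, W) uint8 in {0, 1}
    region_labels: np.ndarray | None  # (H, W) int, or None
    generator_params: dict
    blobs: list = field(default_factory=list)  # (cy, cx, ra, rb, theta) per nucleus


def _stamp_ellipses(rng, H, W, n, radius_range, mask, where_scale=None):
    """Draw n random ellipses; returns list of (cy, cx, ra, rb, theta) and
    paints their support into `mask` (in-place)."""
    blobs = []
    rmin, rmax = radius_range
    for _ in range(n):
        cy = rng.uniform(0, H)
        cx = rng.uniform(0, W)
        if where_scale is not None:
            # thinning: keep the blob with probability given by the local
            # density multiplier at its centre (normalised to max 1)
            keep_p = where_scale[min(int(cy), H - 1), min(int(cx), W - 1)]
            if rng.uniform() > keep_p:
                continue
        ra = rng.uniform(rmin, rmax)
        rb = rng.uniform(rmin, rmax)
        theta = rng.uniform(0, np.pi)
        blobs.append((cy, cx, ra, rb, theta))
        r = max(ra, rb)
        y0, y1 = max(0, int(cy - r) - 1), min(H, int(cy + r) + 2)
        x0, x1 = max(0, int(cx - r) - 1), min(W, int(cx + r) + 2)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dy, dx = yy - cy, xx - cx
        u = (dx * np.cos(theta) + dy * np.sin(theta)) / ra
        v = (-dx * np.sin(theta) + dy * np.cos(theta)) / rb
        mask[y0:y1, x0:x1] |= (u * u + v * v) <= 1.0
    return blobs


def _voronoi_labels(rng, H, W, k):
    """Voronoi partition into k regions; region classes alternate 0/1
    (class 0 = sparse, class 1 = dense)."""
    pts = np.stack([rng.uniform(0, H, k), rng.uniform(0, W, k)], axis=1)
    yy, xx = np.mgrid[0:H, 0:W]
    d = (yy[None] - pts[:, 0, None, None]) ** 2 + (xx[None] - pts[:, 1, None, None]) ** 2
    site = d.argmin(axis=0)
    classes = np.arange(k) % 2
    return classes[site], site


def generate_slide(params: SlideParams, seed: int) -> SyntheticSlide:
    """Render one synthetic slide; bitwise reproducible from (params, seed)."""
    rng = np.random.default_rng(seed)
    H, W = params.height, params.width
    mask = np.zeros((H, W), dtype=bool)
    region_labels = None
    where_scale = None
    if params.n_regions > 0:
        labels, _ = _voronoi_labels(rng, H, W, params.n_regions)
        region_labels = labels.astype(np.int64)
        lo, hi = params.region_density_scale
        scale_per_class = np.where(np.arange(labels.max() + 1) == 0, lo, hi)
        where_scale = scale_per_class[labels] / max(lo, hi)

    n_expected = params.nuclei_density * H * W
    if params.n_regions > 0:
        n_expected *= max(params.region_density_scale)
    n = max(int(rng.poisson(n_expected)), params.min_nuclei)
    blobs = _stamp_ellipses(rng, H, W, n, params.radius_range, mask, where_scale)

    img = np.empty((H, W, 3), dtype=np.float64)
    img[:] = np.asarray(params.background_color, dtype=np.float64)
    if mask.any():
        jitter = rng.normal(0, params.color_jitter, 3)
        img[mask] = np.asarray(params.nucleus_color, dtype=np.float64) + jitter
    img += rng.normal(0, params.noise_sd, (H, W, 3))
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)

    gp = dataclasses.asdict(params)
    gp["seed"] = int(seed)
    return SyntheticSlide(img, mask.astype(np.uint8), region_labels, gp, blobs)


def default_class_params(task: str, image_size: int = 64) -> list[SlideParams]:
    """Class-conditional generator settings with a clear effect size.

    Classification classes differ in nucleus density (sparse / medium /
    dense) with a mild stain shift; segmentation classes are spatial regions
    of low vs high nucleus density.
    """
    if task == "cls":
        base = dict(height=image_size, width=image_size)
        return [
            SlideParams(nuclei_density=0.4e-3,
                        nucleus_color=(92, 64, 150), **base),
            SlideParams(nuclei_density=1.1e-3,
                        nucleus_color=(110, 60, 130), **base),
            SlideParams(nuclei_density=2.2e-3,
                        nucleus_color=(70, 70, 165), **base),
        ]
    if task == "seg":
        return [SlideParams(height=image_size, width=image_size,
                            n_regions=3, region_density_scale=(0.15, 2.0))]
    raise ValueError(f"unknown task {task!r}")


def make_downstream_dataset(task: str, n_per_class: int,
                            params: list[SlideParams] | None = None,
                            seed: int = 0, image_size: int = 64):
    """Labeled synthetic datasets for fine-tuning.

    ``task='cls'``: list of (image, class_index) with class-dependent
    generator parameters.  ``task='seg'``: list of (image, region_label_map)
    where the map assigns each pixel the class of its texture region.
    """
    if params is None:
        params = default_class_params(task, image_size)
    if task == "cls":
        if len(params) < 2:
            raise ValueError("need at least 2 classes")
        keyed = [dataclasses.asdict(p) for p in params]
        if any(keyed[i] == keyed[j] for i in range(len(keyed))
               for j in range(i + 1, len(keyed))):
            import warnings
            warnings.warn("classes with identical generator params are "
                          "inseparable by construction")
        items = []
        for ci, p in enumerate(params):
            for j in range(n_per_class):
                slide = generate_slide(p, seed * 1_000_003 + ci * 10_007 + j)
                items.append((slide.image, ci))
        return items
    if task == "seg":
        p = params[0]
        if p.n_regions < 2:
            raise ValueError("segmentation generator needs n_regions >= 2")
        items = []
        for j in range(n_per_class):
            slide = generate_slide(p, seed * 1_000_003 + j)
            items.append((slide.image, slide.region_labels))
        return items
    raise ValueError(f"unknown task {task!r}")
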