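"""Patch extraction, background filtering and random sampling for large images.

Whole-slide-style images are tiled into non-overlapping fixed-size patches
from the top-left origin (partial edge tiles discarded), patches whose mean
8-bit intensity falls outside the tissue band are removed, and a fixed number
of survivors is sampled uniformly without replacement.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = ["PatchSpec", "Patch", "extract_patches", "tissue_filter",
           "sample_patches", "reassemble", "run_patch_pipeline", "write_manifest"]


@dataclass
class PatchSpec:
    magnification: int = 20           # nominal metadata tag
    patch_size: int = 1024
    intensity_low: float = 50.0
    intensity_high: float = 245.0
    sample_n: int | None = None

    def __post_init__(self):
        if not (0 <= self.intensity_low < self.intensity_high <= 255):
            raise ValueError("need 0 <= intensity_low < intensity_high <= 255")
        if self.patch_size < 1:
            raise ValueError("patch_size must be >= 1")


class Patch(NamedTuple):
    image: np.ndarray      # (P, P, 3) uint8
    row: int
    col: int

    @property
    def mean_intensity(self) -> float:
        return float(self.image.mean())


def extract_patches(image: np.ndarray, spec: PatchSpec) -> list[Patch]:
    """Non-overlapping tiling in row-major order; edge remainders discarded."""
    image = np.asarray(image)
    P = spec.patch_size
    H, W = image.shape[:2]
    n_rows, n_cols = H // P, W // P
    if n_rows == 0 or n_cols == 0:
        warnings.warn(f"image {H}x{W} smaller than one {P}x{P} patch; "
                      "returning empty list")
        return []
    out = []
    for r in range(n_rows):
        for c in range(n_cols):
            out.append(Patch(image[r * P:(r + 1) * P, c * P:(c + 1) * P], r, c))
    return out


def reassemble(patches: list[Patch], spec: PatchSpec) -> np.ndarray:
    """Stitch patches back onto their grid (inverse of extract_patches on the
    covered region)."""
    P = spec.patch_size
    n_rows = max(p.row for p in patches) + 1
    n_cols = max(p.col for p in patches) + 1
    sample = patches[0].image
    canvas = np.zeros((n_rows * P, n_cols * P) + sample.shape[2:], dtype=sample.dtype)
    for p in patches:
        canvas[p.row * P:(p.row + 1) * P, p.col * P:(p.col + 1) * P] = p.image
    return canvas


def tissue_filter(patch: np.ndarray | Patch, spec: PatchSpec) -> bool:
    """Keep iff the mean over all pixels and channels lies in the inclusive
    intensity band (8-bit scale)."""
    img = patch.image if isinstance(patch, Patch) else np.asarray(patch)
    if img.dtype != np.uint8:
        warnings.warn(f"converting {img.dtype} patch to 8-bit for filtering")
        img = np.clip(np.asarray(img, dtype=np.float64), 0, 255).astype(np.uint8)
    m = float(img.mean())
    return spec.intensity_low <= m <= spec.intensity_high


def sample_patches(patches: list, n: int, seed: int) -> list:
    """Uniform sampling without replacement, deterministic for a given seed."""
    rng = np.random.default_rng(seed)
    if n >= len(patches):
        if n > len(patches):
            warnings.warn(f"requested {n} > {len(patches)} patches; taking all")
        n = len(patches)
    idx = rng.choice(len(patches), size=n, replace=False)
    return [patches[i] for i in idx]


def run_patch_pipeline(image: np.ndarray, spec: PatchSpec, seed: int = 0):
    """Tile -> filter -> sample, with a log of counts at each step."""
    tiles = extract_patches(image, spec)
    kept = [p for p in tiles if tissue_filter(p, spec)]
    n = spec.sample_n if spec.sample_n is not None else len(kept)
    chosen = sample_patches(kept, n, seed)
    log = {"n_tiles": len(tiles), "n_kept": len(kept), "n_sampled": len(chosen)}
    return chosen, log


def write_manifest(patches: list[Patch], spec: PatchSpec, path, kept_flags=None):
    """CSV manifest: filename, row, col, mean_intensity, kept_flag."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["filename", "row", "col", "mean_intensity", "kept_flag"])
        for i, p in enumerate(patches):
            kept = kept_flags[i] if kept_flags is not None else tissue_filter(p, spec)
            w.writerow([f"patch_r{p.row}_c{p.col}.png", p.row, p.col,
                        f"{p.mean_intensity:.3f}", int(kept)])
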