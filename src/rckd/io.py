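"""Serialization: model checkpoints (.npz with embedded config) and images."""

from __future__ import annotations

import json

import numpy as np
from PIL import Image

from .csat import CSAT, CSATConfig

__all__ = ["save_checkpoint", "load_checkpoint", "load_image", "save_image",
           "save_mask_png", "load_mask_png", "save_prob_png16", "load_prob_png16"]


def save_checkpoint(model, path, config: CSATConfig | None = None,
                    meta: dict | None = None):
    """Write model weights as .npz with the config and metadata embedded."""
    arrays = {f"param/{name}": p.data for name, p in model.named_parameters()}
    header = {"meta": meta or {}}
    if config is not None:
        header["config"] = config.to_dict()
    elif hasattr(model, "config"):
        header["config"] = model.config.to_dict()
    arrays["__header__"] = np.frombuffer(
        json.dumps(header).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path, model=None, head: str | None = None):
    """Load a checkpoint; if ``model`` is None, rebuild a CSAT from the
    embedded config."""
    with np.load(path) as z:
        header = json.loads(bytes(z["__header__"].tobytes()).decode())
        state = {k[len("param/"):]: z[k] for k in z.files if k.startswith("param/")}
    if model is None:
        if "config" not in header:
            raise ValueError("checkpoint has no embedded config; pass a model")
        model = CSAT(CSATConfig(**header["config"]), head=head)
    model.load_state_dict(state)
    return model, header


def load_image(path) -> np.ndarray:
    """Read a raster image (PNG/JPEG/TIFF) as an (H, W, 3) uint8 array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def save_image(arr: np.ndarray, path):
    Image.fromarray(np.asarray(arr, dtype=np.uint8)).save(path)


def save_mask_png(mask: np.ndarray, path):
    """Binary mask as 8-bit single-channel PNG (0/255)."""
    Image.fromarray((np.asarray(mask) > 0).astype(np.uint8) * 255).save(path)


def load_mask_png(path) -> np.ndarray:
    with Image.open(path) as im:
        return (np.asarray(im.convert("L")) > 127).astype(np.uint8)


def save_prob_png16(prob: np.ndarray, path):
    """Probability map in [0,1] as 16-bit single-channel PNG."""
    arr = np.clip(np.asarray(prob, dtype=np.float64), 0, 1)
    Image.fromarray(np.round(arr * 65535).astype(np.uint16)).save(path)


def load_prob_png16(path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im, dtype=np.float64) / 65535.0
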