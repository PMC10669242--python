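"""Response-based cross-task knowledge distillation (pretraining).

A frozen teacher predicts per-pixel nuclei probabilities for unlabeled
images; thresholding at alpha gives binary pseudo-labels; a student
(backbone + U-Net-style decoder with a single sigmoid output) is trained to
reproduce them under a pixel-averaged binary cross-entropy, optimised with
LARS (linear warm-up from a zero initial rate, cosine decay after).  The
teacher's task (nuclei segmentation) need not match the student's downstream
task: knowledge transfers through the pretrained backbone, whose
segmentation head is discarded afterwards.
"""

from __future__ import annotations

import hashlib
import json
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn
from .nn import Tensor
from .nn.autograd import interpolate_bilinear, no_grad
from .csat import CSAT, CSATConfig, build_csat
from .heads import UNetDecoder

__all__ = ["DistillConfig", "MockTeacher", "ExternalCommandTeacher", "binarize",
           "kd_loss", "resize_for_pretraining", "StudentModel", "build_student",
           "pretrain"]

EPS = 1e-12


@dataclass
class DistillConfig:
    threshold_alpha: float = 0.5
    input_size: int = 512
    batch_size: int = 64
    epochs: int = 100
    warmup_epochs: int = 10
    base_lr: float = 0.0          # initial global rate; LARS adapts per layer
    peak_lr: float = 1.0          # end of linear warm-up
    trust_coefficient: float = 0.001
    momentum: float = 0.9
    weight_decay: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.threshold_alpha < 1.0):
            raise ValueError("threshold_alpha must lie in (0, 1)")
        if self.warmup_epochs > self.epochs and self.epochs > 0:
            raise ValueError("warmup_epochs must not exceed epochs")


# -- teachers -----------------------------------------------------------------

def _image_key(image: np.ndarray) -> str:
    image = np.ascontiguousarray(image)
    return hashlib.sha1(image.tobytes() + str(image.shape).encode()).hexdigest()


class MockTeacher:
    """Oracle teacher for synthetic slides: returns the stored ground-truth
    nuclei mask of each known image as a probability map.

    Input convention: 8-bit RGB arrays (H, W, 3) in [0, 255].
    """

    def __init__(self, pairs):
        """``pairs``: iterable of (image, mask) or SyntheticSlide objects."""
        self._maps = {}
        for item in pairs:
            if hasattr(item, "nuclei_mask"):
                image, mask = item.image, item.nuclei_mask
            else:
                image, mask = item
            self._maps[_image_key(image)] = np.asarray(mask, dtype=np.float64)

    def predict(self, image: np.ndarray) -> np.ndarray:
        key = _image_key(np.asarray(image))
        if key not in self._maps:
            raise KeyError("mock teacher has no ground truth for this image")
        return self._maps[key]


class ExternalCommandTeacher:
    """Subprocess teacher contract: the command receives an input PNG path and
    an output path and writes the probability map as a 16-bit single-channel
    PNG (0..65535 mapped to [0, 1])."""

    def __init__(self, command: list[str]):
        self.command = list(command)

    def predict(self, image: np.ndarray) -> np.ndarray:
        from PIL import Image
        with tempfile.TemporaryDirectory() as td:
            inp = Path(td) / "in.png"
            out = Path(td) / "out.png"
            Image.fromarray(np.asarray(image, dtype=np.uint8)).save(inp)
            subprocess.run(self.command + [str(inp), str(out)], check=True)
            arr = np.asarray(Image.open(out), dtype=np.float64)
        if arr.ndim != 2:
            raise ValueError("external teacher must write a single-channel map")
        return arr / 65535.0


# -- core operations ----------------------------------------------------------

def binarize(y: np.ndarray, alpha: float = 0.5) -> np.ndarray:
    """Pseudo-label map: 1 where y >= alpha (inclusive), else 0."""
    y = np.asarray(y)
    if y.size and (y.min() < 0.0 or y.max() > 1.0):
        raise ValueError("probability map entries must lie in [0, 1]")
    return (y >= alpha).astype(np.uint8)


def kd_loss(student_probs, pseudo) -> Tensor:
    """Binary cross-entropy between student probabilities and pseudo-labels,
    averaged over all pixels."""
    p = student_probs if isinstance(student_probs, Tensor) else Tensor(np.asarray(student_probs, dtype=np.float64))
    t = np.asarray(pseudo, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: student {p.shape} vs pseudo {t.shape}")
    pc = p.clamp(EPS, 1.0 - EPS)
    loss = -(Tensor(t) * pc.log() + Tensor(1.0 - t) * (1.0 - pc).log()).mean()
    if not np.isfinite(loss.data):
        bad = int(np.sum(~np.isfinite(p.data)))
        raise FloatingPointError(f"non-finite distillation loss ({bad} bad pixels)")
    return loss


def _resize_nearest(mask: np.ndarray, size: int) -> np.ndarray:
    H, W = mask.shape
    iy = np.minimum((np.arange(size) + 0.5) * H / size, H - 1).astype(int)
    ix = np.minimum((np.arange(size) + 0.5) * W / size, W - 1).astype(int)
    return mask[iy[:, None], ix[None, :]]


def resize_for_pretraining(image: np.ndarray, pseudo: np.ndarray | None = None,
                           input_size: int = 512):
    """Bilinear resize of the image to input_size x input_size; the
    pseudo-label (if given) is resized nearest-neighbour to stay binary."""
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 3:
        raise ValueError("expected an RGB image (H, W, 3)")
    x = Tensor(img.transpose(2, 0, 1)[None])
    with no_grad():
        out = interpolate_bilinear(x, input_size, input_size)
    resized = out.data[0].transpose(1, 2, 0)
    if pseudo is None:
        return resized
    return resized, _resize_nearest(np.asarray(pseudo), input_size)


# -- student ------------------------------------------------------------------

class StudentModel(nn.Module):
    """CSAT backbone + single-channel sigmoid segmentation decoder."""

    def __init__(self, backbone: CSAT):
        super().__init__()
        if backbone.head_kind is not None:
            raise ValueError("student backbone must be headless")
        self.backbone = backbone
        self.seg_head = UNetDecoder(backbone.config.stage_channels, 1,
                                    activation="sigmoid")

    def forward(self, x: Tensor) -> Tensor:
        _, _, H, W = x.shape
        feats = self.backbone.forward_features(x)
        return self.seg_head(feats, H, W)


def build_student(config: CSATConfig | None = None, seed: int = 0) -> StudentModel:
    backbone = build_csat(config, head=None, seed=seed)
    student = StudentModel(backbone)
    student.init_parameters(np.random.default_rng(seed))
    return student


# -- pretraining loop ---------------------------------------------------------

def _normalise_image(img: np.ndarray) -> np.ndarray:
    return np.asarray(img, dtype=np.float64) / 255.0


def pretrain(student: StudentModel, teacher, images: list,
             config: DistillConfig, log_path=None):
    """Distillation pretraining; returns (backbone, per-epoch log).

    ``images``: list of 8-bit RGB arrays.  Pseudo-labels are generated once
    (the teacher is frozen) and cached; pairs are resized to
    ``config.input_size``; the loop is fully deterministic given
    ``config.seed``.
    """
    if len(images) == 0:
        raise ValueError("empty image set")
    s = config.input_size
    pairs = []
    for img in images:
        y = np.asarray(teacher.predict(img))
        if y.shape != np.asarray(img).shape[:2]:
            raise ValueError(f"teacher output {y.shape} does not match image "
                             f"{np.asarray(img).shape[:2]}")
        pseudo = binarize(y, config.threshold_alpha)
        im_r, ps_r = resize_for_pretraining(img, pseudo, s)
        pairs.append((_normalise_image(im_r).transpose(2, 0, 1), ps_r[None]))

    params = dict(student.named_parameters())
    opt = nn.LARS(params.values(), lr=0.0,
                  trust_coefficient=config.trust_coefficient,
                  momentum=config.momentum, weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed)
    log = []
    for epoch in range(config.epochs):
        lr = nn.warmup_cosine_lr(epoch, config.epochs, config.warmup_epochs,
                                 config.base_lr, config.peak_lr)
        opt.lr = lr
        order = rng.permutation(len(pairs))
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            xb = Tensor(np.stack([pairs[i][0] for i in idx]))
            tb = np.stack([pairs[i][1] for i in idx])
            probs = student(xb)
            loss = kd_loss(probs, tb)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        rec = {"epoch": epoch, "mean_loss": float(np.mean(losses)),
               "lr": float(lr), "seed": int(config.seed)}
        log.append(rec)
        if log_path is not None:
            with open(log_path, "a") as fh:
                fh.write(json.dumps(rec) + "\n")
    return student.backbone, log
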