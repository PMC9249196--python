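"""Region-of-interest cropping, aspect-preserving resize, and augmentation.

Detected (or ground-truth) boxes are cropped out of the radiograph and
brought to the common network input size of 77x35 pixels.  Because the
relative proportions of the vertebral bodies carry the staging signal, both
axes are scaled by the single factor that fits the crop inside 77x35 and the
remainder is padded symmetrically with the crop's median intensity.

Augmentation produces exactly ten label-preserving variants per image:
eight integer translations (+/-3 and +/-6 px along each axis) and two
rotations (+/-5 degrees about the centre), with median-intensity fill.  The
evaluation protocol only ever augments training folds; the ``is_augmented``
flag makes leakage assertable downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from skimage.transform import resize as sk_resize
from skimage.transform import rotate as sk_rotate

from .roi_types import RoiBox

__all__ = [
    "TARGET_SHAPE", "LabeledImage",
    "crop_and_resize", "augment_image", "augment_dataset",
]

TARGET_SHAPE: tuple[int, int] = (77, 35)   # rows, cols

SHIFTS_PX: tuple[tuple[int, int], ...] = (
    (0, 3), (0, -3), (0, 6), (0, -6),      # right / left
    (3, 0), (-3, 0), (6, 0), (-6, 0),      # down / up
)
ROTATIONS_DEG: tuple[float, float] = (5.0, -5.0)


@dataclass(frozen=True)
class LabeledImage:
    """A 77x35 grayscale crop with its stage label and provenance."""

    pixels: np.ndarray
    label: int
    source_id: str
    is_augmented: bool = False

    def __post_init__(self) -> None:
        if self.label not in range(1, 7):
            raise ValueError("label must be a stage in 1..6")
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.min() < -1e-9 or px.max() > 1 + 1e-9:
            raise ValueError("pixel values must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)


def crop_and_resize(
    image: np.ndarray,
    box: RoiBox,
    target: tuple[int, int] = TARGET_SHAPE,
) -> np.ndarray:
    """Crop ``box``, rescale by one shared factor, pad to exactly ``target``.

    Bilinear interpolation; padding uses the crop's median intensity and is
    split as evenly as possible on both sides of each axis.
    """
    th, tw = target
    crop = np.asarray(image, dtype=np.float64)[box.y:box.y2, box.x:box.x2]
    if crop.size == 0:
        raise ValueError("empty crop")
    ch, cw = crop.shape
    scale = min(th / ch, tw / cw)
    nh = min(th, max(1, round(ch * scale)))
    nw = min(tw, max(1, round(cw * scale)))
    resized = sk_resize(crop, (nh, nw), order=1, mode="reflect",
                        anti_aliasing=scale < 1.0, preserve_range=True)
    out = np.full((th, tw), np.median(crop))
    r0 = (th - nh) // 2
    c0 = (tw - nw) // 2
    out[r0:r0 + nh, c0:c0 + nw] = resized
    return np.clip(out, 0.0, 1.0)


def _shift(pixels: np.ndarray, dy: int, dx: int, fill: float) -> np.ndarray:
    out = np.full_like(pixels, fill)
    h, w = pixels.shape
    ys = slice(max(0, dy), min(h, h + dy))
    xs = slice(max(0, dx), min(w, w + dx))
    ys_src = slice(max(0, -dy), min(h, h - dy))
    xs_src = slice(max(0, -dx), min(w, w - dx))
    out[ys, xs] = pixels[ys_src, xs_src]
    return out


def augment_image(
    img: LabeledImage,
    rng: Optional[np.random.Generator] = None,
) -> list[LabeledImage]:
    """Exactly ten augmented copies: 8 shifts and 2 rotations.

    Deterministic given the input (``rng`` is accepted for interface
    compatibility but the displacement set is fixed).
    """
    if img.pixels.shape != TARGET_SHAPE:
        raise ValueError(f"expected {TARGET_SHAPE} input")
    med = float(np.median(img.pixels))
    out: list[LabeledImage] = []
    for dy, dx in SHIFTS_PX:
        out.append(LabeledImage(
            pixels=_shift(img.pixels, dy, dx, med),
            label=img.label,
            source_id=f"{img.source_id}#shift({dy},{dx})",
            is_augmented=True))
    for angle in ROTATIONS_DEG:
        rot = sk_rotate(img.pixels, angle, order=1, mode="constant",
                        cval=med, preserve_range=True)
        out.append(LabeledImage(
            pixels=np.clip(rot, 0.0, 1.0),
            label=img.label,
            source_id=f"{img.source_id}#rot({angle:+.0f})",
            is_augmented=True))
    return out


def augment_dataset(train: Sequence[LabeledImage]) -> list[LabeledImage]:
    """Originals plus ten variants each: N inputs -> 11N outputs.

    Per-class proportions are preserved by construction (761 -> 8371 for the
    study-sized training split).
    """
    out: list[LabeledImage] = []
    for img in train:
        out.append(img)
        out.extend(augment_image(img))
    return out
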