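"""Synthetic lateral-cephalogram generator with known stage labels and boxes.

Real staging data are full skull radiographs in which the shapes of the
second to fourth cervical vertebral bodies (C2, C3, C4) encode skeletal
maturation.  This module emulates the essentials on a noisy canvas: a bright
skull-like distractor, a textured background, and a stack of three vertebral
bodies whose inferior-border concavity and width/height aspect ratio follow
the six-stage morphology:

* stage 1: all inferior borders flat; C3/C4 trapezoidal (narrower on top)
* stage 2: concavity on C2 only; C3/C4 still flat trapezoids
* stage 3: concavities on C2 and C3; C4 flat; trapezoids
* stage 4: concavities on C2-C4; C3/C4 horizontally elongated rectangles
           (aspect > 1.15)
* stage 5: concavities on C2-C4; C3/C4 near-square (aspect in [0.9, 1.1])
* stage 6: concavities on C2-C4; C3/C4 vertically elongated (aspect < 0.85)

All numeric shape parameters are the generator's own operationalisation of
those qualitative rules; neighbouring stages are kept close so that the
classification task is realistic rather than trivially separable.  Every
sample carries the tight bounding box of the stack (padded 10%) as ground
truth for the region-of-interest detector.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from skimage.draw import polygon as draw_polygon
from skimage.draw import ellipse as draw_ellipse

from .roi_types import RoiBox

__all__ = [
    "STUDY_PROFILE", "BodyGeometry", "VertebraGeometry", "SyntheticSample",
    "sample_stage_geometry", "render_cephalogram", "generate_dataset",
    "generate_manifest",
]

#: Per-stage image counts of the 1018-image study layout used as defaults.
STUDY_PROFILE: dict[int, int] = {1: 154, 2: 187, 3: 174, 4: 159, 5: 167, 6: 177}

DEFAULT_CANVAS: tuple[int, int] = (400, 300)   # rows, cols


@dataclass(frozen=True)
class BodyGeometry:
    """One vertebral body: size in pixels, shape ratios, border concavity."""

    width: float            # inferior-border width, px
    aspect: float           # width / height
    taper: float            # superior width / inferior width (<1: trapezoid)
    concavity: float        # notch depth as a fraction of body height

    def __post_init__(self) -> None:
        if not 0.0 <= self.concavity <= 0.35:
            raise ValueError("concavity depth must be in [0, 0.35]")
        if self.aspect <= 0 or self.width <= 0 or self.taper <= 0:
            raise ValueError("degenerate body geometry")

    @property
    def height(self) -> float:
        return self.width / self.aspect


@dataclass(frozen=True)
class VertebraGeometry:
    """C2 (top), C3, C4 (bottom) body geometries."""

    c2: BodyGeometry
    c3: BodyGeometry
    c4: BodyGeometry

    @property
    def bodies(self) -> tuple[BodyGeometry, BodyGeometry, BodyGeometry]:
        return (self.c2, self.c3, self.c4)


@dataclass(frozen=True)
class SyntheticSample:
    pixels: np.ndarray          # float in [0, 1], shape = canvas
    label: int                  # stage 1..6
    true_box: RoiBox
    seed: Optional[int] = None


_FLAT = (0.0, 0.04)
_NOTCH = (0.15, 0.30)


def _u(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(rng.uniform(lo, hi))


def sample_stage_geometry(stage: int, rng: np.random.Generator) -> VertebraGeometry:
    """Draw body geometry from the stage-conditional shape distributions."""
    if stage not in range(1, 7):
        raise ValueError("stage must be in 1..6")

    conc_c2 = _u(rng, *(_FLAT if stage == 1 else _NOTCH))
    conc_c3 = _u(rng, *(_NOTCH if stage >= 3 else _FLAT))
    conc_c4 = _u(rng, *(_NOTCH if stage >= 4 else _FLAT))

    if stage <= 3:      # trapezoidal, wider than tall
        taper = lambda: _u(rng, 0.72, 0.90)
        aspect = lambda: _u(rng, 1.25, 1.65)
    elif stage == 4:    # horizontally elongated rectangle
        taper = lambda: _u(rng, 0.96, 1.04)
        aspect = lambda: _u(rng, 1.16, 1.45)
    elif stage == 5:    # near-square
        taper = lambda: _u(rng, 0.96, 1.04)
        aspect = lambda: _u(rng, 0.90, 1.10)
    else:               # vertically elongated rectangle
        taper = lambda: _u(rng, 0.96, 1.04)
        aspect = lambda: _u(rng, 0.62, 0.84)

    base_w = _u(rng, 38.0, 48.0)
    c2 = BodyGeometry(width=base_w * _u(rng, 1.05, 1.2),
                      aspect=_u(rng, 1.4, 1.8),
                      taper=_u(rng, 0.88, 1.0),
                      concavity=conc_c2)
    c3 = BodyGeometry(width=base_w, aspect=aspect(), taper=taper(),
                      concavity=conc_c3)
    c4 = BodyGeometry(width=base_w * _u(rng, 0.95, 1.05), aspect=aspect(),
                      taper=taper(), concavity=conc_c4)
    return VertebraGeometry(c2=c2, c3=c3, c4=c4)


def _notch_polygon(xl: float, xr: float, yb: float, depth_px: float,
                   n: int = 17) -> tuple[np.ndarray, np.ndarray]:
    """Parabolic segment rising ``depth_px`` into the body from its inferior
    border between x = xl..xr (the carved concavity)."""
    t = np.linspace(0.0, 1.0, n)
    xs = xl + t * (xr - xl)
    ys = yb - depth_px * (1.0 - (2.0 * t - 1.0) ** 2)
    return np.concatenate([ys, [yb + 1.0, yb + 1.0]]), np.concatenate([xs, [xr, xl]])


def render_cephalogram(
    geom: VertebraGeometry,
    stage: int,
    rng: np.random.Generator,
    size: tuple[int, int] = DEFAULT_CANVAS,
    noise_sigma: float = 0.03,
    tilt_deg: float = 0.0,
) -> SyntheticSample:
    """Render one radiograph-like image for the given geometry.

    The three bodies are drawn as bright filled polygons over smooth
    background texture, inferior-border concavities are carved as parabolic
    notches, and the whole canvas is blurred and corrupted with Gaussian
    noise.  ``tilt_deg`` rotates the stack to mimic posture inclination
    (off by default).
    """
    h, w = size
    stack_h = sum(b.height for b in geom.bodies) + 2 * 9.0
    if stack_h > 0.9 * h or max(b.width for b in geom.bodies) > 0.9 * w:
        raise ValueError("geometry larger than canvas")

    # background: low-frequency texture
    coarse = rng.random((10, 8))
    bg = ndimage.zoom(coarse, (h / 10, w / 8), order=1)[:h, :w]
    img = 0.22 + 0.10 * bg

    # skull-like distractor: bright ellipse + rim in the upper-left
    cy, cx = int(0.18 * h + rng.uniform(-8, 8)), int(0.30 * w + rng.uniform(-10, 10))
    ry, rx = int(0.13 * h), int(0.22 * w)
    rr, cc = draw_ellipse(cy, cx, ry, rx, shape=img.shape)
    img[rr, cc] = 0.50 + 0.05 * bg[rr, cc]
    rr, cc = draw_ellipse(cy, cx, int(ry * 0.75), int(rx * 0.75), shape=img.shape)
    img[rr, cc] = 0.38 + 0.05 * bg[rr, cc]

    # vertebral stack
    cx0 = _u(rng, 0.40, 0.62) * w
    y = _u(rng, 0.36, 0.50) * h
    gap = _u(rng, 6.0, 9.0)
    tilt = np.deg2rad(tilt_deg)
    xs_all, ys_all = [], []
    for body in geom.bodies:
        bh, bw, tw = body.height, body.width, body.width * body.taper
        # corner order: top-left, top-right, bottom-right, bottom-left
        px = np.array([cx0 - tw / 2, cx0 + tw / 2, cx0 + bw / 2, cx0 - bw / 2])
        py = np.array([y, y, y + bh, y + bh])
        if tilt != 0.0:
            mx, my = cx0, y + bh / 2
            px, py = (mx + (px - mx) * np.cos(tilt) - (py - my) * np.sin(tilt),
                      my + (px - mx) * np.sin(tilt) + (py - my) * np.cos(tilt))
        val = _u(rng, 0.72, 0.86)
        rr, cc = draw_polygon(py, px, shape=img.shape)
        img[rr, cc] = val
        if body.concavity > 0.0:
            nys, nxs = _notch_polygon(cx0 - bw * 0.38, cx0 + bw * 0.38,
                                      y + bh, body.concavity * bh)
            rr, cc = draw_polygon(nys, nxs, shape=img.shape)
            img[rr, cc] = 0.30 + 0.05 * bg[rr, cc]
        xs_all.extend(px)
        ys_all.extend(py)
        y += bh + gap

    img = ndimage.gaussian_filter(img, sigma=1.1)
    if noise_sigma > 0:
        img = img + rng.normal(0.0, noise_sigma, img.shape)
    img = np.clip(img, 0.0, 1.0)

    x0, x1 = min(xs_all), max(xs_all)
    y0, y1 = min(ys_all), max(ys_all)
    pad_x, pad_y = 0.10 * (x1 - x0), 0.10 * (y1 - y0)
    bx = int(max(0, np.floor(x0 - pad_x)))
    by = int(max(0, np.floor(y0 - pad_y)))
    bx2 = int(min(w, np.ceil(x1 + pad_x)))
    by2 = int(min(h, np.ceil(y1 + pad_y)))
    box = RoiBox(x=bx, y=by, width=bx2 - bx, height=by2 - by)
    return SyntheticSample(pixels=img, label=stage, true_box=box)


def _sample_rng(seed: int, index: int) -> np.random.Generator:
    # one stream per sample, keyed by (seed, index)
    return np.random.default_rng(np.random.SeedSequence([seed, index]))


def generate_dataset(
    n_per_class: Union[dict[int, int], Sequence[int], int],
    seed: int = 0,
    size: tuple[int, int] = DEFAULT_CANVAS,
    noise_sigma: float = 0.03,
) -> list[SyntheticSample]:
    """Generate labelled samples in memory; order is stage-major."""
    counts = _normalize_counts(n_per_class)
    out: list[SyntheticSample] = []
    index = 0
    for stage in range(1, 7):
        for _ in range(counts.get(stage, 0)):
            rng = _sample_rng(seed, index)
            geom = sample_stage_geometry(stage, rng)
            sample = render_cephalogram(geom, stage, rng, size=size,
                                        noise_sigma=noise_sigma)
            out.append(SyntheticSample(pixels=sample.pixels, label=stage,
                                       true_box=sample.true_box, seed=index))
            index += 1
    return out


def _normalize_counts(n_per_class) -> dict[int, int]:
    if isinstance(n_per_class, int):
        return {s: n_per_class for s in range(1, 7)}
    if isinstance(n_per_class, dict):
        counts = {int(k): int(v) for k, v in n_per_class.items()}
    else:
        counts = {s: int(c) for s, c in zip(range(1, 7), n_per_class)}
    if any(v < 0 for v in counts.values()):
        raise ValueError("counts must be nonnegative")
    return counts


def generate_manifest(
    n_per_class: Union[dict[int, int], Sequence[int], int],
    seed: int,
    outdir: Union[str, Path],
    size: tuple[int, int] = DEFAULT_CANVAS,
    noise_sigma: float = 0.03,
) -> Path:
    """Write PNGs plus a CSV manifest (path, label, x, y, w, h, seed).

    With the :data:`STUDY_PROFILE` counts the manifest totals 1018 rows.
    Two runs with the same seed produce byte-identical output.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts = _normalize_counts(n_per_class)
    rows = []
    index = 0
    for stage in range(1, 7):
        for _ in range(counts.get(stage, 0)):
            rng = _sample_rng(seed, index)
            geom = sample_stage_geometry(stage, rng)
            s = render_cephalogram(geom, stage, rng, size=size,
                                   noise_sigma=noise_sigma)
            name = f"img_{index:05d}_cs{stage}.png"
            iio.imwrite(outdir / name,
                        (s.pixels * 255).round().astype(np.uint8))
            rows.append((name, stage, s.true_box.x, s.true_box.y,
                         s.true_box.width, s.true_box.height, index))
            index += 1
    csv_path = outdir / "manifest.csv"
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "label", "x", "y", "w", "h", "seed"])
        writer.writerows(rows)
    return csv_path
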