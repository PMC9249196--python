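"""Design and application of the tunable directional edge-filter bank.

The bank starts from a 7th-order half-band Lagrange (maximally flat) lowpass
prototype

    H_lp(z) = 1 + (9/16)(z + z^-1) - (1/16)(z^3 + z^-3),

whose DC gain is H_lp(1) = 2.  Modulating by (-1)^n (H_hp(z) = H_lp(-z))
turns it into a high-pass filter; convolving the high-pass impulse response
with the short smoother h_c[n] = {1, 2, 1} suppresses noise amplification at
the highest frequencies and yields a band-pass edge detector h_bp with gain 2
at omega = pi/2 and exact nulls at omega = 0 and pi.

A 2-D horizontal prototype is formed by laying h_bp along the centre row,

    h_0deg[n1, n2] = h_bp[n1] * delta[n2],

(n1 indexes columns, n2 rows), which produces zero-crossings at vertical
edges.  Rotating the prototype to theta in {-63.43, -45, -26.56, 0, 26.56,
45, 63.43, 90} degrees gives eight directional kernels.  Rotation is by
sparse digital-line placement rather than interpolation: each prototype tap
is placed on (or split across) the lattice points nearest the ideal line, so
the coefficient sums taken perpendicular to the filter direction reproduce
the prototype taps exactly and every kernel keeps a coefficient sum of zero
(no response to constant images).

Prototype coefficients are kept as exact rationals (sixteenths) and only
converted to floating point when a kernel or response is materialised.
"""

from __future__ import annotations

import cmath
import json
import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
from scipy import ndimage

__all__ = [
    "DEFAULT_ANGLES_DEG",
    "Filter1D",
    "Kernel2D",
    "DirectionalFilterBank",
    "FrequencyPoint",
    "lagrange_halfband_lowpass",
    "modulate_to_highpass",
    "smoothing_lowpass",
    "smooth_bandpass",
    "bandpass_prototype",
    "frequency_response",
    "build_directional_kernel",
    "build_bank",
    "apply_bank",
]

#: Orientations (degrees from horizontal) of the eight directional kernels.
#: tan(26.56deg) ~ 1/2 and tan(63.43deg) ~ 2: digital lines of slope 1/2 and 2.
DEFAULT_ANGLES_DEG: tuple[float, ...] = (
    -63.43, -45.0, -26.56, 0.0, 26.56, 45.0, 63.43, 90.0,
)

_ANGLE_TOL = 0.05


@dataclass(frozen=True)
class Filter1D:
    """Odd-length FIR filter with exact rational taps, centred at ``center``."""

    taps: tuple[Fraction, ...]
    center: int

    def __post_init__(self) -> None:
        if len(self.taps) % 2 != 1:
            raise ValueError("Filter1D requires an odd number of taps")
        if self.center != len(self.taps) // 2:
            raise ValueError("center must be the middle tap index")

    def __len__(self) -> int:
        return len(self.taps)

    def as_array(self, dtype=np.float64) -> np.ndarray:
        return np.array([float(t) for t in self.taps], dtype=dtype)

    @property
    def dc_gain(self) -> Fraction:
        return sum(self.taps, Fraction(0))


@dataclass(frozen=True)
class Kernel2D:
    """Square 2-D kernel oriented at ``angle_deg`` (weights[row, col])."""

    weights: np.ndarray
    angle_deg: float

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        if w.ndim != 2 or w.shape[0] != w.shape[1] or w.shape[0] % 2 != 1:
            raise ValueError("kernel must be square with odd support")
        object.__setattr__(self, "weights", w)

    @property
    def support(self) -> tuple[int, int]:
        return self.weights.shape


@dataclass(frozen=True)
class FrequencyPoint:
    """Magnitude of a transfer function at one (1-D or 2-D) radian frequency."""

    omega: tuple[float, ...]
    magnitude: float

    def __post_init__(self) -> None:
        if self.magnitude < 0:
            raise ValueError("magnitude must be nonnegative")


@dataclass(frozen=True)
class DirectionalFilterBank:
    """Ordered set of directional 2-D kernels, one per orientation."""

    kernels: tuple[Kernel2D, ...]
    angles_deg: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.kernels) != len(self.angles_deg):
            raise ValueError("kernels/angles length mismatch")
        if len(set(self.angles_deg)) != len(self.angles_deg):
            raise ValueError("duplicate angles in bank")

    def __len__(self) -> int:
        return len(self.kernels)

    @property
    def support(self) -> tuple[int, int]:
        return self.kernels[0].support

    def as_stack(self, dtype=np.float64) -> np.ndarray:
        """Kernels stacked along axis 0, shape (n_kernels, S, S)."""
        return np.stack([k.weights for k in self.kernels]).astype(dtype)

    # -- serialization -----------------------------------------------------

    def to_json(self, path: Union[str, Path]) -> None:
        payload = {
            "angles_deg": list(self.angles_deg),
            "support": list(self.support),
            "kernels": [
                {"angle_deg": k.angle_deg, "weights": k.weights.tolist()}
                for k in self.kernels
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "DirectionalFilterBank":
        payload = json.loads(Path(path).read_text())
        kernels = tuple(
            Kernel2D(np.array(k["weights"], dtype=np.float64), k["angle_deg"])
            for k in payload["kernels"]
        )
        return cls(kernels=kernels, angles_deg=tuple(payload["angles_deg"]))


# ---------------------------------------------------------------------------
# 1-D prototypes
# ---------------------------------------------------------------------------


def lagrange_halfband_lowpass() -> Filter1D:
    """7-tap half-band Lagrange maximally flat lowpass, DC gain 2.

    Taps (lags -3..3): {-1/16, 0, 9/16, 1, 9/16, 0, -1/16}.
    """
    s = Fraction(1, 16)
    taps = (-s, Fraction(0), 9 * s, Fraction(1), 9 * s, Fraction(0), -s)
    return Filter1D(taps=taps, center=3)


def modulate_to_highpass(f: Filter1D) -> Filter1D:
    """High-pass by modulation: tap[n] -> (-1)^n tap[n], n from the centre.

    Equivalent to evaluating the transfer function at -z, which mirrors the
    response about omega = pi/2.
    """
    taps = tuple(
        t if (n - f.center) % 2 == 0 else -t for n, t in enumerate(f.taps)
    )
    return Filter1D(taps=taps, center=f.center)


def smoothing_lowpass() -> Filter1D:
    """The 3-tap binomial smoother h_c[n] = {1, 2, 1}."""
    return Filter1D(taps=(Fraction(1), Fraction(2), Fraction(1)), center=1)


def smooth_bandpass(f_hp: Filter1D, f_c: Filter1D) -> Filter1D:
    """Full linear convolution of two centred filters (exact rationals)."""
    a, b = f_hp.taps, f_c.taps
    out = [Fraction(0)] * (len(a) + len(b) - 1)
    for i, ai in enumerate(a):
        for j, bj in enumerate(b):
            out[i + j] += ai * bj
    return Filter1D(taps=tuple(out), center=len(out) // 2)


def bandpass_prototype() -> Filter1D:
    """The 9-tap band-pass edge prototype h_bp = h_c * h_hp."""
    return smooth_bandpass(
        modulate_to_highpass(lagrange_halfband_lowpass()), smoothing_lowpass()
    )


# ---------------------------------------------------------------------------
# Frequency responses
# ---------------------------------------------------------------------------


def frequency_response(
    f: Union[Filter1D, Kernel2D],
    omega: Union[float, Sequence[float]],
) -> FrequencyPoint:
    """Magnitude of the DTFT at ``omega``, by direct summation over taps.

    For a :class:`Kernel2D`, ``omega`` is ``(omega1, omega2)`` with omega1
    conjugate to the column index and omega2 to the row index.
    """
    if isinstance(f, Filter1D):
        (w,) = np.atleast_1d(omega).astype(float)
        if not -math.pi <= w <= math.pi:
            raise ValueError("frequency outside [-pi, pi]")
        h = sum(
            float(t) * cmath.exp(-1j * w * (n - f.center))
            for n, t in enumerate(f.taps)
        )
        return FrequencyPoint(omega=(w,), magnitude=abs(h))

    w1, w2 = (float(x) for x in np.atleast_1d(omega))
    for w in (w1, w2):
        if not -math.pi <= w <= math.pi:
            raise ValueError("frequency outside [-pi, pi]")
    rows, cols = f.weights.shape
    cr, cc = rows // 2, cols // 2
    h = 0j
    for r in range(rows):
        for c in range(cols):
            if f.weights[r, c] != 0.0:
                h += f.weights[r, c] * cmath.exp(
                    -1j * (w1 * (c - cc) + w2 * (r - cr))
                )
    return FrequencyPoint(omega=(w1, w2), magnitude=abs(h))


# ---------------------------------------------------------------------------
# 2-D directional kernels
# ---------------------------------------------------------------------------


def _canonical_angle(theta_deg: float) -> float:
    for a in DEFAULT_ANGLES_DEG:
        if abs(theta_deg - a) <= _ANGLE_TOL:
            return a
    raise ValueError(
        f"angle {theta_deg} not in the supported set {DEFAULT_ANGLES_DEG}"
    )


def _place_split(grid: list[list[Fraction]], c: int, row: Fraction, col: Fraction,
                 value: Fraction) -> None:
    """Place ``value`` at (row, col) offsets from centre, splitting any
    half-integer coordinate equally between the two nearest lattice rows
    (or columns)."""
    def cells(x: Fraction) -> list[tuple[int, Fraction]]:
        if x.denominator == 1:
            return [(int(x), Fraction(1))]
        lo = math.floor(x)
        return [(lo, Fraction(1, 2)), (lo + 1, Fraction(1, 2))]

    for r, wr in cells(row):
        for cl, wc in cells(col):
            grid[c + r][c + cl] += value * wr * wc


def build_directional_kernel(
    theta_deg: float, prototype: Filter1D | None = None
) -> Kernel2D:
    """Directional 2-D kernel at one of the eight supported orientations.

    0 deg lays the prototype along the centre row (detects vertical edges);
    90 deg is its transpose; +/-45 deg place taps on the diagonals; the
    slope-1/2 (+/-26.56 deg) and slope-2 (+/-63.43 deg) kernels use sparse
    digital-line placement with equal splitting at half-integer positions,
    so sums perpendicular to the line reproduce the prototype exactly.
    """
    angle = _canonical_angle(theta_deg)
    proto = prototype if prototype is not None else bandpass_prototype()
    m = proto.center
    size = len(proto)
    c = size // 2
    grid = [[Fraction(0)] * size for _ in range(size)]

    for k in range(-m, m + 1):
        v = proto.taps[m + k]
        if v == 0:
            continue
        kf = Fraction(k)
        if angle == 0.0:
            row, col = Fraction(0), kf
        elif angle == 90.0:
            row, col = kf, Fraction(0)
        elif angle == 45.0:
            row, col = kf, kf
        elif angle == -45.0:
            row, col = kf, -kf
        elif angle == 26.56:            # slope 1/2: tap index runs along columns
            row, col = kf / 2, kf
        elif angle == -26.56:
            row, col = -kf / 2, kf
        elif angle == 63.43:            # slope 2: tap index runs along rows
            row, col = kf, kf / 2
        else:                            # -63.43
            row, col = kf, -kf / 2
        _place_split(grid, c, row, col, v)

    weights = np.array([[float(x) for x in row] for row in grid])
    return Kernel2D(weights=weights, angle_deg=angle)


def build_bank(
    angles: Iterable[float] = DEFAULT_ANGLES_DEG,
    prototype: Filter1D | None = None,
    support: int = 9,
) -> DirectionalFilterBank:
    """Bank of directional kernels in the given angle order.

    ``support=9`` (default) rotates the 9-tap band-pass prototype; ``support=7``
    rotates the 7-tap high-pass instead, matching a 7x7 layer kernel while
    keeping the zero-DC property.
    """
    if prototype is None:
        if support == 9:
            prototype = bandpass_prototype()
        elif support == 7:
            prototype = modulate_to_highpass(lagrange_halfband_lowpass())
        else:
            raise ValueError("support must be 9 or 7")
    angles = tuple(_canonical_angle(a) for a in angles)
    if len(set(angles)) != len(angles):
        raise ValueError("duplicate angles")
    kernels = tuple(build_directional_kernel(a, prototype) for a in angles)
    return DirectionalFilterBank(kernels=kernels, angles_deg=angles)


def apply_bank(image: np.ndarray, bank: DirectionalFilterBank) -> np.ndarray:
    """Direct 2-D convolution of ``image`` with every kernel in the bank.

    Returns a stack of shape (n_kernels, H, W).  Boundaries are handled by
    symmetric (mirror) padding so that no artificial edges are injected.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("image must be 2-D grayscale")
    s = bank.support[0]
    if image.shape[0] < s or image.shape[1] < s:
        raise ValueError("image smaller than kernel support")
    out = np.empty((len(bank), *image.shape))
    for i, k in enumerate(bank.kernels):
        # ndimage.convolve flips the kernel (true convolution); mode="reflect"
        # is symmetric padding (edge sample repeated).
        out[i] = ndimage.convolve(image, k.weights, mode="reflect")
    return out
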