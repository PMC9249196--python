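"""Shared fixtures: the default filter bank and small synthetic data sets."""

from __future__ import annotations

import numpy as np
import pytest

from cvmstage.filters import build_bank
from cvmstage.preprocess import crop_and_resize
from cvmstage.synth import generate_dataset


@pytest.fixture(scope="session")
def bank():
    return build_bank()


@pytest.fixture(scope="session")
def small_dataset():
    """36 synthetic radiographs, six per stage."""
    return generate_dataset(6, seed=7)


@pytest.fixture(scope="session")
def small_crops(small_dataset):
    """77x35 crops (via true boxes) and their 6-stage labels."""
    x = np.stack([crop_and_resize(s.pixels, s.true_box) for s in small_dataset])
    y = np.array([s.label for s in small_dataset])
    return x.astype(np.float32), y


def conv2d_bruteforce(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Independent direct-convolution oracle: nested loops over taps with
    symmetric boundary padding (true convolution, kernel flipped)."""
    kh, kw = kernel.shape
    ph, pw = kh // 2, kw // 2
    padded = np.pad(img, ((ph, ph), (pw, pw)), mode="symmetric")
    out = np.zeros(img.shape, dtype=float)
    for r in range(img.shape[0]):
        for c in range(img.shape[1]):
            acc = 0.0
            for i in range(kh):
                for j in range(kw):
                    acc += kernel[i, j] * padded[r + kh - 1 - i, c + kw - 1 - j]
            out[r, c] = acc
    return out
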