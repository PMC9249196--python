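"""CSV manifest I/O: path, label, optional crop box (x, y, w, h) per image."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .preprocess import LabeledImage, crop_and_resize
from .roi_types import RoiBox

__all__ = ["read_manifest", "load_image", "load_rois"]


def read_manifest(path: Union[str, Path]) -> pd.DataFrame:
    """Read a manifest CSV; ``path`` and ``label`` are required columns."""
    df = pd.read_csv(path)
    missing = {"path", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest is missing columns: {sorted(missing)}")
    return df


def load_image(manifest_dir: Union[str, Path], rel_path: str) -> np.ndarray:
    """Load a grayscale image as float in [0, 1]."""
    arr = iio.imread(Path(manifest_dir) / rel_path)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    arr = arr.astype(np.float64)
    if arr.max() > 1.0:
        arr /= 255.0
    return np.clip(arr, 0.0, 1.0)


def load_rois(
    manifest: pd.DataFrame,
    manifest_dir: Union[str, Path],
    detector=None,
) -> list[LabeledImage]:
    """Materialise 77x35 labelled crops for every manifest row.

    The crop box comes from the detector when one is given; rows the detector
    misses (and all rows when ``detector`` is None) fall back to the manual
    crop columns x, y, w, h.  Rows with neither are an error.
    """
    from .roi import detect_roi  # local import to keep module load light

    out: list[LabeledImage] = []
    has_cols = {"x", "y", "w", "h"} <= set(manifest.columns)
    for _, row in manifest.iterrows():
        img = load_image(manifest_dir, row["path"])
        box = None
        if detector is not None:
            box = detect_roi(img, detector)
        if box is None:
            if not has_cols or pd.isna(row.get("x")):
                raise ValueError(f"no detection and no manual crop for {row['path']}")
            box = RoiBox(x=int(row["x"]), y=int(row["y"]),
                         width=int(row["w"]), height=int(row["h"]))
        out.append(LabeledImage(pixels=crop_and_resize(img, box),
                                label=int(row["label"]),
                                source_id=str(row["path"])))
    return out
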