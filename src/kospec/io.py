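"""Image and table IO.

Internally everything is float; images on disk are 16-bit grayscale TIFF
with an explicit, documented intensity scaling: ``pixel = round(value *
65535 / white_level)`` with the chosen white level stored in the TIFF
description so reading is lossless up to quantization.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

DEFAULT_WHITE_LEVEL = 400.0


def write_image16(
    path: str | Path, image: np.ndarray, white_level: float = DEFAULT_WHITE_LEVEL
) -> None:
    """Write a float image as scaled 16-bit grayscale TIFF.

    Values are clipped to [0, white_level]; the scaling is recorded in the
    image description.
    """
    img = np.clip(np.asarray(image, dtype=float), 0.0, white_level)
    data = np.round(img * (65535.0 / white_level)).astype(np.uint16)
    tifffile.imwrite(
        str(path), data,
        description=json.dumps({"white_level": white_level, "format": "kospec-u16"}),
    )


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale TIFF/PNG back to float.

    TIFFs written by :func:`write_image16` are rescaled to their original
    intensity units; anything else is returned as plain float values.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(str(path)) as tf:
            page = tf.pages[0]
            data = page.asarray().astype(float)
            desc = page.description or ""
        try:
            meta = json.loads(desc)
            if meta.get("format") == "kospec-u16":
                return data * (float(meta["white_level"]) / 65535.0)
        except (json.JSONDecodeError, KeyError, TypeError):
            pass
        return data
    import imageio.v3 as iio

    data = iio.imread(str(path)).astype(float)
    if data.ndim == 3:  # collapse RGB(A) to grayscale
        data = data[..., :3].mean(axis=-1)
    return data


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a boolean mask as 8-bit TIFF (0/255)."""
    tifffile.imwrite(str(path), (np.asarray(mask, dtype=bool) * 255).astype(np.uint8))


def read_mask(path: str | Path) -> np.ndarray:
    """Read a mask image back to boolean (nonzero = inside)."""
    return np.asarray(tifffile.imread(str(path))) > 0
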