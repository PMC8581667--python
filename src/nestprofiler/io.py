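"""Reading and writing the pipeline's file formats.

Marker stacks are multichannel TIFFs (one page per marker, the marker name
in the page description) or per-marker grayscale PNGs; masks are 8-bit
PNGs (0/255); cell and cohort tables are headed CSVs; specs and configs
are YAML; run metadata is JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from .segmentation import BinaryMask, GrayImage
from .simulate import MarkerImageStack

__all__ = [
    "write_stack_tiff",
    "read_stack_tiff",
    "write_mask_png",
    "read_mask_png",
    "write_gray_png",
    "read_gray_image",
    "write_yaml",
    "read_yaml",
    "write_json",
    "read_json",
]


def write_stack_tiff(stack: MarkerImageStack, path) -> Path:
    path = Path(path)
    with tifffile.TiffWriter(path) as tif:
        for name, channel in stack.channels.items():
            tif.write(
                np.asarray(channel, np.uint8),
                description=name,
                metadata=None,
                resolution=(10000.0 / stack.pixel_size_um,) * 2,  # px per cm
            )
    return path


def read_stack_tiff(path, pixel_size_um: float) -> MarkerImageStack:
    channels: dict[str, np.ndarray] = {}
    with tifffile.TiffFile(path) as tif:
        for i, page in enumerate(tif.pages):
            name = (page.description or f"channel_{i}").strip()
            channels[name] = page.asarray()
    return MarkerImageStack(channels, pixel_size_um)


def write_mask_png(mask: BinaryMask, path) -> Path:
    path = Path(path)
    iio.imwrite(path, (mask.pixels.astype(np.uint8) * 255))
    return path


def read_mask_png(path, pixel_size_um: float) -> BinaryMask:
    return BinaryMask(iio.imread(path) > 127, pixel_size_um)


def write_gray_png(image: GrayImage, path) -> Path:
    path = Path(path)
    iio.imwrite(path, np.clip(np.rint(image.pixels), 0, 255).astype(np.uint8))
    return path


def read_gray_image(path, pixel_size_um: float) -> GrayImage:
    arr = iio.imread(path)
    if arr.ndim == 3:  # RGB(A) -> luminance
        arr = arr[..., :3].mean(axis=-1)
    return GrayImage(arr.astype(float), pixel_size_um)


def write_yaml(data, path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(data, sort_keys=True))
    return path


def read_yaml(path):
    return yaml.safe_load(Path(path).read_text())


def write_json(data, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(data, indent=2, sort_keys=True, default=_jsonable))
    return path


def read_json(path):
    return json.loads(Path(path).read_text())


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)!r}")
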