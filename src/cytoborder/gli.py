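"""Gray level index (GLI) mapping.

The GLI estimates the volume fraction of cell bodies: a stained section is
binarized (cells are dark on a light background) and the foreground
fraction is counted in non-overlapping square measuring fields (default
16 x 16 px), yielding a coarse raster that all laminar profiles sample
from.  GLI values are stored as fractions in [0, 1], never percent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

__all__ = ["BinaryImage", "GLIMap", "segment_cell_bodies", "compute_gli", "gli_map_from_image"]


@dataclass
class BinaryImage:
    """Cell-body mask (True = cell body) with segmentation provenance."""

    pixels: np.ndarray
    pixel_size_um: float
    method: str
    threshold: float


@dataclass
class GLIMap:
    """2D grid of cell-body volume fractions, one value per measuring field.

    Field (i, j) covers image pixels ``[i*f:(i+1)*f, j*f:(j+1)*f)``;
    trailing partial fields are discarded.  The centre of field (i, j) in
    micrometres is ``((j+0.5)*f*px, (i+0.5)*f*px)`` (x, y).
    """

    values: np.ndarray
    field_size_px: int
    pixel_size_um: float

    @property
    def field_size_um(self) -> float:
        return self.field_size_px * self.pixel_size_um

    def cell_coords_from_um(self, xy_um: np.ndarray) -> np.ndarray:
        """Fractional (row, col) GLI-grid coordinates of points given in um."""
        xy = np.asarray(xy_um, float)
        f = self.field_size_um
        col = xy[..., 0] / f - 0.5
        row = xy[..., 1] / f - 0.5
        return np.stack([row, col], axis=-1)


def _validate_image(image: np.ndarray):
    image = np.asarray(image)
    if image.ndim != 2 or min(image.shape) < 16:
        raise ValueError("image must be 2D and at least 16 x 16 px")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    return image


def segment_cell_bodies(image: np.ndarray, pixel_size_um: float = 1.02,
                        method: str = "otsu", threshold: float | None = None) -> BinaryImage:
    """Binarize a stained section; foreground = pixels darker than threshold."""
    image = _validate_image(image)
    if method == "otsu":
        thr = float(threshold_otsu(image))
    elif method == "fixed":
        if threshold is None:
            raise ValueError("method='fixed' requires an explicit threshold")
        thr = float(threshold)
    else:
        raise ValueError(f"unknown segmentation method {method!r}")
    return BinaryImage(pixels=image < thr, pixel_size_um=pixel_size_um,
                       method=method, threshold=thr)


def compute_gli(binary: BinaryImage | np.ndarray, field_size_px: int = 16,
                pixel_size_um: float | None = None) -> GLIMap:
    """Foreground fraction per non-overlapping ``field_size_px`` square field."""
    if field_size_px < 1:
        raise ValueError("field_size_px must be >= 1")
    if isinstance(binary, BinaryImage):
        pixels, px = binary.pixels, binary.pixel_size_um
    else:
        pixels = np.asarray(binary, bool)
        px = 1.02 if pixel_size_um is None else pixel_size_um
    h, w = pixels.shape
    nh, nw = h // field_size_px, w // field_size_px
    if nh < 1 or nw < 1:
        raise ValueError("image smaller than one measuring field")
    trimmed = pixels[: nh * field_size_px, : nw * field_size_px]
    counts = trimmed.reshape(nh, field_size_px, nw, field_size_px).sum(axis=(1, 3))
    return GLIMap(values=counts / field_size_px**2, field_size_px=field_size_px,
                  pixel_size_um=px)


def gli_map_from_image(image: np.ndarray, pixel_size_um: float = 1.02,
                       field_size_px: int = 16, method: str = "otsu",
                       threshold: float | None = None) -> GLIMap:
    """Convenience: segmentation followed by GLI counting."""
    binary = segment_cell_bodies(image, pixel_size_um, method=method, threshold=threshold)
    return compute_gli(binary, field_size_px)
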