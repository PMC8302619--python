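"""Shared data model, calibrated image I/O, masks and small statistical utilities.

Conventions used throughout the package
---------------------------------------
* Image stacks are ``(T, Y, X)`` arrays; single frames are ``(Y, X)``.
* Coordinates are 0-based; ``x`` is the column index, ``y`` the row index.
* A pixel's centre sits at its integer index, so the physical position of a
  pixel is ``index * pixel_size_nm`` (nanometres).
* Fluorescence is in arbitrary camera units (FU).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import tifffile
from scipy import ndimage


@dataclass
class ImageStack:
    """Calibrated T×Y×X fluorescence stack.

    Parameters
    ----------
    data:
        Intensity array, ``(T, Y, X)``.  2-D input is promoted to a single
        frame.
    pixel_size_nm:
        Physical width of one pixel in nanometres.
    frame_interval_s:
        Time between frames in seconds; ``None`` for single snapshots.
    channel_label:
        Free-text channel identifier.
    """

    data: np.ndarray
    pixel_size_nm: float
    frame_interval_s: float | None = None
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[None, :, :]
        if self.data.ndim != 3:
            raise ValueError(f"expected 2-D or 3-D data, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError("empty image stack")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite intensities")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")
        if self.frame_interval_s is not None and self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def frame(self, t: int) -> np.ndarray:
        return self.data[t]


@dataclass
class CellMask:
    """Binary Y×X region-of-interest mask with pixel calibration."""

    mask: np.ndarray
    pixel_size_nm: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not self.mask.any():
            raise ValueError("mask has no true pixels")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    @property
    def area_um2(self) -> float:
        return self.n_pixels * (self.pixel_size_nm / 1000.0) ** 2


@dataclass
class RegionPartition:
    """Peripheral/central split of a cell mask.

    ``peripheral`` is the annulus of mask pixels within ``annulus_depth_px``
    (Euclidean distance) of the mask boundary; ``central`` is the remainder.
    The two regions are disjoint and their union is the cell mask.
    """

    peripheral: np.ndarray
    central: np.ndarray
    annulus_depth_px: int


def read_stack(
    path,
    pixel_size_nm: float,
    frame_interval_s: float | None = None,
    channel_label: str = "",
) -> ImageStack:
    """Read a single- or multi-page grayscale TIFF as a calibrated stack.

    Page order is taken as frame order.  Multi-sample (e.g. RGB) pages are
    rejected: every analysis in this package is single-channel per file.
    """
    with tifffile.TiffFile(str(path)) as tif:
        if any(page.samplesperpixel > 1 for page in tif.pages):
            raise ValueError("multi-sample pages unsupported")
        data = tif.asarray()
    if not np.issubdtype(data.dtype, np.number):
        raise ValueError("non-numeric pixel data")
    return ImageStack(data, pixel_size_nm, frame_interval_s, channel_label)


def write_stack(stack: ImageStack, path) -> None:
    """Write a stack as a multi-page TIFF (dtype preserved)."""
    tifffile.imwrite(str(path), stack.data, photometric="minisblack")


def read_mask(path, pixel_size_nm: float) -> CellMask:
    """Read a binary mask TIFF (any non-zero pixel is inside)."""
    data = tifffile.imread(str(path))
    if data.ndim == 3:
        data = data[0]
    return CellMask(data != 0, pixel_size_nm)


def write_mask(mask: CellMask, path) -> None:
    tifffile.imwrite(str(path), mask.mask.astype(np.uint8), photometric="minisblack")


def background_correct(stack: ImageStack, bg_region: CellMask) -> ImageStack:
    """Subtract, frame by frame, the mean intensity of a region outside the cell.

    The mean of ``bg_region`` is computed per frame and subtracted from the
    whole frame; negative results are clamped to zero so that downstream
    segmentation sees non-negative intensities.
    """
    if stack.data.shape[1:] != bg_region.mask.shape:
        raise ValueError("background mask shape does not match stack frames")
    data = stack.data.astype(np.float64, copy=True)
    bg_means = data[:, bg_region.mask].mean(axis=1)
    data -= bg_means[:, None, None]
    np.clip(data, 0.0, None, out=data)
    return replace(stack, data=data)


def partition_regions(mask: CellMask, annulus_depth_px: int = 15) -> RegionPartition:
    """Split a cell mask into a peripheral annulus and a central core.

    The peripheral region is the set of mask pixels whose Euclidean distance
    to the nearest outside pixel is at most ``annulus_depth_px`` (default 15,
    i.e. 2.4 µm at 160 nm pixels); the central region is the rest.
    """
    if annulus_depth_px < 1:
        raise ValueError("annulus_depth_px must be >= 1")
    dist = ndimage.distance_transform_edt(mask.mask)
    peripheral = mask.mask & (dist <= annulus_depth_px)
    central = mask.mask & (dist > annulus_depth_px)
    return RegionPartition(peripheral, central, annulus_depth_px)


def variance_of_product(mean_x: float, var_x: float, mean_y: float, var_y: float) -> float:
    """Variance of the product of two independent random variables.

    Var(XY) = Var(X)Var(Y) + Var(X)E[Y]^2 + Var(Y)E[X]^2 for independent X, Y.
    """
    if var_x < 0 or var_y < 0:
        raise ValueError("variances must be >= 0")
    return var_x * var_y + var_x * mean_y**2 + var_y * mean_x**2
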