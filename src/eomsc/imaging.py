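"""Shared image I/O and segmentation primitives.

All quantification in this package runs on 2D maximum-intensity projections
of multichannel confocal z-stacks, mirroring the whole-mount imaging workflow
the pipeline reproduces.  A stack is a named-channel ``(z, c, y, x)`` volume
with a physical pixel size; projections, masks and labelled regions carry
coordinates in micrometres with the origin at the top-left pixel centre,
axis order ``(y, x)``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
from skimage.filters import threshold_otsu
from skimage.measure import label as _sk_label
from skimage.measure import regionprops

logger = logging.getLogger(__name__)

__all__ = [
    "MultiChannelStack",
    "LabeledRegions",
    "read_stack",
    "write_stack",
    "max_project",
    "binarize",
    "label_regions",
]


class ChannelNotFoundError(KeyError):
    """Requested channel name is absent from a stack."""


@dataclass
class MultiChannelStack:
    """Named-channel 3D intensity volume with a physical pixel size.

    Parameters
    ----------
    voxels
        Intensity array indexed ``(z, channel, y, x)``; non-negative.
    channel_names
        Ordered unique channel labels, one per channel axis entry.
    pixel_size
        Micrometres per pixel, isotropic in y and x.
    """

    voxels: np.ndarray
    channel_names: list[str]
    pixel_size: float

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4:
            raise ValueError(f"voxels must be (z, c, y, x); got shape {self.voxels.shape}")
        if len(self.channel_names) != self.voxels.shape[1]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {self.voxels.shape[1]} channels"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError(f"channel names must be unique: {self.channel_names}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.voxels.size and self.voxels.min() < 0:
            raise ValueError("intensities must be >= 0")

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise ChannelNotFoundError(
                f"channel {name!r} not in stack; available: {self.channel_names}"
            ) from None

    def channel(self, name: str) -> np.ndarray:
        """Return the ``(z, y, x)`` volume of one named channel."""
        return self.voxels[:, self.channel_index(name)]

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        z, _, y, x = self.voxels.shape
        return z, y, x


@dataclass
class LabeledRegions:
    """Connected regions of a 2D mask with areas and centroids in µm.

    ``labels`` is an integer image (0 = background, regions numbered
    contiguously from 1); ``table`` has one row per region with columns
    ``id, area_px, area_um2, centroid_y_um, centroid_x_um``.
    """

    labels: np.ndarray
    pixel_size: float
    table: pd.DataFrame = field(repr=False)

    def __len__(self) -> int:
        return len(self.table)

    def region_mask(self, region_id: int) -> np.ndarray:
        return self.labels == region_id

    def centroids_um(self) -> np.ndarray:
        """(n, 2) array of region centroids, rows ``(y_um, x_um)``."""
        return self.table[["centroid_y_um", "centroid_x_um"]].to_numpy()


def write_stack(stack: MultiChannelStack, path) -> None:
    """Write a stack as a multi-page TIFF, one page per (z, channel) plane.

    Channel order and pixel size travel in the ImageDescription JSON so the
    file round-trips through :func:`read_stack` without sidecars.
    """
    meta = {
        "axes": "ZCYX",
        "channel_names": list(stack.channel_names),
        "pixel_size_um": float(stack.pixel_size),
    }
    tifffile.imwrite(path, stack.voxels, metadata=meta)


def read_stack(path, channel_map: dict[str, int] | None = None) -> MultiChannelStack:
    """Read a multi-page TIFF into a :class:`MultiChannelStack`.

    Files written by :func:`write_stack` carry their channel names and pixel
    size in metadata.  For foreign TIFFs pass ``channel_map`` assigning a name
    to every channel index (``{"BTX": 0, ...}``); the pixel size then defaults
    to 1 µm unless present in metadata.
    """
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    if arr.ndim == 3:  # single-channel z-stack
        arr = arr[:, None]
    if arr.ndim != 4:
        raise ValueError(f"cannot interpret TIFF of shape {arr.shape} as (z, c, y, x)")
    n_channels = arr.shape[1]
    pixel_size = float(meta.get("pixel_size_um", 1.0))
    if channel_map is not None:
        missing = set(range(n_channels)) - set(channel_map.values())
        if missing:
            raise ValueError(f"channel_map assigns no name to channel indices {sorted(missing)}")
        names = [None] * n_channels
        for name, idx in channel_map.items():
            if not 0 <= idx < n_channels:
                raise ValueError(f"channel_map index {idx} out of range for {n_channels} channels")
            names[idx] = name
    elif "channel_names" in meta:
        names = list(meta["channel_names"])
    else:
        names = [f"ch{i}" for i in range(n_channels)]
    return MultiChannelStack(voxels=arr, channel_names=names, pixel_size=pixel_size)


def max_project(stack: MultiChannelStack, channel: str) -> np.ndarray:
    """Maximum-intensity projection of one channel along z -> 2D image."""
    vol = stack.channel(channel)
    if vol.shape[0] == 0:
        raise ValueError("cannot project a stack with an empty z-dimension")
    return vol.max(axis=0)


#: When the Otsu threshold lands in the lowest quarter of the intensity
#: range, the foreground class is so sparse that the split fell inside the
#: background noise; re-thresholding the tentative foreground recovers it.
_OTSU_GUARD_FRACTION = 0.25
_OTSU_MAX_PASSES = 4


def binarize(image: np.ndarray, method: str = "otsu", threshold: float | None = None) -> np.ndarray:
    """Threshold a 2D image to a boolean mask (True where intensity > threshold).

    ``method="otsu"`` picks the threshold by Otsu's criterion.  Plain Otsu
    fails on images whose foreground occupies a tiny pixel fraction (the
    split falls inside the background noise), so while the threshold sits in
    the lowest quarter of the intensity range Otsu is re-applied to the
    tentative foreground — a guard that is invariant to positive affine
    intensity maps.  A constant image has no Otsu threshold and yields an
    all-False mask with a logged warning.  ``method="fixed"`` requires
    ``threshold``.
    """
    image = np.asarray(image)
    if method == "fixed":
        if threshold is None:
            raise ValueError("fixed thresholding requires a threshold value")
        thr = threshold
    elif method == "otsu":
        if image.size == 0 or image.min() == image.max():
            logger.warning("otsu thresholding on a constant image; returning all-false mask")
            return np.zeros(image.shape, dtype=bool)
        mn, mx = float(image.min()), float(image.max())
        thr = threshold_otsu(image)
        for _ in range(_OTSU_MAX_PASSES):
            if thr - mn >= _OTSU_GUARD_FRACTION * (mx - mn):
                break
            fg = image[image > thr]
            if fg.size == 0 or fg.min() == fg.max():
                break
            thr = threshold_otsu(fg)
    else:
        raise ValueError(f"unknown binarization method {method!r}; use 'otsu' or 'fixed'")
    return image > thr


def label_regions(
    mask: np.ndarray,
    pixel_size: float,
    min_area_um2: float = 0.0,
    connectivity: int = 8,
) -> LabeledRegions:
    """Connected components of a boolean mask, filtered by physical area.

    ``connectivity`` is 4 (edge neighbours) or 8 (edge + diagonal, the ImageJ
    particle-analysis default).  Components with area < ``min_area_um2`` are
    dropped and survivors relabelled contiguously from 1 in scan order.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    mask = np.asarray(mask, dtype=bool)
    raw = _sk_label(mask, connectivity=1 if connectivity == 4 else 2)
    px_area = pixel_size**2
    rows = []
    relabeled = np.zeros_like(raw)
    next_id = 1
    for prop in regionprops(raw):
        area_um2 = prop.area * px_area
        if area_um2 < min_area_um2:
            continue
        relabeled[raw == prop.label] = next_id
        cy, cx = prop.centroid
        rows.append(
            {
                "id": next_id,
                "area_px": int(prop.area),
                "area_um2": area_um2,
                "centroid_y_um": cy * pixel_size,
                "centroid_x_um": cx * pixel_size,
            }
        )
        next_id += 1
    table = pd.DataFrame(
        rows, columns=["id", "area_px", "area_um2", "centroid_y_um", "centroid_x_um"]
    )
    return LabeledRegions(labels=relabeled, pixel_size=pixel_size, table=table)
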