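"""Oil Red O lipid-stain quantification from worm micrographs.

The stain signal of a pixel is its red-channel intensity in excess of the
blue channel, clipped at zero (blue > red carries no lipid signal). A
worm's lipid index is the summed excess over stained pixels (excess above
a threshold) divided by the worm's pixel area, and group reports rescale
each worm's index by the control-group mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label

from .data_model import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class WormImage:
    """Three-channel raster in [0, 1] plus a boolean worm mask."""

    pixels: np.ndarray  # H x W x 3 float
    worm_mask: np.ndarray  # H x W bool

    def __post_init__(self) -> None:
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValidationError("pixels must be an H x W x 3 array")
        if self.worm_mask.shape != self.pixels.shape[:2]:
            raise ValidationError("mask shape must equal image shape")
        if not self.worm_mask.any():
            raise ValidationError("worm mask is empty")


@dataclass
class OroMeasurement:
    worm_id: str
    worm_area: int
    stained_area: int
    total_excess: float
    lipid_index: float
    group: str | None = None
    relative_index: float | None = None


def _to_unit_float(arr: np.ndarray) -> np.ndarray:
    """Rescale 8/16-bit integer images to [0, 1]; floats pass through."""
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        return arr.astype(float) / info.max
    return np.clip(arr.astype(float), 0.0, 1.0)


def load_worm_image(path, mask_path=None) -> WormImage:
    """Load a PNG/TIFF micrograph, segmenting the worm unless a mask file
    (nonzero = worm) is supplied."""
    raw = iio.imread(path)
    if raw.ndim == 3 and raw.shape[2] >= 3:
        raw = raw[:, :, :3]
    else:
        raise ValidationError(f"{path} is not a three-channel color image")
    pixels = _to_unit_float(raw)
    if mask_path is not None:
        m = iio.imread(mask_path)
        if m.ndim == 3:
            m = m[:, :, 0]
        mask = m > 0
    else:
        mask = segment_worm(pixels)
    return WormImage(pixels, mask)


def segment_worm(pixels: np.ndarray, min_area: int = 100) -> np.ndarray:
    """Dark-object segmentation: Otsu threshold on inverted luminance,
    largest connected component, holes filled."""
    pixels = _to_unit_float(pixels)
    lum = pixels.mean(axis=2)
    inv = 1.0 - lum
    if np.ptp(inv) < 1e-6:
        raise ValidationError(
            "image has no contrast; supply an explicit worm mask"
        )
    mask = inv > threshold_otsu(inv)
    lab = label(mask)
    if lab.max() == 0:
        raise ValidationError("segmentation found no object; supply an explicit mask")
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    mask = lab == sizes.argmax()
    mask = ndimage.binary_fill_holes(mask)
    if mask.sum() < min_area:
        raise ValidationError(
            f"segmented object has {int(mask.sum())} px (< {min_area}); "
            "supply an explicit worm mask"
        )
    return mask


def stain_excess(image: WormImage) -> np.ndarray:
    """Per-pixel max(red - blue, 0), zeroed outside the worm mask."""
    excess = np.maximum(image.pixels[:, :, 0] - image.pixels[:, :, 2], 0.0)
    return np.where(image.worm_mask, excess, 0.0)


def quantify_oro(
    image: WormImage, stain_threshold: float = 0.05, worm_id: str = "worm"
) -> OroMeasurement:
    """Lipid index of one worm: summed stain excess over stained pixels
    (excess > threshold, inside the worm) divided by worm area."""
    if not (0.0 <= stain_threshold < 1.0):
        raise ValidationError("stain_threshold must be in [0, 1)")
    excess = stain_excess(image)
    stained = image.worm_mask & (excess > stain_threshold)
    worm_area = int(image.worm_mask.sum())
    total = float(excess[stained].sum())
    return OroMeasurement(
        worm_id=worm_id,
        worm_area=worm_area,
        stained_area=int(stained.sum()),
        total_excess=total,
        lipid_index=total / worm_area,
    )


def relative_oro(
    measurements: list[OroMeasurement],
    groups: list[str],
    control_group: str,
) -> pd.DataFrame:
    """Group report of lipid indices relative to the control-group mean.

    Returns one row per group with n, mean and SD of the relative index;
    the control group's mean relative index is 1 by construction. Each
    measurement's ``relative_index`` and ``group`` fields are filled in.
    """
    if len(measurements) != len(groups):
        raise ValidationError("one group label per measurement required")
    if control_group not in set(groups):
        raise ValidationError(f"unknown control group {control_group!r}")
    idx = np.array([m.lipid_index for m in measurements])
    grp = np.array(groups)
    control_mean = idx[grp == control_group].mean()
    if control_mean == 0:
        raise ValidationError("control group has zero mean lipid index")
    rel = idx / control_mean
    for m, g, r in zip(measurements, groups, rel):
        m.group = g
        m.relative_index = float(r)
    rows = []
    for g in dict.fromkeys(groups):  # stable first-seen order
        sel = rel[grp == g]
        rows.append((g, len(sel), float(sel.mean()),
                     float(sel.std(ddof=1)) if len(sel) > 1 else 0.0))
    return pd.DataFrame(rows, columns=["group", "n", "mean_relative_index", "sd"])


def measurements_frame(measurements: list[OroMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (m.worm_id, m.group, m.worm_area, m.stained_area, m.total_excess,
             m.lipid_index, m.relative_index)
            for m in measurements
        ],
        columns=["worm_id", "group", "worm_area", "stained_area", "total_excess",
                 "lipid_index", "relative_index"],
    )
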