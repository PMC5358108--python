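"""Aggregate segmentation from the DAPI channel.

Two routes, mirroring common practice for organoid sections:

* automatic — Chan-Vese active contour (morphological ACWE) started
  from a central disk, followed by morphological clean-up (largest
  component, hole filling, opening);
* manual — load a user-drawn binary mask, which lets the user exclude
  easily recognised artefacts such as dead cells stuck to the outside
  of the aggregate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.morphology import disk
from skimage.segmentation import morphological_chan_vese

from .containers import AggregateMask


@dataclass
class SegmentationParams:
    """Tunables for the automatic route.

    ``init_shape`` is the area fraction of the frame covered by the
    initial disk level set.  ``presmooth_sigma`` blurs the DAPI image
    before contour evolution so that individual nuclei merge into one
    region; set to 0 to disable.
    """

    chanvese_iterations: int = 200
    chanvese_smoothing: int = 2
    init_shape: float = 0.25
    opening_radius: int = 2
    min_area: int = 64
    presmooth_sigma: float = 2.0

    def __post_init__(self) -> None:
        if self.chanvese_iterations < 1:
            raise ValueError("need at least one Chan-Vese iteration")
        if min(self.chanvese_smoothing, self.init_shape, self.opening_radius,
               self.min_area, self.presmooth_sigma) < 0:
            raise ValueError("segmentation parameters must be nonnegative")


def _disk_level_set(shape: tuple[int, int], area_fraction: float) -> np.ndarray:
    """Centred disk covering the given fraction of the frame area."""
    h, w = shape
    radius = np.sqrt(area_fraction * h * w / np.pi)
    yy, xx = np.mgrid[0:h, 0:w]
    return (np.hypot(yy - (h - 1) / 2.0, xx - (w - 1) / 2.0) <= radius).astype(np.int8)


def _cleanup(mask: np.ndarray, opening_radius: int) -> np.ndarray:
    """Largest component -> fill holes -> opening, re-asserting the
    single-component/no-hole invariant after the opening."""
    labels, ncomp = ndimage.label(mask)
    if ncomp == 0:
        return mask
    if ncomp > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, ncomp + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    mask = ndimage.binary_fill_holes(mask)
    if opening_radius > 0:
        mask = ndimage.binary_opening(mask, structure=disk(opening_radius))
        # opening can split thin necks; restore the invariant
        labels, ncomp = ndimage.label(mask)
        if ncomp > 1:
            sizes = ndimage.sum_labels(
                np.ones_like(labels), labels, np.arange(1, ncomp + 1)
            )
            mask = labels == (1 + int(np.argmax(sizes)))
        mask = ndimage.binary_fill_holes(mask)
    return mask


def segment_aggregate(
    dapi: np.ndarray, params: SegmentationParams | None = None
) -> AggregateMask:
    """Segment the aggregate footprint from a DAPI section.

    The two-phase Chan-Vese evolution partitions the frame by mean
    intensity; the phase whose mean DAPI intensity is higher is taken
    as foreground, so the result is orientation-independent.

    Raises
    ------
    ValueError
        If the input is non-finite, too small, or no region of at
        least ``min_area`` pixels is found ("no aggregate found").
    """
    params = params or SegmentationParams()
    img = np.asarray(dapi, dtype=float)
    if img.ndim != 2 or min(img.shape) < 32:
        raise ValueError("DAPI image must be 2D and at least 32x32")
    if not np.all(np.isfinite(img)):
        raise ValueError("DAPI image contains non-finite values")
    if img.min() < 0:
        raise ValueError("DAPI image contains negative intensities")
    if np.ptp(img) == 0:
        raise ValueError("no aggregate found: image is constant")

    work = img
    if params.presmooth_sigma > 0:
        work = ndimage.gaussian_filter(img, params.presmooth_sigma)

    # evolve in chunks and stop once the level set is stationary, up to
    # the configured iteration budget
    level = _disk_level_set(work.shape, params.init_shape)
    chunk = 20
    done = 0
    while done < params.chanvese_iterations:
        n_iter = min(chunk, params.chanvese_iterations - done)
        new = morphological_chan_vese(
            work,
            num_iter=n_iter,
            init_level_set=level,
            smoothing=params.chanvese_smoothing,
        ).astype(np.int8)
        done += n_iter
        if np.array_equal(new, level):
            break
        level = new
    seg = level.astype(bool)

    # choose the phase with the brighter DAPI mean
    if seg.any() and (~seg).any():
        if img[seg].mean() < img[~seg].mean():
            seg = ~seg
    elif not seg.any():
        seg = ~seg

    mask = _cleanup(seg, params.opening_radius)
    if mask.sum() < params.min_area:
        raise ValueError("no aggregate found")
    out = AggregateMask(mask=mask, provenance="auto")
    out.validate()
    return out


def load_mask(path: str | Path, expected_dims: tuple[int, int]) -> AggregateMask:
    """Load a user-supplied binary mask (PNG or TIFF).

    The image is thresholded at half its maximum, the largest
    component is kept and holes are filled; the result carries
    ``provenance="manual"``.

    Raises
    ------
    ValueError
        If the dimensions differ from ``expected_dims`` or the image
        has more than two distinct values (probably not a mask).
    """
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(Path(path)))
    if arr.ndim == 3:  # collapse grey RGB / drop alpha
        arr = arr[..., 0]
    if arr.shape != tuple(expected_dims):
        raise ValueError(
            f"mask dimensions {arr.shape} do not match image {tuple(expected_dims)}"
        )
    values = np.unique(arr)
    if values.size > 2:
        raise ValueError(
            f"image has {values.size} distinct values; expected a binary mask"
        )
    mask = arr > arr.max() / 2.0
    mask = _cleanup(mask, opening_radius=0)
    if not mask.any():
        raise ValueError("mask file contains no foreground")
    out = AggregateMask(mask=mask, provenance="manual")
    out.validate()
    return out
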