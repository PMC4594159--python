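"""Automated cell segmentation on the uniform cytoplasmic channel.

The workflow follows the classic wide-field cell-counting recipe: the z stack
is reshaped into a single m x (n*z) plane, a normalized threshold is derived
from the Otsu split of that plane, the plane is median-filtered, squared to
emphasize gradients, Canny edge detection is run with the normalized
threshold, and the edges are dilated (diamond radius 1), hole-filled, eroded
and cleaned with a 3x3 majority filter. Connected components of the restored
stack are then labelled; their number is the cell count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
from pydantic import BaseModel, ConfigDict, Field
from scipy.ndimage import (binary_dilation, binary_erosion, binary_fill_holes,
                           convolve, generate_binary_structure, median_filter)
from skimage.feature import canny
from skimage.measure import label as cc_label

from .containers import DegenerateHistogramError, ImageStack, LabelMask

logger = logging.getLogger(__name__)


class SegmentationParams(BaseModel):
    """Tunables of the segmentation workflow (defaults follow the reference recipe)."""

    model_config = ConfigDict(extra="forbid")

    median_size: int = Field(3, ge=1)
    canny_sigma: float = Field(1.0, gt=0)
    canny_low_ratio: float = Field(0.4, gt=0, le=1)
    # percentile used as the "image maximum" for threshold normalization and
    # rescaling; robust to the <0.1% of pixels occupied by bright foci on
    # channels that carry puncta (equals the true maximum on focus-free
    # channels; set to 100 for the literal maximum)
    max_percentile: float = Field(99.5, gt=0, le=100)
    connectivity: int = Field(2, ge=1, le=3)
    label_mode: str = Field("stack3d", pattern="^(stack3d|plane)$")
    # automated stand-in for manual curation of the mask: drop specks far
    # smaller than any credible cell footprint (a 0.8 um-wide rod covers
    # >300 px at 0.08 um/px)
    min_area_px: int = Field(50, ge=0)


def reshape_stack(stack: ImageStack | np.ndarray) -> np.ndarray:
    """Concatenate z slices side by side: (m, n, z) -> (m, n*z).

    Columns ``k*n:(k+1)*n`` of the plane hold slice ``k``.
    """
    vox = stack.voxels if isinstance(stack, ImageStack) else np.asarray(stack)
    if vox.ndim == 2:
        vox = vox[:, :, None]
    m, n, z = vox.shape
    return vox.transpose(0, 2, 1).reshape(m, n * z)


def inverse_reshape(plane: np.ndarray, n_cols: int) -> np.ndarray:
    """Inverse of :func:`reshape_stack`: (m, n*z) -> (m, n, z)."""
    m, total = plane.shape
    if total % n_cols:
        raise ValueError("plane width is not a multiple of the slice width")
    z = total // n_cols
    return plane.reshape(m, z, n_cols).transpose(0, 2, 1)


def exact_otsu_threshold(values: np.ndarray) -> float:
    """Threshold maximizing between-class variance over the observed values.

    The returned threshold lies strictly between two adjacent observed
    intensities; "below threshold" is therefore unambiguous. Ties are broken
    toward the lowest threshold.
    """
    v = np.sort(np.asarray(values, dtype=float).ravel())
    uniq, counts = np.unique(v, return_counts=True)
    if len(uniq) < 2:
        raise DegenerateHistogramError("constant image: cannot compute Otsu threshold")
    n = v.size
    w = np.cumsum(counts)[:-1]  # class-0 sizes for each candidate split
    s = np.cumsum(counts * uniq)[:-1]
    total = float(np.sum(counts * uniq))
    mu0 = s / w
    mu1 = (total - s) / (n - w)
    between = (w / n) * (1 - w / n) * (mu0 - mu1) ** 2
    i = int(np.argmax(between))
    return float((uniq[i] + uniq[i + 1]) / 2.0)


def otsu_normalized_threshold(plane: np.ndarray,
                              max_percentile: float = 100.0) -> float:
    """Mean of the sub-Otsu pixels divided by the image maximum.

    Used as the (high) Canny threshold of the edge-detection stage.
    ``max_percentile < 100`` replaces the literal maximum with a robust one
    (see :class:`SegmentationParams`).
    """
    plane = np.asarray(plane, dtype=float)
    thr = exact_otsu_threshold(plane)
    below = plane[plane < thr]
    peak = (plane.max() if max_percentile >= 100
            else float(np.percentile(plane, max_percentile)))
    t = float(below.mean() / peak) if peak > 0 else 0.0
    return min(max(t, 0.0), 1.0)


_MAJORITY_KERNEL = np.ones((3, 3), dtype=int)


def _majority(binary: np.ndarray) -> np.ndarray:
    """Pixel is foreground iff >= 5 of its 3x3 neighbourhood (itself included) are."""
    neigh = convolve(binary.astype(np.uint8), _MAJORITY_KERNEL, mode="constant")
    return neigh >= 5


def binarize_plane(plane: np.ndarray, t: float,
                   params: SegmentationParams | None = None) -> np.ndarray:
    """Edge-based binarization of the reshaped plane.

    Order: median filter -> per-pixel squaring -> rescale to [0, 1] -> Canny
    (high threshold ``t``, low ``canny_low_ratio * t``) -> dilate diamond(1)
    -> fill enclosed holes -> erode diamond(1) -> 3x3 majority cleanup.
    """
    if not 0.0 <= t <= 1.0:
        raise ValueError("threshold t must lie in [0, 1]")
    params = params or SegmentationParams()
    plane = np.asarray(plane, dtype=float)
    filtered = median_filter(plane, size=params.median_size, mode="nearest")
    squared = filtered * filtered
    peak = (squared.max() if params.max_percentile >= 100
            else float(np.percentile(squared, params.max_percentile)))
    if peak > 0:
        squared = np.clip(squared / peak, 0.0, 1.0)
    if squared.max() == squared.min():
        return np.zeros(plane.shape, dtype=bool)
    edges = canny(squared, sigma=params.canny_sigma,
                  low_threshold=params.canny_low_ratio * t, high_threshold=t)
    se = generate_binary_structure(2, 1)  # diamond of radius 1
    grown = binary_dilation(edges, structure=se)
    filled = binary_fill_holes(grown)
    shrunk = binary_erosion(filled, structure=se)
    return _majority(shrunk)


def label_and_count(binary: np.ndarray, connectivity: int = 2) -> LabelMask:
    """Connected-component labelling; ``n_cells`` is the component count.

    ``connectivity`` follows scikit-image: in 2D, 1 = 4-connected,
    2 = 8-connected; in 3D up to 3 = full 26-connectivity.
    """
    labels = cc_label(np.asarray(binary).astype(bool), connectivity=connectivity)
    return LabelMask(labels)


@dataclass
class SegmentationResult:
    mask: LabelMask
    threshold: float
    log: dict = dc_field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return self.mask.n_cells


def segment_cells(stack: ImageStack,
                  params: SegmentationParams | None = None) -> SegmentationResult:
    """Full segmentation workflow on a cytoplasmic-marker stack.

    By default the binarized plane is restored to stack geometry and labelled
    in 3D, so a cell visible in several z slices receives a single label.
    ``label_mode="plane"`` labels the reshaped 2D plane instead (each slice
    appearance counts separately); the labelled plane is still restored to
    stack geometry on output.
    """
    params = params or SegmentationParams()
    plane = reshape_stack(stack)
    t = otsu_normalized_threshold(plane, params.max_percentile)
    logger.info("segmentation: normalized Otsu threshold = %.5f", t)
    binary = binarize_plane(plane, t, params)
    n = stack.shape[1]
    if params.label_mode == "plane":
        mask2d = label_and_count(binary, connectivity=min(params.connectivity, 2))
        labels3d = inverse_reshape(mask2d.labels, n)
        mask = LabelMask(labels3d)
        n_cells = mask2d.n_cells
    else:
        binary3d = inverse_reshape(binary, n)
        mask = label_and_count(binary3d, connectivity=params.connectivity + 1)
        n_cells = mask.n_cells
    if params.min_area_px > 0:
        # filter on the projected (in-plane) footprint: a credible cell has a
        # solid 2D footprint regardless of how many z slices it binarized in
        labels = mask.labels
        foot = mask.plane_labels()
        vals, counts = np.unique(foot[foot > 0], return_counts=True)
        small = vals[counts < params.min_area_px]
        if small.size:
            labels[np.isin(labels, small)] = 0
            mask = LabelMask(labels)
            n_cells = mask.n_cells
    log = {"threshold": t, "label_mode": params.label_mode, "n_cells": n_cells}
    return SegmentationResult(mask=mask, threshold=t, log=log)
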