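"""Nucleus segmentation from single-channel fluorescence images.

The chain mirrors standard colony-image practice: adaptive (Wiener-style)
noise suppression -> Otsu binarization -> morphological opening/closing ->
removal of components under 8 px and of border-touching structures ->
watershed on the negated Euclidean distance transform with h-minima
imposition to split touching nuclei without over-segmentation.

Coordinate convention used throughout the package: pixel-centered, origin at
the top-left corner, ``x`` = column, ``y`` = row, 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.ndimage as ndi
import tifffile
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import closing, opening, reconstruction, remove_small_objects
from skimage.segmentation import clear_border, relabel_sequential, watershed

from .morphometrics import CellRecord, region_eccentricity, roundness

__all__ = [
    "ColonyImage",
    "SegmentationParams",
    "LabeledMask",
    "DegenerateHistogramError",
    "load_tiff",
    "denoise",
    "binarize_otsu",
    "morphological_cleanup",
    "filter_small_and_border",
    "watershed_segment",
    "extract_cells",
    "segment_image",
]


class DegenerateHistogramError(ValueError):
    """Otsu thresholding requested on an image with a single intensity value."""


@dataclass
class ColonyImage:
    """Single-channel intensity raster plus acquisition metadata."""

    pixels: np.ndarray
    bit_depth: int = 14
    pixel_size_um: float = 0.7373

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"expected a single-channel 2D image, got shape {px.shape}")
        if px.shape[0] < 64 or px.shape[1] < 64:
            raise ValueError("image must be at least 64x64 pixels")
        if px.min() < 0 or px.max() > 2**self.bit_depth - 1:
            raise ValueError("intensities out of range for declared bit depth")
        self.pixels = px


@dataclass
class SegmentationParams:
    """Tunable parameters of the segmentation chain.

    ``connectivity`` is the pixel neighborhood (4 or 8) used for component
    labeling and watershed flooding.  ``hmin_depth`` is the minimum depth (in
    distance-transform levels) a catchment basin must have to survive minima
    imposition; shallower minima are filled before flooding.
    """

    filter_window_px: int = 3
    min_component_px: int = 8
    connectivity: int = 8
    hmin_depth: float = 2.0
    clear_border: bool = True
    opening_radius: int = 1

    def __post_init__(self) -> None:
        if self.filter_window_px < 1 or self.filter_window_px % 2 == 0:
            raise ValueError("filter_window_px must be odd and positive")
        if self.min_component_px < 1:
            raise ValueError("min_component_px must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.hmin_depth <= 0:
            raise ValueError("hmin_depth must be > 0")

    @property
    def _skimage_connectivity(self) -> int:
        return 1 if self.connectivity == 4 else 2


@dataclass
class LabeledMask:
    """Integer label raster; 0 = background, labels consecutive 1..n_regions."""

    labels: np.ndarray
    n_regions: int


def load_tiff(path: str | Path, bit_depth: int = 14, pixel_size_um: float = 0.7373) -> ColonyImage:
    """Read a grayscale TIFF; multi-channel inputs are rejected."""
    px = tifffile.imread(path)
    if px.ndim != 2:
        raise ValueError(
            f"{path}: expected single-channel grayscale TIFF, got shape {px.shape}"
        )
    return ColonyImage(pixels=px, bit_depth=bit_depth, pixel_size_um=pixel_size_um)


def denoise(image: ColonyImage, params: SegmentationParams | None = None) -> ColonyImage:
    """Adaptive local-mean / local-variance (Wiener-style) noise shrinkage.

    In each ``filter_window_px`` window the pixel is pulled toward the local
    mean by the factor ``max(var - noise, 0) / var``, where ``noise`` is the
    image-wide mean of local variances — the classical pixelwise shrinkage for
    constant-power additive noise.  Output keeps shape, dtype and bit depth;
    a constant image passes through unchanged.
    """
    params = params or SegmentationParams()
    x = image.pixels.astype(np.float64)
    w = params.filter_window_px
    mu = ndi.uniform_filter(x, size=w, mode="reflect")
    var = ndi.uniform_filter(x * x, size=w, mode="reflect") - mu * mu
    np.maximum(var, 0.0, out=var)
    noise = var.mean()
    with np.errstate(invalid="ignore", divide="ignore"):
        gain = np.where(var > noise, (var - noise) / np.where(var > 0, var, 1.0), 0.0)
    out = mu + gain * (x - mu)
    top = 2**image.bit_depth - 1
    out = np.clip(np.rint(out), 0, top).astype(image.pixels.dtype)
    return ColonyImage(pixels=out, bit_depth=image.bit_depth, pixel_size_um=image.pixel_size_um)


def binarize_otsu(image: ColonyImage | np.ndarray) -> np.ndarray:
    """Otsu threshold; pixels strictly above the threshold are foreground."""
    px = image.pixels if isinstance(image, ColonyImage) else np.asarray(image)
    if px.min() == px.max():
        raise DegenerateHistogramError(
            "image has a single intensity value; Otsu threshold undefined"
        )
    t = threshold_otsu(px)
    return px > t


def morphological_cleanup(mask: np.ndarray, params: SegmentationParams | None = None) -> np.ndarray:
    """Opening (removes small bright specks) then closing (fills small holes).

    The structuring element is the Chebyshev disc of ``opening_radius``
    (a (2r+1)x(2r+1) square, 3x3 by default), which leaves large convex
    shapes exactly invariant."""
    params = params or SegmentationParams()
    r = params.opening_radius
    se = np.ones((2 * r + 1, 2 * r + 1), dtype=bool)
    out = opening(mask.astype(bool), se)
    out = closing(out, se)
    return out.astype(bool)


def filter_small_and_border(mask: np.ndarray, params: SegmentationParams | None = None) -> np.ndarray:
    """Drop components with fewer than ``min_component_px`` pixels (strict <)
    and, when ``clear_border`` is set, components touching any image edge."""
    params = params or SegmentationParams()
    conn = params._skimage_connectivity
    lab = cc_label(mask.astype(bool), connectivity=conn)
    # remove components with strictly fewer than min_component_px pixels
    lab = remove_small_objects(lab, max_size=params.min_component_px - 1)
    if params.clear_border:
        lab = clear_border(lab)
    return lab > 0


def watershed_segment(mask: np.ndarray, params: SegmentationParams | None = None) -> LabeledMask:
    """Split touching nuclei by watershed on the negated distance transform.

    The relief is ``-EDT(mask)``; minima shallower than ``hmin_depth`` are
    filled by grayscale reconstruction (h-minima imposition) before flooding,
    so tiny spurious basins do not fragment a nucleus.  Every foreground pixel
    receives exactly one label; background stays 0.
    """
    params = params or SegmentationParams()
    mask = mask.astype(bool)
    if not mask.any():
        return LabeledMask(labels=np.zeros(mask.shape, dtype=np.int32), n_regions=0)
    relief = -ndi.distance_transform_edt(mask)
    # h-minima imposition: erosion-reconstruct relief+h over relief, then flood
    filled = reconstruction(relief + params.hmin_depth, relief, method="erosion")
    labels = watershed(filled, mask=mask, connectivity=params._skimage_connectivity)
    labels, _, _ = relabel_sequential(labels)
    return LabeledMask(labels=labels.astype(np.int32), n_regions=int(labels.max()))


def extract_cells(labeled: LabeledMask) -> list[CellRecord]:
    """One CellRecord per region: geometric centroid, area, perimeter,
    eccentricity and roundness, ordered by label."""
    records: list[CellRecord] = []
    if labeled.n_regions == 0:
        return records
    for rp in regionprops(labeled.labels):
        cy, cx = rp.centroid
        area = float(rp.area)
        perim = float(rp.perimeter)
        ecc = region_eccentricity(rp.image) if area >= 3 else 0.0
        records.append(
            CellRecord(
                cell_id=int(rp.label),
                x=float(cx),
                y=float(cy),
                area=area,
                perimeter=perim,
                eccentricity=ecc,
                roundness=roundness(area, perim) if perim > 0 else float("nan"),
            )
        )
    records.sort(key=lambda r: r.cell_id)
    return records


def segment_image(
    image: ColonyImage, params: SegmentationParams | None = None
) -> tuple[LabeledMask, list[CellRecord]]:
    """Full chain: denoise -> Otsu -> open/close -> size & border filter ->
    watershed -> per-nucleus records.  Deterministic."""
    params = params or SegmentationParams()
    den = denoise(image, params)
    mask = binarize_otsu(den)
    mask = morphological_cleanup(mask, params)
    mask = filter_small_and_border(mask, params)
    labeled = watershed_segment(mask, params)
    return labeled, extract_cells(labeled)
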