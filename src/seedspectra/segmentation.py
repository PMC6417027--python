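"""Seed segmentation: 780 nm thresholding, blob labelling, mask application.

Seeds appear as bright objects against an opaque background at 780 nm, so the
mask is a simple threshold of that single band: 0 where reflectance <= T,
1 where it exceeds T. T can be given explicitly or selected by Otsu's method.
Connected components of the mask (8-connectivity) are the per-seed regions of
interest; tiny components are discarded as specks.

Touching seeds are NOT separated (no watershed): dishes are assumed to have
spaced seeds, which the synthetic scenes guarantee by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure, morphology
from skimage.filters import threshold_otsu

from .cube import MultispectralCube
from .exceptions import ThresholdError, ValidationError

__all__ = ["SeedMask", "Blob", "BlobTable", "threshold_band", "label_blobs", "apply_mask"]

#: Default minimum blob area in pixels (~0.09 mm^2 at 0.0432 mm/px), far
#: below any real seed but large enough to suppress specks.
DEFAULT_MIN_AREA_PX = 50


@dataclass(frozen=True)
class SeedMask:
    """Binary seed mask with provenance of how it was produced."""

    mask: np.ndarray
    threshold_used: float
    source_wavelength_nm: float | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.ndim != 2:
            raise ValidationError(f"mask must be 2-D, got shape {m.shape}")
        vals = np.unique(m)
        if not np.isin(vals, (0, 1)).all():
            raise ValidationError("mask values must be 0/1")
        object.__setattr__(self, "mask", m.astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape  # type: ignore[return-value]

    @property
    def foreground_px(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class Blob:
    """One labelled connected component (a seed region of interest)."""

    blob_id: int
    rows: np.ndarray
    cols: np.ndarray
    area_px: int
    centroid: tuple[float, float]
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row_excl, max_col_excl)


@dataclass(frozen=True)
class BlobTable:
    """Area-filtered blobs, ids 1..K in raster order of each blob's first pixel."""

    blobs: tuple[Blob, ...]
    image_shape: tuple[int, int]

    def __len__(self) -> int:
        return len(self.blobs)

    def __iter__(self):
        return iter(self.blobs)

    def labels_image(self) -> np.ndarray:
        """Integer label image: 0 background, blob_id on each blob's pixels."""
        out = np.zeros(self.image_shape, dtype=np.int32)
        for b in self.blobs:
            out[b.rows, b.cols] = b.blob_id
        return out


def threshold_band(
    plane: np.ndarray,
    threshold: float | str = "auto",
    opening_radius: int = 0,
) -> SeedMask:
    """Binarise a reflectance plane: foreground where value > T.

    Parameters
    ----------
    plane
        2-D reflectance image (typically the 780 nm band).
    threshold
        A scalar T, or ``"auto"`` to select T by Otsu's method on the plane
        histogram. A constant plane cannot be auto-thresholded.
    opening_radius
        Optional morphological opening (disk radius, px) applied to the mask;
        0 disables any cleanup.
    """
    plane = np.asarray(plane)
    if plane.ndim != 2:
        raise ValidationError(f"expected a 2-D plane, got shape {plane.shape}")
    if not np.isfinite(plane).all():
        raise ValidationError("plane contains non-finite values")
    if isinstance(threshold, str):
        if threshold != "auto":
            raise ValidationError(f"unknown threshold mode '{threshold}'")
        if np.ptp(plane) == 0:
            raise ThresholdError("constant plane: Otsu threshold is undefined")
        t = float(threshold_otsu(plane))
    else:
        t = float(threshold)
    mask = (plane > t).astype(np.uint8)
    if opening_radius > 0:
        mask = morphology.binary_opening(
            mask.astype(bool), morphology.disk(opening_radius)
        ).astype(np.uint8)
    return SeedMask(mask=mask, threshold_used=t)


def label_blobs(mask: SeedMask, min_area_px: int = DEFAULT_MIN_AREA_PX) -> BlobTable:
    """Label 8-connected foreground components and drop those below ``min_area_px``.

    Ids are reassigned 1..K in raster-scan order of each surviving component's
    first pixel, so blob order is stable and independent of the filtering.
    An empty mask yields an empty table.
    """
    labelled = measure.label(mask.mask, connectivity=2)  # 8-connectivity
    blobs: list[Blob] = []
    for region in measure.regionprops(labelled):
        if region.area < min_area_px:
            continue
        coords = region.coords
        blobs.append(
            Blob(
                blob_id=0,  # assigned after ordering
                rows=coords[:, 0].copy(),
                cols=coords[:, 1].copy(),
                area_px=int(region.area),
                centroid=tuple(region.centroid),
                bbox=tuple(region.bbox),
            )
        )
    # raster order of first (topmost-then-leftmost) pixel
    blobs.sort(key=lambda b: (int(b.rows.min()), int(b.cols[b.rows == b.rows.min()].min())))
    blobs = [
        Blob(i + 1, b.rows, b.cols, b.area_px, b.centroid, b.bbox)
        for i, b in enumerate(blobs)
    ]
    return BlobTable(tuple(blobs), mask.shape)


def apply_mask(cube: MultispectralCube, mask: SeedMask) -> MultispectralCube:
    """Zero background pixels in every band; foreground is untouched.

    Idempotent: applying the same mask twice equals applying it once.
    """
    if mask.shape != cube.spatial_shape:
        raise ValidationError(
            f"mask shape {mask.shape} does not match cube spatial shape "
            f"{cube.spatial_shape}"
        )
    out = cube.pixels * mask.mask[:, :, None]
    return MultispectralCube(out, cube.grid, cube.pixel_size_mm)
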