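"""Pixel-wise classification images.

A trained discriminant model is applied to every seed pixel of a cube: the
cube is unfolded to an ``(H*W) x B`` matrix of pixel spectra (row-major), the
model classifies the masked rows, and the verdict vector is refolded to an
``H x W`` label plane. Background pixels (outside the seed mask) carry label 0
and are never sent through the model — the background is handled by masking,
not by a trained background class.

The rendered map uses the conventional colouring: blue background, green
"Non-aged", red "Aged"; further classes get distinct fixed colours.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import tifffile

from .cube import MultispectralCube
from .discriminant import LDAResult
from .exceptions import RenderingError, ValidationError
from .segmentation import SeedMask

__all__ = ["ClassificationImage", "classify_pixels", "render_map", "DEFAULT_COLORS"]

#: Display colours: background plus the conventional class colours, then a
#: fixed cycle of distinct fallbacks for any further classes.
DEFAULT_COLORS: dict[str, tuple[int, int, int]] = {
    "Background": (0, 0, 255),  # blue
    "Non-aged": (0, 255, 0),    # green
    "Aged": (255, 0, 0),        # red
}

_FALLBACK_CYCLE: tuple[tuple[int, int, int], ...] = (
    (255, 165, 0),   # orange
    (255, 0, 255),   # magenta
    (0, 255, 255),   # cyan
    (255, 255, 0),   # yellow
    (128, 0, 128),   # purple
    (165, 42, 42),   # brown
    (255, 255, 255), # white
)


@dataclass(frozen=True)
class ClassificationImage:
    """Per-pixel class-label raster with a display legend.

    ``labels`` holds 0 on background pixels and ``1..K`` on seed pixels, where
    label ``i`` is model class ``i - 1``. ``legend`` maps each label to its
    ``(class name, RGB colour)``.
    """

    labels: np.ndarray
    legend: Mapping[int, tuple[str, tuple[int, int, int]]]
    posteriors: np.ndarray | None = None  # optional H x W x K confidence layer

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValidationError(f"label plane must be 2-D, got {lab.shape}")
        object.__setattr__(self, "labels", lab.astype(np.int32))

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def to_tiff(self, path: str | Path) -> Path:
        """Export the label plane as a single-band TIFF."""
        path = Path(path)
        tifffile.imwrite(path, self.labels)
        return path


def classify_pixels(
    cube: MultispectralCube,
    mask: SeedMask,
    result: LDAResult,
    keep_posteriors: bool = False,
) -> ClassificationImage:
    """Classify every masked pixel of ``cube`` with a fitted discriminant model.

    Parameters
    ----------
    cube
        The reflectance cube; its band count must match the model.
    mask
        Seed mask; pixels outside it are labelled 0 without prediction.
    result
        A fitted :class:`~seedspectra.discriminant.LDAResult`.
    keep_posteriors
        Also return the per-pixel posterior probabilities as an
        ``H x W x K`` layer (zeros on background). Off by default.
    """
    if mask.shape != cube.spatial_shape:
        raise ValidationError(
            f"mask shape {mask.shape} vs cube spatial shape {cube.spatial_shape}"
        )
    if cube.shape[2] != result.n_bands:
        raise ValidationError(
            f"cube has {cube.shape[2]} bands but model expects {result.n_bands}"
        )
    h, w, _ = cube.shape
    flat = cube.unfold()
    fg = mask.mask.reshape(-1).astype(bool)
    labels = np.zeros(h * w, dtype=np.int32)
    post_layer = None
    if fg.any():
        assigned, post, _ = result.predict(flat[fg])
        labels[fg] = assigned + 1
        if keep_posteriors:
            post_layer = np.zeros((h * w, result.n_classes))
            post_layer[fg] = post
            post_layer = post_layer.reshape(h, w, result.n_classes)
    elif keep_posteriors:
        post_layer = np.zeros((h, w, result.n_classes))

    legend = {0: ("Background", DEFAULT_COLORS["Background"])}
    fallback = iter(_FALLBACK_CYCLE)
    for i, name in enumerate(result.class_names, start=1):
        color = DEFAULT_COLORS.get(name)
        if color is None:
            color = next(fallback)
        legend[i] = (name, color)
    return ClassificationImage(labels.reshape(h, w), legend, post_layer)


def render_map(
    cimg: ClassificationImage,
    palette: Mapping[int, tuple[int, int, int]] | None = None,
) -> np.ndarray:
    """Colour the label plane into an ``H x W x 3`` uint8 RGB image.

    ``palette`` maps label -> RGB and defaults to the legend colours; it must
    cover every label present in the plane.
    """
    if palette is None:
        palette = {lab: rgb for lab, (_, rgb) in cimg.legend.items()}
    present = np.unique(cimg.labels)
    missing = [int(l) for l in present if int(l) not in palette]
    if missing:
        raise RenderingError(f"palette lacks entries for labels {missing}")
    lut = np.zeros((int(present.max()) + 1, 3), dtype=np.uint8)
    for lab in present:
        lut[int(lab)] = palette[int(lab)]
    return lut[cimg.labels]


def save_map_png(
    cimg: ClassificationImage,
    path: str | Path,
    palette: Mapping[int, tuple[int, int, int]] | None = None,
) -> Path:
    """Render and save the classification map as a PNG."""
    import imageio.v3 as iio

    path = Path(path)
    iio.imwrite(path, render_map(cimg, palette))
    return path
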