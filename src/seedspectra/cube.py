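"""Multispectral cube container and band-stack I/O.

A *cube* is an ``H x W x B`` stack of reflectance planes, one per LED band,
together with the grid of band-centre wavelengths. Reflectance is dimensionless
(calibrated against a white reference) and stored in 32-bit floating point;
values slightly above 1 are legal because specular points can overshoot the
white standard.

Cubes are serialised as multi-page grayscale TIFF (one page per band) plus a
JSON sidecar manifest ``{"wavelengths_nm": [...], "pixel_size_mm": x}`` —
no public dialect exists for the acquisition instrument's native format, so a
plain open stack is used instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

from .exceptions import BandLookupError, CubeFormatError, ValidationError

__all__ = [
    "DEFAULT_WAVELENGTHS_NM",
    "DEFAULT_PIXEL_SIZE_MM",
    "WavelengthGrid",
    "MultispectralCube",
    "read_cube",
    "write_cube",
    "band",
]

#: Band-centre wavelengths (nm) of the 20-LED instrument configuration,
#: non-uniformly distributed from the UV to the shortwave NIR.
DEFAULT_WAVELENGTHS_NM: tuple[float, ...] = (
    375, 405, 435, 450, 470, 505, 525, 570, 590, 630,
    645, 660, 700, 780, 850, 870, 890, 910, 940, 970,
)

#: Spatial resolution (mm per pixel) of the reference acquisition geometry.
DEFAULT_PIXEL_SIZE_MM: float = 0.0432

#: Wavelengths within this many nm of a grid entry resolve to that band.
WAVELENGTH_TOL_NM: float = 0.5


@dataclass(frozen=True)
class WavelengthGrid:
    """Ordered band-centre wavelengths of a multispectral cube.

    Parameters
    ----------
    wavelengths_nm
        Strictly increasing band centres in nanometres; at least two bands.

    Notes
    -----
    User-facing band addressing is always by wavelength, never by raw index:
    vendor documentation counts bands 1-based while arrays are 0-based, and
    addressing by physical wavelength removes the ambiguity.
    """

    wavelengths_nm: tuple[float, ...] = DEFAULT_WAVELENGTHS_NM

    def __post_init__(self) -> None:
        wl = tuple(float(w) for w in self.wavelengths_nm)
        if len(wl) < 2:
            raise ValidationError("a wavelength grid needs at least 2 bands")
        if any(b <= a for a, b in zip(wl, wl[1:])):
            raise ValidationError(
                f"wavelengths must be strictly increasing, got {wl}"
            )
        object.__setattr__(self, "wavelengths_nm", wl)

    def __len__(self) -> int:
        return len(self.wavelengths_nm)

    def index_of(self, wavelength_nm: float) -> int:
        """Return the 0-based band index of ``wavelength_nm``.

        The match tolerance is ±0.5 nm. A miss raises
        :class:`~seedspectra.exceptions.BandLookupError` naming the nearest
        available band.
        """
        wl = np.asarray(self.wavelengths_nm)
        dist = np.abs(wl - float(wavelength_nm))
        i = int(np.argmin(dist))
        if dist[i] > WAVELENGTH_TOL_NM:
            raise BandLookupError(
                f"no band at {wavelength_nm} nm; nearest available band is "
                f"{wl[i]:g} nm"
            )
        return i


@dataclass
class MultispectralCube:
    """An ``H x W x B`` reflectance image with band metadata.

    Parameters
    ----------
    pixels
        Reflectance array of shape ``(H, W, B)``; finite floating point.
    grid
        The :class:`WavelengthGrid`; its length must equal ``B``.
    pixel_size_mm
        Physical size of one pixel (mm).
    """

    pixels: np.ndarray
    grid: WavelengthGrid = field(default_factory=WavelengthGrid)
    pixel_size_mm: float = DEFAULT_PIXEL_SIZE_MM

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float32)
        if px.ndim != 3:
            raise ValidationError(
                f"cube pixels must be H x W x B, got shape {px.shape}"
            )
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValidationError("cube spatial dimensions must be >= 1")
        if px.shape[2] != len(self.grid):
            raise ValidationError(
                f"cube has {px.shape[2]} bands but grid lists "
                f"{len(self.grid)} wavelengths"
            )
        if not np.isfinite(px).all():
            raise ValidationError("cube contains non-finite reflectance values")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]  # type: ignore[return-value]

    def band(self, wavelength_nm: float) -> np.ndarray:
        """Return the ``H x W`` plane for the band centred at ``wavelength_nm``."""
        return self.pixels[:, :, self.grid.index_of(wavelength_nm)]

    def unfold(self) -> np.ndarray:
        """Unfold to an ``(H*W) x B`` matrix of per-pixel spectra (row-major)."""
        h, w, b = self.pixels.shape
        return self.pixels.reshape(h * w, b)


def band(cube: MultispectralCube, wavelength_nm: float) -> np.ndarray:
    """Functional alias of :meth:`MultispectralCube.band`."""
    return cube.band(wavelength_nm)


def _manifest_path_for(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_cube(cube: MultispectralCube, path: str | Path) -> Path:
    """Write ``cube`` as a multi-page TIFF plus a JSON wavelength manifest.

    One grayscale float32 page is written per band, in grid order, so the
    round trip through :func:`read_cube` is lossless at stored precision.

    Returns
    -------
    Path
        Location of the manifest file (``<path>.json``).
    """
    path = Path(path)
    with tifffile.TiffWriter(path) as writer:
        for b in range(cube.shape[2]):  # one grayscale page per band
            writer.write(
                cube.pixels[:, :, b], photometric="minisblack", contiguous=False
            )
    manifest = _manifest_path_for(path)
    manifest.write_text(
        json.dumps(
            {
                "wavelengths_nm": list(cube.grid.wavelengths_nm),
                "pixel_size_mm": cube.pixel_size_mm,
            },
            indent=2,
        )
    )
    return manifest


def read_cube(path: str | Path, manifest: str | Path | None = None) -> MultispectralCube:
    """Read a multi-page TIFF band stack with its wavelength manifest.

    Parameters
    ----------
    path
        The TIFF written by :func:`write_cube` (or any single-channel
        multi-page raster with one page per band).
    manifest
        JSON manifest path; defaults to ``<path>.json``.

    Raises
    ------
    CubeFormatError
        If the page count disagrees with the manifest's wavelength count.
    ValidationError
        If the manifest wavelengths are not strictly increasing.
    """
    path = Path(path)
    manifest = _manifest_path_for(path) if manifest is None else Path(manifest)
    meta = json.loads(manifest.read_text())
    wavelengths: Sequence[float] = meta["wavelengths_nm"]
    with tifffile.TiffFile(path) as tf:
        planes = [p.asarray() for p in tf.pages]
    if any(p.ndim != 2 for p in planes):
        shapes = sorted({p.shape for p in planes})
        raise CubeFormatError(f"expected single-channel pages, got page shapes {shapes}")
    if len({p.shape for p in planes}) > 1:
        raise CubeFormatError("pages disagree on spatial shape")
    pages = np.stack(planes)
    if pages.shape[0] != len(wavelengths):
        raise CubeFormatError(
            f"file has {pages.shape[0]} pages but manifest lists "
            f"{len(wavelengths)} wavelengths"
        )
    grid = WavelengthGrid(tuple(wavelengths))
    return MultispectralCube(
        pixels=np.moveaxis(pages, 0, 2),
        grid=grid,
        pixel_size_mm=float(meta.get("pixel_size_mm", DEFAULT_PIXEL_SIZE_MM)),
    )


def write_band_png(cube: MultispectralCube, wavelength_nm: float, path: str | Path) -> Path:
    """Export a single band as an 8-bit grayscale PNG (display only).

    Reflectance is linearly rescaled from its [min, max] to [0, 255]; this is
    a visualisation convenience and is not reversible.
    """
    import imageio.v3 as iio

    plane = cube.band(wavelength_nm)
    lo, hi = float(plane.min()), float(plane.max())
    scale = 255.0 / (hi - lo) if hi > lo else 0.0
    img = ((plane - lo) * scale).astype(np.uint8)
    path = Path(path)
    iio.imwrite(path, img)
    return path
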