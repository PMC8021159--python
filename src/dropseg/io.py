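"""Image input/output and per-image preprocessing.

Quantitative-phase images (QPI) record the optical phase delay of light
through a specimen rather than intensity.  Background phase is ~0, the
cell cytosol sits at an intermediate level and lipid droplets are the
brightest structures, which is why a direct phase threshold is a useful
(if crude) segmentation baseline.

On disk, phase images are single-band 32-bit float TIFFs and masks are
single-band 8-bit TIFFs with the {0, 255} dialect; in memory masks are
{0, 1} arrays.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import tifffile


class FormatError(ValueError):
    """Raised for files or arrays that violate the expected image format."""


@dataclass
class QPIImage:
    """A 2D grid of real-valued optical-phase values (arbitrary phase units)."""

    pixels: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise FormatError(
                f"QPIImage requires a 2D single-band grid, got ndim={self.pixels.ndim}"
            )
        if self.pixels.size == 0:
            raise FormatError("QPIImage requires width >= 1 and height >= 1")
        if not np.all(np.isfinite(self.pixels)):
            raise FormatError("QPIImage pixels must be finite (no NaN/Inf)")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class NormalizedImage:
    """8-bit internal representation of a phase image.

    ``norm_params`` records the observed (min, max) of the source image so
    the affine rescaling is documented alongside the data.
    """

    pixels: np.ndarray
    norm_params: tuple[float, float] = (0.0, 255.0)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise FormatError("NormalizedImage requires a non-empty 2D grid")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise FormatError("NormalizedImage values must lie in [0, 255]")
        self.pixels = self.pixels.astype(np.uint8)
        lo, hi = self.norm_params
        if lo > hi:
            raise FormatError("norm_params must satisfy min <= max")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class BinaryMask:
    """A {0, 1} per-pixel label grid; 1 marks lipid-droplet pixels."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise FormatError("BinaryMask requires a non-empty 2D grid")
        vals = np.unique(self.pixels)
        if not np.isin(vals, (0, 1)).all():
            raise FormatError("BinaryMask values must be 0 or 1")
        self.pixels = self.pixels.astype(np.uint8)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class PadRecord:
    """Border widths used to centre an image on a square canvas.

    Invertible: :func:`unpad` uses it to restore the original exactly.
    """

    left: int
    right: int
    top: int
    bottom: int
    canvas: int = 256

    def __post_init__(self) -> None:
        for name in ("left", "right", "top", "bottom"):
            if getattr(self, name) < 0:
                raise ValueError(f"PadRecord.{name} must be non-negative")
        if abs(self.left - self.right) > 1 or abs(self.top - self.bottom) > 1:
            raise ValueError("padding must be even up to a single-pixel remainder")


def read_grayscale_tiff(path: str | os.PathLike) -> QPIImage:
    """Read a single-band 32-bit grayscale TIFF as a :class:`QPIImage`.

    Multi-band (e.g. RGB) files and non-finite pixel data are rejected.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    data = tifffile.imread(path)
    if data.ndim != 2:
        raise FormatError(
            f"{path}: expected a single-band image, got shape {data.shape}"
        )
    data = data.astype(np.float32)
    if not np.all(np.isfinite(data)):
        raise FormatError(f"{path}: image contains NaN or Inf pixels")
    return QPIImage(pixels=data, source_id=os.fspath(path))


def write_grayscale_tiff(path: str | os.PathLike, image: QPIImage) -> None:
    """Write a phase image as a single-band 32-bit float TIFF."""
    tifffile.imwrite(path, image.pixels.astype(np.float32))


def write_mask(path: str | os.PathLike, mask: BinaryMask) -> None:
    """Write a binary mask as an 8-bit single-band TIFF, 1 -> 255, 0 -> 0."""
    tifffile.imwrite(path, (mask.pixels * 255).astype(np.uint8))


def read_mask(path: str | os.PathLike) -> BinaryMask:
    """Read an 8-bit {0, 255} mask TIFF back into the in-memory {0, 1} form."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    data = tifffile.imread(path)
    if data.ndim != 2:
        raise FormatError(f"{path}: expected a single-band mask, got {data.shape}")
    vals = np.unique(data)
    if not np.isin(vals, (0, 255)).all():
        raise FormatError(f"{path}: mask pixels must be 0 or 255, found {vals[:8]}")
    return BinaryMask(pixels=(data > 0).astype(np.uint8))


def max_project(stack: list[np.ndarray] | list[QPIImage]) -> QPIImage:
    """Compress an ordered z-stack into 2D by the maximum projection method.

    Each output pixel is the maximum across slices at that location; this is
    the standard way to flatten a 3D acquisition whose axial resolution is
    lower than its lateral one.
    """
    if len(stack) == 0:
        raise ValueError("max_project requires at least one slice")
    arrays = [s.pixels if isinstance(s, QPIImage) else np.asarray(s) for s in stack]
    shape = arrays[0].shape
    for i, a in enumerate(arrays):
        if a.ndim != 2:
            raise FormatError(f"slice {i} is not 2D")
        if a.shape != shape:
            raise FormatError(
                f"ragged stack: slice {i} has shape {a.shape}, expected {shape}"
            )
    return QPIImage(pixels=np.max(np.stack(arrays, axis=0), axis=0))


def normalize_to_uint8(image: QPIImage) -> NormalizedImage:
    """Min-max rescale a phase image to the 8-bit internal representation.

    v -> round(255 * (v - min) / (max - min)) with round-half-up.  A
    constant image has zero range and no signal; it maps to all 0.
    """
    pix = image.pixels.astype(np.float64)
    lo = float(pix.min())
    hi = float(pix.max())
    if hi == lo:
        out = np.zeros_like(pix, dtype=np.uint8)
    else:
        scaled = 255.0 * (pix - lo) / (hi - lo)
        # round-half-up, deterministic across platforms (numpy rounds half-even)
        out = np.floor(scaled + 0.5).astype(np.uint8)
    return NormalizedImage(pixels=out, norm_params=(lo, hi))


def _split_border(total: int) -> tuple[int, int]:
    # odd remainders go to the right/bottom by convention
    first = total // 2
    return first, total - first


def pad_to_canvas(
    image: NormalizedImage | BinaryMask | np.ndarray, canvas: int = 256
) -> tuple[np.ndarray, PadRecord]:
    """Centre an image on a ``canvas`` x ``canvas`` square, border filled with 0.

    Background phase is ~0 in QPI so a zero border is a natural continuation
    of the scene.  Returns the padded array and an invertible
    :class:`PadRecord`; images larger than the canvas are rejected rather
    than cropped.
    """
    pix = image if isinstance(image, np.ndarray) else image.pixels
    h, w = pix.shape
    if h > canvas or w > canvas:
        raise ValueError(
            f"image {w}x{h} exceeds canvas {canvas}x{canvas}; cropping is not supported"
        )
    left, right = _split_border(canvas - w)
    top, bottom = _split_border(canvas - h)
    padded = np.zeros((canvas, canvas), dtype=pix.dtype)
    padded[top : top + h, left : left + w] = pix
    return padded, PadRecord(left=left, right=right, top=top, bottom=bottom, canvas=canvas)


def unpad(padded: np.ndarray, record: PadRecord) -> np.ndarray:
    """Invert :func:`pad_to_canvas`, restoring the original array exactly."""
    c = record.canvas
    if padded.shape != (c, c):
        raise ValueError(f"padded array shape {padded.shape} != canvas {(c, c)}")
    return padded[
        record.top : c - record.bottom, record.left : c - record.right
    ].copy()


def direct_phase_threshold(image: QPIImage, cutoff: float) -> BinaryMask:
    """Direct optical-phase thresholding baseline: mask = 1 where pixel >= cutoff.

    The comparison is >= so the boundary rule is exact and testable.
    """
    return BinaryMask(pixels=(image.pixels >= cutoff).astype(np.uint8))
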