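"""Image stack I/O, maximum-intensity projection, and tabular output.

The quantification pipeline starts from multi-frame grayscale TIFF stacks of
junction-labelled monolayers (typically a confocal z-stack of ZO-1
immunofluorescence).  All downstream measurements are physical lengths, so
every image carries an explicit pixel size in micrometres per pixel; it is
never silently assumed.

Pixel-size precedence: an explicit override (function argument / CLI flag)
wins over TIFF resolution metadata; if neither is available reading fails
with :class:`CalibrationError`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger("tjquant")

__all__ = [
    "CalibrationError",
    "FormatError",
    "ImageStack",
    "Image2D",
    "read_stack",
    "write_stack",
    "max_project",
    "write_segments_table",
    "read_segments_table",
]


class CalibrationError(ValueError):
    """No resolvable physical pixel size for an image."""


class FormatError(ValueError):
    """Unsupported image layout (e.g. an RGB page in a grayscale pipeline)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ImageStack:
    """An ordered stack of 2-D intensity frames with a physical pixel size.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, height, width)
        Non-negative intensities in the original acquisition units.  8- and
        16-bit integer TIFF data are converted to float without rescaling,
        because downstream thresholds are data-driven.
    pixel_size : float
        Micrometres per pixel, strictly positive and finite.
    channel_label, source_id : str
        Free-text provenance (e.g. ``"ZO-1"`` and a file name).
    """

    frames: np.ndarray
    pixel_size: float
    channel_label: str = ""
    source_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError(
                "frames must be a (n_frames, height, width) array with at "
                f"least one frame, got shape {self.frames.shape}"
            )
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frame intensities must be finite")
        if not (np.isfinite(self.pixel_size) and self.pixel_size > 0):
            raise ValueError(f"pixel_size must be positive and finite, got {self.pixel_size}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class Image2D:
    """A single 2-D intensity grid with a physical pixel size."""

    values: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError(f"values must be 2-D, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("intensities must be finite")
        if not (np.isfinite(self.pixel_size) and self.pixel_size > 0):
            raise ValueError(f"pixel_size must be positive and finite, got {self.pixel_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


# ---------------------------------------------------------------------------
# TIFF I/O
# ---------------------------------------------------------------------------

_UM_PER_UNIT = {
    # TIFF ResolutionUnit tag values -> micrometres per unit.  "NONE" (1) has
    # no defined unit; we follow the ImageJ convention of pixels per
    # micrometre in that case (unit = 1 um).
    1: 1.0,
    2: 25400.0,   # inch
    3: 10000.0,   # centimetre
}


def _pixel_size_from_tags(page: "tifffile.TiffPage") -> float | None:
    tag = page.tags.get("XResolution")
    if tag is None:
        return None
    num, den = tag.value
    if num == 0:
        return None
    px_per_unit = num / den
    unit_tag = page.tags.get("ResolutionUnit")
    unit = int(unit_tag.value) if unit_tag is not None else 1
    if unit == 1 and px_per_unit == 1.0:
        # the (1, 1) unitless default many writers emit when nothing was
        # calibrated; treating it as 1 um/px would silently fabricate lengths
        return None
    um_per_unit = _UM_PER_UNIT.get(unit)
    if um_per_unit is None:
        return None
    return um_per_unit / px_per_unit


def read_stack(
    path,
    pixel_size: float | None = None,
    channel_label: str = "",
) -> ImageStack:
    """Read a single- or multi-page grayscale TIFF as an :class:`ImageStack`.

    Parameters
    ----------
    path : str or Path
        TIFF file.  Pages must be single-channel grayscale.
    pixel_size : float, optional
        Micrometres per pixel.  Overrides any TIFF resolution metadata.
        If omitted, the pixel size is derived from the file's XResolution /
        ResolutionUnit tags (interpreted as pixels per micrometre when the
        unit is unspecified); if that fails a :class:`CalibrationError` is
        raised.

    Raises
    ------
    FileNotFoundError
        Missing file.
    FormatError
        A page is RGB / multi-sample.
    CalibrationError
        No override and no resolvable resolution metadata.
    """
    with tifffile.TiffFile(path) as tif:
        pages = tif.pages
        frames = []
        for i, page in enumerate(pages):
            if page.samplesperpixel != 1:
                raise FormatError(
                    f"page {i} of {path!s} has {page.samplesperpixel} samples "
                    "per pixel; select or pre-extract a single channel"
                )
            frames.append(np.asarray(page.asarray(), dtype=np.float64))
        if pixel_size is None:
            pixel_size = _pixel_size_from_tags(pages[0])
        if pixel_size is None:
            raise CalibrationError(
                f"{path!s}: no pixel-size override and no usable resolution "
                "metadata; physical lengths would be undefined"
            )
    stack = ImageStack(
        frames=np.stack(frames),
        pixel_size=float(pixel_size),
        channel_label=channel_label,
        source_id=str(path),
    )
    logger.info(
        "read_stack: %s -> %d frame(s) of %dx%d, pixel_size=%.4g um/px",
        path, stack.n_frames, *stack.shape, stack.pixel_size,
    )
    return stack


def write_stack(stack: ImageStack, path, dtype=np.float32) -> None:
    """Write an :class:`ImageStack` to TIFF with its resolution recorded.

    The XResolution tag is written as pixels per centimetre, so
    :func:`read_stack` can recover ``pixel_size`` without an override.
    Integer dtypes round-trip bit-exactly.
    """
    data = stack.frames.astype(dtype)
    px_per_cm = 10000.0 / stack.pixel_size
    tifffile.imwrite(
        path, data, photometric="minisblack",
        resolution=(px_per_cm, px_per_cm), resolutionunit=3,
    )


def max_project(stack: ImageStack) -> Image2D:
    """Maximum-intensity projection of a stack.

    Each output pixel is the maximum over frames at that position; the pixel
    size is propagated unchanged.
    """
    proj = stack.frames.max(axis=0)
    logger.info(
        "max_project: %d frame(s) %dx%d -> single frame (max %.4g)",
        stack.n_frames, *stack.shape, proj.max() if proj.size else float("nan"),
    )
    return Image2D(values=proj, pixel_size=stack.pixel_size)


# ---------------------------------------------------------------------------
# Segment tables
# ---------------------------------------------------------------------------

SEGMENT_COLUMNS = ["segment_id", "pixel_count", "length_um", "geodesic_length_um", "image_id"]


def write_segments_table(segments, path) -> None:
    """Write a :class:`~tjquant.skeleton.SegmentSet` as a CSV table.

    One row per segment, ordered by segment id; an empty set yields a
    header-only file.  Both the pixel-count length (the primary metric) and
    the geodesic length are emitted.
    """
    rows = [
        {
            "segment_id": s.id,
            "pixel_count": s.pixel_count,
            "length_um": s.length_um,
            "geodesic_length_um": s.geodesic_length_um,
            "image_id": segments.image_id,
        }
        for s in segments.segments
    ]
    df = pd.DataFrame(rows, columns=SEGMENT_COLUMNS)
    df.sort_values("segment_id", inplace=True, ignore_index=True)
    df.to_csv(path, index=False, float_format="%.6f")
    logger.info("write_segments_table: %d segment(s) -> %s", len(rows), path)


def read_segments_table(path) -> pd.DataFrame:
    """Read back a segment CSV written by :func:`write_segments_table`."""
    return pd.read_csv(path)
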