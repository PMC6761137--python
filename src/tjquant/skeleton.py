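"""Skeletonization, branch-point detection and branch measurement.

The binary junction mask is thinned to 1-px-wide medial curves; skeleton
pixels where three or more branches meet are detected and subtracted, and
the remaining 8-connected components are the continuous membrane segments
whose lengths the whole pipeline exists to measure.

Branch-point rule
-----------------
A skeleton pixel is a junction point iff its 8-neighbourhood contains three
or more skeleton pixels.  This is the classical skeleton-analysis convention
(ImageJ's skeleton tools use it) and the only rule that guarantees the
branches actually separate after subtraction: at a crossing, the pixels
orthogonally adjacent to the centre touch the other arms diagonally, so they
must be removed too.  Consequently a 4-armed cross loses a small cluster of
junction pixels (centre + 4 neighbours), and each arm is shortened by one
pixel.

Detection is implemented as a binary hit-or-miss union: the catalogue of all
3×3 neighbourhood templates with ≥3 foreground neighbours (219 of the 256
possible neighbour configurations) is compiled into a 512-entry lookup table
applied via one bit-encoding convolution.  A literal per-template
``scipy.ndimage.binary_hit_or_miss`` union and a direct neighbour-count are
provided as alternative methods and are exhaustively equivalent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import skeletonize as _skimage_skeletonize

from .ridge import BinaryMask

logger = logging.getLogger("tjquant")

__all__ = [
    "Skeleton",
    "JunctionSet",
    "Segment",
    "SegmentSet",
    "skeletonize",
    "detect_junctions",
    "remove_junctions",
    "measure_branches",
]

_EIGHT = np.ones((3, 3), dtype=int)  # 8-connectivity structuring element
_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=np.uint16)

# Bit positions for encoding a 3x3 neighbourhood (row-major, centre = bit 4).
_BIT_KERNEL = (2 ** np.arange(9, dtype=np.uint16)).reshape(3, 3)


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class Skeleton:
    """1-px-wide boolean medial curves of a binary mask."""

    values: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.dtype != bool or self.values.ndim != 2:
            raise ValueError("skeleton values must be a 2-D boolean grid")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


@dataclass
class JunctionSet:
    """Coordinates of skeleton branch points (row, col), raster-ordered."""

    coords: np.ndarray  # (n, 2) int array

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=int).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.coords)

    def as_mask(self, shape: tuple[int, int]) -> np.ndarray:
        mask = np.zeros(shape, dtype=bool)
        if len(self.coords):
            mask[self.coords[:, 0], self.coords[:, 1]] = True
        return mask

    def n_clusters(self) -> int:
        """Number of 8-connected clusters of junction pixels.

        Branch points at a single geometric vertex typically form one small
        cluster; this is the natural count of distinct junction sites.
        """
        if not len(self.coords):
            return 0
        rmax, cmax = self.coords.max(axis=0)
        _, n = ndi.label(self.as_mask((rmax + 2, cmax + 2)), structure=_EIGHT)
        return int(n)


@dataclass
class Segment:
    """One continuous membrane segment (an 8-connected skeleton branch)."""

    id: int
    pixel_count: int
    length_um: float
    geodesic_length_um: float
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=int).reshape(-1, 2)


@dataclass
class SegmentSet:
    """The measured segments of one image plus bookkeeping for conservation.

    ``length_um`` of each segment is ``pixel_count * pixel_size`` (the
    primary metric, mirroring particle-size measurement on a 1-px skeleton);
    ``geodesic_length_um`` additionally weights diagonal steps by √2 and is
    the better estimator of Euclidean length.  ``discarded_px`` counts the
    pixels of branches shorter than the minimum branch size, so that
    ``|skeleton| = |junctions| + Σ pixel_count + discarded_px`` always holds.
    """

    segments: list[Segment] = field(default_factory=list)
    image_id: str = ""
    pixel_size: float = 1.0
    discarded_px: int = 0

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def lengths_um(self) -> np.ndarray:
        return np.array([s.length_um for s in self.segments], dtype=float)

    @property
    def geodesic_lengths_um(self) -> np.ndarray:
        return np.array([s.geodesic_length_um for s in self.segments], dtype=float)

    @property
    def total_pixels(self) -> int:
        return int(sum(s.pixel_count for s in self.segments))


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def skeletonize(mask: BinaryMask) -> Skeleton:
    """Morphological thinning to 1-px-wide, connectivity-preserving curves."""
    skel = _skimage_skeletonize(mask.values)
    logger.info(
        "skeletonize: %d mask px -> %d skeleton px", int(mask.values.sum()), int(skel.sum())
    )
    return Skeleton(values=skel, pixel_size=mask.pixel_size)


def _branch_point_lut() -> np.ndarray:
    """LUT over 9-bit neighbourhood codes: centre on and ≥3 neighbours on."""
    codes = np.arange(512, dtype=np.uint16)
    center_on = (codes >> 4) & 1
    neighbor_bits = codes & ~np.uint16(1 << 4)
    popcount = np.zeros(512, dtype=np.uint16)
    for b in range(9):
        if b != 4:
            popcount += (neighbor_bits >> b) & 1
    return (center_on == 1) & (popcount >= 3)


_BRANCH_LUT = _branch_point_lut()


def _junctions_lut(skel: np.ndarray) -> np.ndarray:
    """Catalogue hit-or-miss via one bit-encoding convolution + table lookup."""
    codes = ndi.convolve(skel.astype(np.uint16), _BIT_KERNEL, mode="constant", cval=0)
    return _BRANCH_LUT[codes]


def _junctions_neighbor_count(skel: np.ndarray) -> np.ndarray:
    neighbors = ndi.convolve(skel.astype(np.uint16), _NEIGHBOR_KERNEL, mode="constant", cval=0)
    return skel & (neighbors >= 3)


def _junctions_hit_or_miss_literal(skel: np.ndarray) -> np.ndarray:
    """Union of scipy ``binary_hit_or_miss`` over every catalogue template.

    One erosion pair per template (219 templates); exact but two orders of
    magnitude slower than the LUT form — kept as an independent
    implementation for cross-checking.
    """
    out = np.zeros_like(skel, dtype=bool)
    for code in np.nonzero(_BRANCH_LUT)[0]:
        pattern = (code >> np.arange(9)) & 1
        template = pattern.reshape(3, 3).astype(bool)
        hit = template.astype(int)
        miss = (~template).astype(int)
        out |= ndi.binary_hit_or_miss(skel, structure1=hit, structure2=miss)
    return out


_JUNCTION_METHODS = {
    "hit-or-miss": _junctions_lut,
    "hit-or-miss-literal": _junctions_hit_or_miss_literal,
    "neighbor-count": _junctions_neighbor_count,
}


def detect_junctions(skeleton: Skeleton, method: str = "hit-or-miss") -> JunctionSet:
    """Detect branch points: skeleton pixels with ≥3 skeleton neighbours.

    ``method`` selects among equivalent implementations: the table-driven
    hit-or-miss union (default), a literal per-template scipy hit-or-miss
    union, or direct neighbour counting.  All three return identical sets on
    every input.
    """
    try:
        fn = _JUNCTION_METHODS[method]
    except KeyError:
        raise ValueError(f"unknown junction detection method {method!r}") from None
    mask = fn(skeleton.values)
    coords = np.argwhere(mask)
    logger.info("detect_junctions(%s): %d junction px", method, len(coords))
    return JunctionSet(coords=coords)


def remove_junctions(skeleton: Skeleton, junctions: JunctionSet) -> BinaryMask:
    """Subtract junction pixels from the skeleton.

    The result has exactly ``|skeleton| - |junctions|`` foreground pixels;
    a junction coordinate off the skeleton is a consistency error.
    """
    skel = skeleton.values
    out = skel.copy()
    if len(junctions):
        rows, cols = junctions.coords[:, 0], junctions.coords[:, 1]
        if (
            rows.min() < 0 or cols.min() < 0
            or rows.max() >= skel.shape[0] or cols.max() >= skel.shape[1]
            or not np.all(skel[rows, cols])
        ):
            raise ValueError("junction coordinates must lie on the skeleton")
        out[rows, cols] = False
    return BinaryMask(values=out, pixel_size=skeleton.pixel_size)


def measure_branches(
    branch_mask: BinaryMask,
    min_branch_px: int = 3,
    image_id: str = "",
) -> SegmentSet:
    """Label and measure the junction-free skeleton branches.

    8-connected components are labelled in raster order of their first
    pixel; components smaller than ``min_branch_px`` pixels are discarded
    (their pixel total is retained in ``discarded_px``).  Each surviving
    component becomes a segment with ``length_um = pixel_count *
    pixel_size`` plus a geodesic length.
    """
    if min_branch_px < 1:
        raise ValueError("min_branch_px must be >= 1")
    values = branch_mask.values
    ps = branch_mask.pixel_size
    labels, n_labels = ndi.label(values, structure=_EIGHT)
    if n_labels == 0:
        return SegmentSet(segments=[], image_id=image_id, pixel_size=ps)

    counts = np.bincount(labels.ravel())[1:]
    # scipy labels in raster order of first pixel already; make it explicit
    # so the output contract does not depend on scipy internals.
    flat_first = np.full(n_labels, np.iinfo(np.int64).max, dtype=np.int64)
    flat_idx = np.flatnonzero(values.ravel())
    np.minimum.at(flat_first, labels.ravel()[flat_idx] - 1, flat_idx)
    order = np.argsort(flat_first, kind="stable")

    geodesic = np.zeros(n_labels + 1, dtype=float)
    for pairs, weight in (
        ((labels[:-1, :], labels[1:, :]), 1.0),
        ((labels[:, :-1], labels[:, 1:]), 1.0),
        ((labels[:-1, :-1], labels[1:, 1:]), np.sqrt(2.0)),
        ((labels[:-1, 1:], labels[1:, :-1]), np.sqrt(2.0)),
    ):
        a, b = pairs
        same = (a > 0) & (a == b)
        np.add.at(geodesic, a[same], weight)

    objects = ndi.find_objects(labels)
    segments: list[Segment] = []
    discarded = 0
    next_id = 0
    for lab in order:  # lab is 0-based label index
        count = int(counts[lab])
        if count < min_branch_px:
            discarded += count
            continue
        sl = objects[lab]
        local = labels[sl] == (lab + 1)
        coords = np.argwhere(local) + [sl[0].start, sl[1].start]
        segments.append(
            Segment(
                id=next_id,
                pixel_count=count,
                length_um=count * ps,
                geodesic_length_um=float(geodesic[lab + 1]) * ps,
                coords=coords,
            )
        )
        next_id += 1
    logger.info(
        "measure_branches: %d component(s) -> %d segment(s), %d px discarded "
        "(< %d px)",
        n_labels, len(segments), discarded, min_branch_px,
    )
    return SegmentSet(
        segments=segments, image_id=image_id, pixel_size=ps, discarded_px=discarded
    )
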