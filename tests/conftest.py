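"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from tjquant.ridge import BinaryMask
from tjquant.skeleton import Segment, SegmentSet, Skeleton


# ---------------------------------------------------------------------------
# Canonical skeleton fixtures
# ---------------------------------------------------------------------------

def make_plus(arm: int = 5) -> np.ndarray:
    """Plus-shaped skeleton: centre pixel with 4 orthogonal arms."""
    size = 2 * arm + 3
    grid = np.zeros((size, size), dtype=bool)
    c = size // 2
    grid[c, c - arm: c + arm + 1] = True
    grid[c - arm: c + arm + 1, c] = True
    return grid


def make_line(n: int = 15) -> np.ndarray:
    grid = np.zeros((5, n + 4), dtype=bool)
    grid[2, 2: 2 + n] = True
    return grid


def make_loop(radius: int = 10) -> np.ndarray:
    """Closed ring, thinned to a 1-px loop."""
    from skimage.draw import disk
    from skimage.morphology import skeletonize as _sk

    size = 2 * radius + 9
    grid = np.zeros((size, size), dtype=bool)
    c = size // 2
    rr, cc = disk((c, c), radius)
    grid[rr, cc] = True
    rr, cc = disk((c, c), radius - 4)
    grid[rr, cc] = False
    return _sk(grid)


def random_sparse_skeleton(rng: np.random.Generator, shape=(24, 24), p=0.18) -> np.ndarray:
    return rng.random(shape) < p


def random_blob_mask(rng: np.random.Generator, shape=(48, 48)) -> np.ndarray:
    """Smooth random field thresholded into blobby foreground."""
    from scipy import ndimage as ndi

    field = ndi.gaussian_filter(rng.normal(size=shape), 3.0)
    return field > np.quantile(field, 0.7)


def as_skeleton(grid: np.ndarray, pixel_size: float = 1.0) -> Skeleton:
    return Skeleton(values=np.asarray(grid, dtype=bool), pixel_size=pixel_size)


def as_mask(grid: np.ndarray, pixel_size: float = 1.0) -> BinaryMask:
    return BinaryMask(values=np.asarray(grid, dtype=bool), pixel_size=pixel_size)


def segset_from_lengths(lengths, pixel_size: float = 1.0, image_id: str = "") -> SegmentSet:
    """Build a SegmentSet carrying given physical lengths (for statistics tests)."""
    segments = [
        Segment(
            id=i,
            pixel_count=max(int(round(l / pixel_size)), 1),
            length_um=float(l),
            geodesic_length_um=float(l),
            coords=np.zeros((1, 2), dtype=int),
        )
        for i, l in enumerate(lengths)
    ]
    return SegmentSet(segments=segments, image_id=image_id, pixel_size=pixel_size)


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def brute_force_junctions(skel: np.ndarray) -> np.ndarray:
    """Per-pixel neighbour counting with an explicit python loop."""
    out = np.zeros_like(skel, dtype=bool)
    rows, cols = skel.shape
    for r in range(rows):
        for c in range(cols):
            if not skel[r, c]:
                continue
            n = 0
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < rows and 0 <= cc < cols and skel[rr, cc]:
                        n += 1
            out[r, c] = n >= 3
    return out


def brute_force_otsu(values: np.ndarray, nbins: int = 256) -> float:
    """Exhaustive search over all histogram split points."""
    values = np.asarray(values, dtype=float).ravel()
    counts, edges = np.histogram(values, bins=nbins, range=(values.min(), values.max()))
    centers = 0.5 * (edges[:-1] + edges[1:])
    best_var, best_thr = -np.inf, None
    for k in range(nbins - 1):
        w0 = counts[: k + 1].sum()
        w1 = counts[k + 1:].sum()
        # canonical candidates: split directly after a non-empty bin (splits
        # through empty-bin runs yield the identical data partition)
        if w0 == 0 or w1 == 0 or counts[k] == 0:
            continue
        mu0 = (counts[: k + 1] * centers[: k + 1]).sum() / w0
        mu1 = (counts[k + 1:] * centers[k + 1:]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_thr = var, centers[k]
    return float(best_thr)


_U_NULL_CACHE: dict[tuple[int, int], np.ndarray] = {}


def exact_u_null(n_a: int, n_b: int) -> np.ndarray:
    """All C(n_a+n_b, n_a) values of U(group a) under the null (tie-free)."""
    key = (n_a, n_b)
    if key not in _U_NULL_CACHE:
        n = n_a + n_b
        ranks = np.array(
            list(itertools.combinations(range(1, n + 1), n_a)), dtype=float
        )
        _U_NULL_CACHE[key] = ranks.sum(axis=1) - n_a * (n_a + 1) / 2.0
    return _U_NULL_CACHE[key]


def enumeration_p_value(a, b) -> tuple[float, float]:
    """Two-sided exact Mann-Whitney p by full enumeration (tie-free input).

    Counts permutations whose U is at least as far from the null mean as the
    observed U (equivalent to twice the smaller tail, by symmetry).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    u_obs = float(sum((x > y) for x in a for y in b))
    null = exact_u_null(len(a), len(b))
    mean = len(a) * len(b) / 2.0
    p = float(np.mean(np.abs(null - mean) >= abs(u_obs - mean) - 1e-12))
    return u_obs, p


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20251001)
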