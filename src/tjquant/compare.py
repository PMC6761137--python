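"""Length histograms, large-segment abundance, and rank-sum comparison.

Fragmentation shifts the segment-length distribution toward short pieces,
so conditions are compared by the abundance of *large* segments — those with
length strictly inside a window (x µm, y µm).  The sampling unit is the
image: per-image large-segment counts from two conditions are compared with
a two-sided Mann-Whitney U test (exact null distribution for small,
tie-free samples; normal approximation with tie correction otherwise).

The window (x, y) is deliberately configuration, defaulting to 5–100 µm;
the full histogram is always available so conclusions can be re-checked
under other windows.  Comparing pooled per-segment lengths instead of
per-image counts is possible (``pooled=True``) but treats segments from one
image as independent replicates — pseudo-replication — and is off by
default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .skeleton import SegmentSet

logger = logging.getLogger("tjquant")

__all__ = [
    "LengthHistogram",
    "GroupComparison",
    "length_histogram",
    "large_segment_count",
    "mann_whitney",
    "compare_conditions",
    "LARGE_WINDOW_UM",
]

#: Default (x, y) window in µm for "large" segments.
LARGE_WINDOW_UM = (5.0, 100.0)

#: Use the exact U null distribution up to this combined sample size.
EXACT_CUTOFF = 20


@dataclass
class LengthHistogram:
    """Histogram of segment lengths over half-open bins [e_i, e_{i+1})."""

    bin_edges: np.ndarray
    counts: np.ndarray
    n_total: int
    n_excluded: int = 0

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)


@dataclass
class GroupComparison:
    """Two-sided rank-sum comparison of a per-image metric between groups.

    ``u_statistic`` is U for group a — the number of (a, b) pairs with
    a > b (ties counted half).  ``method`` records whether the p-value came
    from the exact null distribution or the tie-corrected normal
    approximation.
    """

    metric_name: str
    group_a_values: list
    group_b_values: list
    u_statistic: float
    p_value: float
    method: str
    large_window: tuple[float, float] | None = None


def length_histogram(segments: SegmentSet, bin_edges) -> LengthHistogram:
    """Bin segment lengths (µm) into half-open bins [e_i, e_{i+1}).

    Lengths outside [first edge, last edge) are excluded from the counts but
    tallied in ``n_excluded``.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or not np.all(np.diff(edges) > 0):
        raise ValueError("bin_edges must be >= 2 strictly increasing values")
    lengths = segments.lengths_um
    idx = np.digitize(lengths, edges, right=False)  # 1..nbins inside range
    inside = (idx >= 1) & (idx <= len(edges) - 1) & (lengths < edges[-1])
    counts = np.bincount(idx[inside] - 1, minlength=len(edges) - 1)
    return LengthHistogram(
        bin_edges=edges,
        counts=counts,
        n_total=int(inside.sum()),
        n_excluded=int(len(lengths) - inside.sum()),
    )


def large_segment_count(segments: SegmentSet, x: float, y: float) -> int:
    """Number of segments with x < length_um < y (strict inequalities)."""
    if not (0 <= x < y):
        raise ValueError(f"need 0 <= x < y, got x={x}, y={y}")
    lengths = segments.lengths_um
    return int(np.sum((lengths > x) & (lengths < y)))


def mann_whitney(group_a, group_b, metric_name: str = "value") -> GroupComparison:
    """Two-sided Mann-Whitney U test between two independent samples.

    The exact null distribution is used whenever n_a + n_b <= 20 and the
    pooled data are tie-free; otherwise the normal approximation with tie
    correction (and continuity correction) is used.  The choice is recorded
    in ``method``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    tie_free = len(np.unique(pooled)) == len(pooled)
    if tie_free and (a.size + b.size) <= EXACT_CUTOFF:
        method = "exact"
    else:
        method = "normal-approx"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided",
        method="exact" if method == "exact" else "asymptotic",
    )
    logger.info(
        "mann_whitney(%s): n=%d vs %d, U=%.1f, p=%.4g (%s)",
        metric_name, a.size, b.size, res.statistic, res.pvalue, method,
    )
    return GroupComparison(
        metric_name=metric_name,
        group_a_values=list(a),
        group_b_values=list(b),
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method=method,
    )


def compare_conditions(
    condition_a: list[SegmentSet],
    condition_b: list[SegmentSet],
    x: float = LARGE_WINDOW_UM[0],
    y: float = LARGE_WINDOW_UM[1],
    pooled: bool = False,
) -> GroupComparison:
    """Compare large-segment abundance between two conditions.

    The per-image large-segment count (x < length < y) is the metric and
    each image is one sampling unit.  With ``pooled=True`` the raw segment
    lengths are pooled across images instead — statistically weaker
    (pseudo-replication), provided only for sensitivity checks.
    """
    if len(condition_a) < 1 or len(condition_b) < 1:
        raise ValueError("each condition needs at least one image")
    if pooled:
        vals_a = np.concatenate([s.lengths_um for s in condition_a])
        vals_b = np.concatenate([s.lengths_um for s in condition_b])
        metric = "pooled_segment_length_um"
    else:
        vals_a = [large_segment_count(s, x, y) for s in condition_a]
        vals_b = [large_segment_count(s, x, y) for s in condition_b]
        metric = "large_segment_count"
    comparison = mann_whitney(vals_a, vals_b, metric_name=metric)
    comparison.large_window = (x, y)
    return comparison
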