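"""End-to-end quantification: stack in, measured segments out.

Mirrors the junction-integrity macro stage by stage: maximum-intensity
projection, Hessian ridge enhancement, binarization, skeletonization,
branch-point subtraction, branch measurement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .compare import LARGE_WINDOW_UM
from .imaging_io import Image2D, ImageStack, max_project
from .ridge import binarize, hessian_ridge
from .skeleton import (
    JunctionSet,
    SegmentSet,
    Skeleton,
    detect_junctions,
    measure_branches,
    remove_junctions,
    skeletonize,
)

logger = logging.getLogger("tjquant")

__all__ = ["QuantifyConfig", "quantify_image", "quantify_stack"]


@dataclass
class QuantifyConfig:
    """Tunable pipeline parameters (all lengths in pixels unless noted)."""

    scale_sigma: float = 1.5
    threshold_method: str = "otsu"
    fixed_threshold: float | None = None
    min_branch_px: int = 3
    large_min_um: float = LARGE_WINDOW_UM[0]
    large_max_um: float = LARGE_WINDOW_UM[1]
    bin_edges_um: list = field(
        default_factory=lambda: [0, 1, 2, 3, 5, 8, 12, 20, 50, 100]
    )


@dataclass
class QuantifyResult:
    """Segments plus the intermediate stages, for inspection and QC."""

    segments: SegmentSet
    skeleton: Skeleton
    junctions: JunctionSet


def quantify_image(
    image: Image2D, config: QuantifyConfig | None = None, image_id: str = ""
) -> QuantifyResult:
    """Run ridge enhancement through branch measurement on one projection."""
    cfg = config or QuantifyConfig()
    ridge = hessian_ridge(image, scale_sigma=cfg.scale_sigma)
    mask = binarize(ridge, method=cfg.threshold_method, fixed_threshold=cfg.fixed_threshold)
    skel = skeletonize(mask)
    junctions = detect_junctions(skel)
    branches = remove_junctions(skel, junctions)
    segments = measure_branches(branches, min_branch_px=cfg.min_branch_px, image_id=image_id)
    return QuantifyResult(segments=segments, skeleton=skel, junctions=junctions)


def quantify_stack(
    stack: ImageStack, config: QuantifyConfig | None = None, image_id: str | None = None
) -> QuantifyResult:
    """Maximum-intensity projection followed by :func:`quantify_image`."""
    projection = max_project(stack)
    return quantify_image(
        projection, config, image_id=image_id if image_id is not None else stack.source_id
    )
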