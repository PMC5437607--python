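"""Zonal partition of meniscus ROIs.

Horizontal zoning splits an ROI into the superficial zone — the first layer
of pixels along the meniscal surface, i.e. every ROI pixel with at least one
of its 8 neighbors outside the ROI — and the deep zone (the remainder).
Equivalently, superficial = ROI minus its 3x3 erosion.

Vertical zoning divides a horn ROI into thirds from the avascular free
(inner) edge to the vascularized periphery: white (inner 1/3), red-white
(middle 1/3) and red (outer 1/3). Each pixel's normalized position
``u = d_free / (d_free + d_periph)`` uses geodesic (within-ROI,
Euclidean-weighted) distances to the two edges; zone cuts at u = 1/3 and
2/3 are half-open with ties going outward. Superficial pixels participate
in the vertical zones. Vertical zoning applies to anterior/posterior horns
only, not the meniscal body.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
from scipy import ndimage
from skimage.graph import MCP_Geometric

from .image_io import RoiMask, Segment

OUTSIDE = 0


class HorizontalZone(IntEnum):
    SUPERFICIAL = 1
    DEEP = 2


class VerticalZone(IntEnum):
    WHITE = 1
    RED_WHITE = 2
    RED = 3


@dataclass
class ZoneLabelMap:
    """Per-pixel zone labels for one ROI (0 = outside the ROI)."""

    horizontal: np.ndarray | None = None
    vertical: np.ndarray | None = None
    source_roi: RoiMask | None = None
    flags: list[str] = field(default_factory=list)

    def zone_mask(self, zone) -> np.ndarray:
        if isinstance(zone, HorizontalZone):
            if self.horizontal is None:
                raise ValueError("horizontal labels not computed")
            return self.horizontal == int(zone)
        if isinstance(zone, VerticalZone):
            if self.vertical is None:
                raise ValueError("vertical labels not computed")
            return self.vertical == int(zone)
        raise TypeError(f"unknown zone {zone!r}")


def horizontal_zones(roi: RoiMask, connectivity: int = 8) -> ZoneLabelMap:
    """Label the ROI's superficial (surface layer) and deep pixels.

    ``connectivity`` selects the neighborhood that defines the surface
    layer: 8 (default, 3x3 erosion) or 4 (cross erosion).
    """
    mask = roi.mask
    if not mask.any():
        raise ValueError("horizontal zoning requires a non-empty ROI")
    if connectivity == 8:
        structure = np.ones((3, 3), bool)
    elif connectivity == 4:
        structure = ndimage.generate_binary_structure(2, 1)
    else:
        raise ValueError("connectivity must be 4 or 8")
    interior = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    labels = np.zeros(mask.shape, dtype=np.int8)
    labels[mask & ~interior] = int(HorizontalZone.SUPERFICIAL)
    labels[interior] = int(HorizontalZone.DEEP)
    zmap = ZoneLabelMap(horizontal=labels, source_roi=roi)
    if not interior.any():
        zmap.flags.append("deep zone empty (ROI is one pixel thick)")
    return zmap


def boundary_pixels(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Boolean raster of ROI pixels touching the outside (surface layer)."""
    structure = (
        np.ones((3, 3), bool) if connectivity == 8 else ndimage.generate_binary_structure(2, 1)
    )
    return mask & ~ndimage.binary_erosion(mask, structure=structure, border_value=0)


def geodesic_distance(mask: np.ndarray, sources: np.ndarray) -> np.ndarray:
    """Shortest within-ROI path length (8-connected, Euclidean step
    weights) from each ROI pixel to the nearest source pixel. Pixels
    unreachable from the sources get +inf."""
    mask = np.asarray(mask, bool)
    sources = np.asarray(sources, bool)
    costs = np.where(mask, 1.0, np.inf)
    mcp = MCP_Geometric(costs)
    starts = np.argwhere(sources & mask)
    if starts.size == 0:
        raise ValueError("no source pixels inside the ROI")
    cum, _ = mcp.find_costs(starts)
    out = np.where(mask, cum, np.inf)
    return out


def vertical_zones(
    roi: RoiMask,
    free_edge: np.ndarray,
    periphery: np.ndarray,
) -> ZoneLabelMap:
    """Partition a horn ROI into white / red-white / red thirds.

    ``free_edge`` and ``periphery`` are boolean rasters of boundary pixels
    (nonempty, disjoint, inside the ROI).
    """
    if roi.segment not in (Segment.AH, Segment.PH):
        raise ValueError(
            "vertical zoning applies to anterior/posterior horns only, "
            f"not {roi.segment.value}"
        )
    mask = roi.mask
    free_edge = np.asarray(free_edge, bool)
    periphery = np.asarray(periphery, bool)
    if not (free_edge & mask).any() or not (periphery & mask).any():
        raise ValueError("free_edge and periphery must be nonempty subsets of the ROI")
    if (free_edge & periphery).any():
        raise ValueError("free_edge and periphery must be disjoint")

    d_free = geodesic_distance(mask, free_edge)
    d_per = geodesic_distance(mask, periphery)
    labels = np.zeros(mask.shape, dtype=np.int8)
    zmap = ZoneLabelMap(vertical=labels, source_roi=roi)

    total = d_free + d_per
    finite = mask & np.isfinite(total)
    if (mask & ~finite).any():
        warnings.warn("ROI pixels unreachable from both edges; labelled red")
        zmap.flags.append("unreachable pixels labelled red")
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.where(finite, d_free / np.where(total > 0, total, 1.0), 1.0)
    labels[mask] = int(VerticalZone.RED)
    labels[mask & (u < 2.0 / 3.0)] = int(VerticalZone.RED_WHITE)
    labels[mask & (u < 1.0 / 3.0)] = int(VerticalZone.WHITE)
    return zmap


def infer_edges(
    roi: RoiMask,
    joint_center: tuple[float, float],
    min_spread_px: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Split the ROI boundary into free-edge and periphery candidate sets.

    The meniscal free edge faces the joint center, the periphery faces away
    from it: boundary pixels nearer the joint center than the median
    boundary distance become free-edge candidates, the rest periphery.
    A degenerate ROI whose boundary is essentially equidistant from the
    joint center (spread below ``min_spread_px``) cannot be split this way
    and raises; the caller must then supply edges explicitly.
    """
    mask = roi.mask
    if not mask.any():
        raise ValueError("empty ROI")
    boundary = boundary_pixels(mask)
    coords = np.argwhere(boundary)
    d = np.hypot(coords[:, 0] - joint_center[0], coords[:, 1] - joint_center[1])
    if d.max() - d.min() < min_spread_px:
        raise ValueError(
            "ROI boundary is equidistant from the joint center; "
            "supply free_edge/periphery explicitly"
        )
    med = np.median(d)
    free_edge = np.zeros(mask.shape, bool)
    periphery = np.zeros(mask.shape, bool)
    near = d < med
    if not near.any() or near.all():
        # median fell on an extreme; split at the midpoint of the range
        near = d < (d.min() + d.max()) / 2.0
    free_edge[tuple(coords[near].T)] = True
    periphery[tuple(coords[~near].T)] = True
    return free_edge, periphery
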