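"""Synthetic meniscus phantom: complete simulated relaxometry studies.

The generator emits everything the analysis pipeline consumes — multi-TSL
and multi-TE magnitude series, per-segment ROI masks for several simulated
observers/sessions, and a ground-truth record — so every stage is testable
without clinical data.

Geometry is an annular ("crescent") sector per meniscus side on each
sagittal slice; the arc is split into equal angular thirds for the anterior
horn, body and posterior horn. Ground-truth relaxation times are assigned
per zone using the same partition rules the analysis applies (horizontal
superficial/deep on the whole side; vertical thirds on the horns), which
guarantees the truth is recoverable. Pixel signals are magnitude-MRI
(Rician) draws around S0*exp(-t/T); optional per-frame rigid motion and
observer boundary jitter emulate patient movement and manual-segmentation
variability.

Default acquisition grids are a 4-point spin-lock series (20/40/60/80 ms)
and a 7-echo series (13-91 ms) at S0 = 500 with noise sigma = S0/50
(SNR 50). Default zonal ground truths are the reference zonal means this
simulator is designed to reproduce (see ``DEFAULT_HORIZONTAL_TRUTHS_MS``
and ``DEFAULT_VERTICAL_TRUTHS_MS``).

All randomness derives from the single spec seed through named substreams
(geometry, noise, motion, jitter, invalid), so a fixed seed yields
byte-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.measure import label as cc_label

from .image_io import ImageSeries, Modality, RoiMask, Segment, Side
from .registration import RigidTransform2D, apply_transform
from .zones import (
    HorizontalZone,
    VerticalZone,
    ZoneLabelMap,
    horizontal_zones,
    infer_edges,
    vertical_zones,
)

TSL_MS = (20.0, 40.0, 60.0, 80.0)
TE_MS = (13.0, 26.0, 39.0, 52.0, 65.0, 78.0, 91.0)

SEQUENCES = {
    "bFFE_T1rho": (Modality.T1RHO, TSL_MS),
    "SPGR_T1rho": (Modality.T1RHO, TSL_MS),
    "T2": (Modality.T2, TE_MS),
}

# (superficial, deep) ms per sequence and side
DEFAULT_HORIZONTAL_TRUTHS_MS = {
    ("bFFE_T1rho", "MM"): (84.3, 76.0),
    ("bFFE_T1rho", "LM"): (80.0, 74.0),
    ("SPGR_T1rho", "MM"): (96.5, 91.7),
    ("SPGR_T1rho", "LM"): (93.5, 90.0),
    ("T2", "MM"): (80.4, 74.4),
    ("T2", "LM"): (77.0, 72.0),
}

# (white, red-white, red) ms per sequence, side and horn
DEFAULT_VERTICAL_TRUTHS_MS = {
    ("bFFE_T1rho", "MM", "PH"): (88.4, 82.7, 77.1),
    ("bFFE_T1rho", "MM", "AH"): (86.0, 81.5, 77.0),
    ("bFFE_T1rho", "LM", "AH"): (84.0, 80.0, 76.0),
    ("bFFE_T1rho", "LM", "PH"): (80.0, 78.0, 76.0),
    ("SPGR_T1rho", "MM", "PH"): (104.9, 100.8, 96.8),
    ("SPGR_T1rho", "MM", "AH"): (102.0, 98.0, 94.0),
    ("SPGR_T1rho", "LM", "AH"): (100.0, 96.5, 93.0),
    ("SPGR_T1rho", "LM", "PH"): (98.0, 95.5, 93.0),
    ("T2", "MM", "PH"): (96.8, 90.5, 84.3),
    ("T2", "MM", "AH"): (82.0, 78.0, 74.0),
    ("T2", "LM", "AH"): (104.6, 94.4, 84.2),
    ("T2", "LM", "PH"): (75.0, 80.0, 85.0),
}


class PhantomSpecError(ValueError):
    pass


@dataclass
class PhantomSpec:
    """Full generative description of one synthetic study subject."""

    grid: tuple[int, int] = (128, 128)
    n_slices: int = 3
    inner_radius: float = 13.0
    outer_radius: float = 23.0
    arc_deg: tuple[float, float] = (-30.0, 210.0)
    side_centers: dict = field(
        default_factory=lambda: {"LM": (64.0, 34.0), "MM": (64.0, 94.0)}
    )
    s0: float = 500.0
    noise_sigma: float = 10.0  # SNR = s0 / sigma = 50
    sequences: tuple[str, ...] = tuple(SEQUENCES)
    horizontal_truths: dict = field(
        default_factory=lambda: dict(DEFAULT_HORIZONTAL_TRUTHS_MS)
    )
    vertical_truths: dict = field(
        default_factory=lambda: dict(DEFAULT_VERTICAL_TRUTHS_MS)
    )
    # which zoning family drives the per-pixel truth in each (side, segment)
    truth_basis: dict = field(default_factory=dict)  # default: horizontal
    motion_max_shift_px: float = 0.0
    motion_max_rot_deg: float = 0.0
    observer_jitter: float = 0.02
    invalid_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.inner_radius >= self.outer_radius:
            raise PhantomSpecError("inner radius must be smaller than outer radius")
        if self.inner_radius <= 0:
            raise PhantomSpecError("radii must be positive")
        if self.n_slices < 1:
            raise PhantomSpecError("need at least one slice")
        for truths in (self.horizontal_truths, self.vertical_truths):
            for key, vals in truths.items():
                if any(v <= 0 for v in vals):
                    raise PhantomSpecError(f"non-positive relaxation truth at {key}")
        if not (0.0 <= self.observer_jitter <= 0.5):
            raise PhantomSpecError("observer_jitter must be in [0, 0.5]")
        if self.noise_sigma < 0:
            raise PhantomSpecError("noise_sigma must be >= 0")

    def basis_for(self, side: str, segment: str) -> str:
        return self.truth_basis.get((side, segment), "horizontal")


@dataclass
class GroundTruth:
    """Generator bookkeeping: everything needed to verify recovery."""

    side_masks: dict  # (side, slice) -> bool raster
    segment_masks: dict  # (side, segment, slice) -> bool raster
    horizontal_labels: dict  # (side, slice) -> ZoneLabelMap
    vertical_labels: dict  # (side, segment, slice) -> ZoneLabelMap (horns)
    t_maps: dict  # (sequence, slice) -> true T raster (ms)
    transforms: dict  # (sequence, slice) -> list[RigidTransform2D]
    forced_invalid: dict  # (sequence, slice) -> bool raster
    zone_true_means: dict  # (sequence, side, segment, zone_name) -> ms
    joint_centers: dict  # side -> (row, col)


@dataclass
class PhantomStudy:
    spec: PhantomSpec
    series: dict  # (sequence, slice) -> ImageSeries
    masks: list  # RoiMask for observers R1/S1, R1/S2, R2/S1
    ground_truth: GroundTruth


# ---------------------------------------------------------------------------
# noise


def add_rician_noise(clean: np.ndarray, sigma: float, rng=None, seed=None) -> np.ndarray:
    """Magnitude-MRI noise: sqrt((v + g1)^2 + g2^2), g1, g2 ~ N(0, sigma)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    clean = np.asarray(clean, float)
    if sigma == 0:
        return clean.copy()
    if rng is None:
        rng = np.random.default_rng(seed)
    g1 = rng.normal(0.0, sigma, clean.shape)
    g2 = rng.normal(0.0, sigma, clean.shape)
    return np.sqrt((clean + g1) ** 2 + g2**2)


def simulate_decay_pixels(
    t_relax_ms: float,
    n_pixels: int,
    times_ms,
    s0: float = 500.0,
    noise_sigma: float = 10.0,
    seed: int | None = None,
    rng=None,
) -> np.ndarray:
    """Rician-noise monoexponential decays for ``n_pixels`` independent
    pixels sharing one ground truth; shape (n_pixels, n_times)."""
    times = np.asarray(times_ms, float)
    clean = s0 * np.exp(-times[None, :] / float(t_relax_ms))
    clean = np.broadcast_to(clean, (n_pixels, times.size))
    return add_rician_noise(clean, noise_sigma, rng=rng, seed=seed)


# ---------------------------------------------------------------------------
# geometry


def _crescent_mask(spec: PhantomSpec, side: str) -> tuple[np.ndarray, np.ndarray]:
    """Annular-sector mask for one side plus each pixel's arc position in
    [0, 1) measured from the arc start."""
    rows, cols = spec.grid
    cy, cx = spec.side_centers[side]
    rr, cc = np.mgrid[0:rows, 0:cols].astype(float)
    dy, dx = rr - cy, cc - cx
    radius = np.hypot(dy, dx)
    ang = np.rad2deg(np.arctan2(dy, dx))
    a0, a1 = spec.arc_deg
    span = a1 - a0
    rel = (ang - a0) % 360.0
    mask = (
        (radius >= spec.inner_radius)
        & (radius <= spec.outer_radius)
        & (rel <= span)
    )
    arcpos = np.where(mask, np.clip(rel / span, 0.0, 1.0 - 1e-12), 0.0)
    return mask, arcpos


def _segment_masks(mask: np.ndarray, arcpos: np.ndarray) -> dict:
    """Split a side mask into AH / BD / PH by equal angular thirds."""
    out = {}
    out["AH"] = mask & (arcpos < 1.0 / 3.0)
    out["BD"] = mask & (arcpos >= 1.0 / 3.0) & (arcpos < 2.0 / 3.0)
    out["PH"] = mask & (arcpos >= 2.0 / 3.0)
    return out


# ---------------------------------------------------------------------------
# observer jitter


def simulate_observer_masks(
    mask: RoiMask | np.ndarray,
    jitter: float,
    seed: int | None = None,
    rng=None,
    observer: str = "R2",
    session: str = "S1",
) -> RoiMask | np.ndarray:
    """Perturb an ROI boundary to emulate a second manual segmentation.

    Each boundary pixel is independently toggled with probability
    ``jitter``: it is either removed (local erosion) or one of its outside
    8-neighbors is added (local dilation), chosen with equal probability.
    Removals that would disconnect (8-connectivity) or empty the mask are
    rejected and resampled as additions.
    """
    if not (0.0 <= jitter <= 0.5):
        raise ValueError("jitter must be in [0, 0.5]")
    if rng is None:
        rng = np.random.default_rng(seed)
    roi = mask if isinstance(mask, RoiMask) else None
    arr = (mask.mask if roi is not None else np.asarray(mask, bool)).copy()
    if jitter > 0 and arr.any():
        structure = np.ones((3, 3), bool)
        interior = ndimage.binary_erosion(arr, structure=structure, border_value=0)
        boundary = np.argwhere(arr & ~interior)
        toggles = rng.random(len(boundary)) < jitter
        grow = rng.random(len(boundary)) < 0.5
        offs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
        for (r, c), do_toggle, do_grow in zip(boundary, toggles, grow):
            if not do_toggle:
                continue
            if do_grow:
                _grow_at(arr, r, c, offs, rng)
            else:
                arr[r, c] = False
                if not arr.any() or cc_label(arr, connectivity=2).max() > 1:
                    arr[r, c] = True  # rejected: would disconnect; grow instead
                    _grow_at(arr, r, c, offs, rng)
    if roi is None:
        return arr
    return RoiMask(
        mask=arr,
        side=roi.side,
        segment=roi.segment,
        observer=observer,
        session=session,
        slice_index=roi.slice_index,
    )


def _grow_at(arr, r, c, offs, rng):
    free = [
        (r + dr, c + dc)
        for dr, dc in offs
        if 0 <= r + dr < arr.shape[0]
        and 0 <= c + dc < arr.shape[1]
        and not arr[r + dr, c + dc]
    ]
    if free:
        pick = free[rng.integers(len(free))]
        arr[pick] = True


# ---------------------------------------------------------------------------
# study generation


def _truth_map_for_sequence(spec, seq, geometry) -> tuple[np.ndarray, dict]:
    """Per-pixel true relaxation time raster plus per-zone true means."""
    tmap = np.zeros(spec.grid)
    zone_means: dict = {}
    for side in ("LM", "MM"):
        hz = geometry["horizontal"][side]
        sup_val, deep_val = spec.horizontal_truths[(seq, side)]
        sup_mask = hz.zone_mask(HorizontalZone.SUPERFICIAL)
        deep_mask = hz.zone_mask(HorizontalZone.DEEP)
        tmap[sup_mask] = sup_val
        tmap[deep_mask] = deep_val
        for segment, segmask in geometry["segments"][side].items():
            if spec.basis_for(side, segment) == "vertical":
                vz = geometry["vertical"][(side, segment)]
                for zone, val in zip(
                    (VerticalZone.WHITE, VerticalZone.RED_WHITE, VerticalZone.RED),
                    spec.vertical_truths[(seq, side, segment)],
                ):
                    tmap[vz.zone_mask(zone) & segmask] = val
        # record the realized per-zone means (exact under the assignment)
        for segment, segmask in geometry["segments"][side].items():
            for zone in (HorizontalZone.SUPERFICIAL, HorizontalZone.DEEP):
                sel = hz.zone_mask(zone) & segmask
                if sel.any():
                    zone_means[(seq, side, segment, zone.name)] = float(tmap[sel].mean())
            if segment in ("AH", "PH"):
                vz = geometry["vertical"][(side, segment)]
                for zone in (VerticalZone.WHITE, VerticalZone.RED_WHITE, VerticalZone.RED):
                    sel = vz.zone_mask(zone) & segmask
                    if sel.any():
                        zone_means[(seq, side, segment, zone.name)] = float(tmap[sel].mean())
    return tmap, zone_means


def _side_geometry(spec: PhantomSpec) -> dict:
    geometry = {"side_masks": {}, "segments": {}, "horizontal": {}, "vertical": {}}
    for side in ("LM", "MM"):
        mask, arcpos = _crescent_mask(spec, side)
        if not mask.any():
            raise PhantomSpecError(f"crescent geometry for {side} is empty")
        geometry["side_masks"][side] = mask
        segs = _segment_masks(mask, arcpos)
        geometry["segments"][side] = segs
        roi = RoiMask(mask=mask, side=side, segment="BD")
        geometry["horizontal"][side] = horizontal_zones(roi)
        for segment in ("AH", "PH"):
            seg_roi = RoiMask(mask=segs[segment], side=side, segment=segment)
            free, per = infer_edges(seg_roi, spec.side_centers[side])
            geometry["vertical"][(side, segment)] = vertical_zones(seg_roi, free, per)
    return geometry


def generate_phantom(spec: PhantomSpec) -> PhantomStudy:
    """Generate one synthetic subject: series, observer masks, ground truth."""
    streams = _substreams(spec.seed, ("noise", "motion", "jitter", "invalid"))
    geometry = _side_geometry(spec)

    t_maps, transforms, forced_invalid, series = {}, {}, {}, {}
    zone_true_means: dict = {}
    for seq in spec.sequences:
        modality, times = SEQUENCES[seq]
        tmap, zmeans = _truth_map_for_sequence(spec, seq, geometry)
        zone_true_means.update(zmeans)
        any_mask = geometry["side_masks"]["LM"] | geometry["side_masks"]["MM"]
        for sl in range(spec.n_slices):
            tissue = tmap > 0
            clean_frames = []
            with np.errstate(divide="ignore"):
                inv_t = np.where(tissue, 1.0 / np.where(tissue, tmap, 1.0), 0.0)
            for t in times:
                clean = np.where(tissue, spec.s0 * np.exp(-t * inv_t), 0.0)
                clean_frames.append(clean)
            t_list = [RigidTransform2D(center=_center_of(spec.grid))]
            moved = [clean_frames[0]]
            for clean in clean_frames[1:]:
                if spec.motion_max_shift_px > 0 or spec.motion_max_rot_deg > 0:
                    rot = streams["motion"].uniform(
                        -spec.motion_max_rot_deg, spec.motion_max_rot_deg
                    )
                    tr = streams["motion"].uniform(
                        -spec.motion_max_shift_px, spec.motion_max_shift_px, 2
                    )
                    t_true = RigidTransform2D(
                        rotation=float(rot),
                        translation=(float(tr[0]), float(tr[1])),
                        center=_center_of(spec.grid),
                    )
                    moved.append(apply_transform(clean, t_true))
                    t_list.append(t_true)
                else:
                    moved.append(clean)
                    t_list.append(RigidTransform2D(center=_center_of(spec.grid)))
            noisy = [
                add_rician_noise(fr, spec.noise_sigma, rng=streams["noise"])
                for fr in moved
            ]
            invalid_mask = np.zeros(spec.grid, bool)
            if spec.invalid_fraction > 0:
                u = streams["invalid"].random(spec.grid)
                invalid_mask = any_mask & (u < spec.invalid_fraction)
                for fr in noisy:
                    fr[invalid_mask] = 0.0
            series[(seq, sl)] = ImageSeries(
                frames=np.stack(noisy),
                weight_times=np.asarray(times),
                modality=modality,
                slice_index=sl,
            )
            t_maps[(seq, sl)] = tmap.copy()
            transforms[(seq, sl)] = t_list
            forced_invalid[(seq, sl)] = invalid_mask

    masks = _observer_masks(spec, geometry, streams["jitter"])
    gt = GroundTruth(
        side_masks={
            (side, sl): geometry["side_masks"][side]
            for side in ("LM", "MM")
            for sl in range(spec.n_slices)
        },
        segment_masks={
            (side, seg, sl): geometry["segments"][side][seg]
            for side in ("LM", "MM")
            for seg in ("AH", "BD", "PH")
            for sl in range(spec.n_slices)
        },
        horizontal_labels={
            (side, sl): geometry["horizontal"][side]
            for side in ("LM", "MM")
            for sl in range(spec.n_slices)
        },
        vertical_labels={
            (side, seg, sl): geometry["vertical"][(side, seg)]
            for side in ("LM", "MM")
            for seg in ("AH", "PH")
            for sl in range(spec.n_slices)
        },
        t_maps=t_maps,
        transforms=transforms,
        forced_invalid=forced_invalid,
        zone_true_means=zone_true_means,
        joint_centers=dict(spec.side_centers),
    )
    return PhantomStudy(spec=spec, series=series, masks=masks, ground_truth=gt)


def _observer_masks(spec, geometry, rng) -> list:
    masks = []
    for side in ("LM", "MM"):
        for segment in ("AH", "BD", "PH"):
            base = geometry["segments"][side][segment]
            for sl in range(spec.n_slices):
                masks.append(
                    RoiMask(
                        mask=base.copy(),
                        side=side,
                        segment=segment,
                        observer="R1",
                        session="S1",
                        slice_index=sl,
                    )
                )
                for observer, session in (("R1", "S2"), ("R2", "S1")):
                    template = RoiMask(
                        mask=base.copy(),
                        side=side,
                        segment=segment,
                        observer=observer,
                        session=session,
                        slice_index=sl,
                    )
                    masks.append(
                        simulate_observer_masks(
                            template,
                            spec.observer_jitter,
                            rng=rng,
                            observer=observer,
                            session=session,
                        )
                    )
    return masks


def _substreams(seed: int, names) -> dict:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def _center_of(grid) -> tuple[float, float]:
    return ((grid[0] - 1) / 2.0, (grid[1] - 1) / 2.0)
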