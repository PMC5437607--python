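"""Rigid 2D coregistration of a relaxometry series to its first frame.

Frames of a T1rho/T2 series share anatomy but differ in contrast scale, so
the similarity metric is normalized cross-correlation (NCC), which is
invariant to affine intensity changes. The optimizer is deterministic: an
exhaustive coarse grid over integer shifts and degree-step rotations,
followed by Nelder-Mead refinement. Resampling is bilinear; pixels mapped
from outside the field of view are set to 0 and excluded via a validity
footprint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .image_io import ImageSeries


@dataclass
class RigidTransform2D:
    """In-plane rigid motion: rotation (deg, CCW in array coordinates)
    about ``center`` followed by a (row, col) pixel translation."""

    rotation: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)
    center: tuple[float, float] = (0.0, 0.0)
    converged: bool = field(default=True, compare=False)

    def __post_init__(self) -> None:
        r = float(self.rotation) % 360.0
        if r > 180.0:
            r -= 360.0
        self.rotation = r

    def matrix(self) -> np.ndarray:
        """3x3 homogeneous matrix mapping source (row, col) to target."""
        th = np.deg2rad(self.rotation)
        c, s = np.cos(th), np.sin(th)
        rot = np.array([[c, -s], [s, c]])
        cen = np.asarray(self.center, float)
        t = np.asarray(self.translation, float)
        m = np.eye(3)
        m[:2, :2] = rot
        m[:2, 2] = cen + t - rot @ cen
        return m

    def inverse(self) -> "RigidTransform2D":
        th = np.deg2rad(self.rotation)
        c, s = np.cos(th), np.sin(th)
        rot_inv = np.array([[c, s], [-s, c]])
        t = np.asarray(self.translation, float)
        return RigidTransform2D(
            rotation=-self.rotation,
            translation=tuple(-(rot_inv @ t)),
            center=self.center,
        )

    def compose(self, other: "RigidTransform2D") -> "RigidTransform2D":
        """Transform equivalent to applying ``other`` first, then ``self``.
        Both must share the same center."""
        if not np.allclose(self.center, other.center):
            raise ValueError("can only compose transforms about a common center")
        m = self.matrix() @ other.matrix()
        rot = np.rad2deg(np.arctan2(m[1, 0], m[0, 0]))
        cen = np.asarray(self.center, float)
        th = np.deg2rad(rot)
        r = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        t = m[:2, 2] - cen + r @ cen
        return RigidTransform2D(rotation=rot, translation=tuple(t), center=self.center)


def apply_transform(
    frame: np.ndarray,
    t: RigidTransform2D,
    return_footprint: bool = False,
):
    """Resample ``frame`` under rigid motion ``t`` with bilinear interpolation.

    The image content is rotated about ``t.center`` and shifted by
    ``t.translation``. Output pixels whose source location falls outside the
    frame are 0 and marked invalid in the footprint.
    """
    frame = np.asarray(frame, dtype=float)
    rows, cols = frame.shape
    rr, cc = np.mgrid[0:rows, 0:cols].astype(float)
    inv = t.inverse().matrix()
    src_r = inv[0, 0] * rr + inv[0, 1] * cc + inv[0, 2]
    src_c = inv[1, 0] * rr + inv[1, 1] * cc + inv[1, 2]
    out = ndimage.map_coordinates(
        frame, [src_r, src_c], order=1, mode="constant", cval=0.0
    )
    footprint = (
        (src_r >= 0) & (src_r <= rows - 1) & (src_c >= 0) & (src_c <= cols - 1)
    )
    out[~footprint] = 0.0
    if return_footprint:
        return out, footprint
    return out


def _ncc(a: np.ndarray, b: np.ndarray, valid: np.ndarray) -> float:
    av = a[valid]
    bv = b[valid]
    if av.size < 16:
        return -np.inf
    av = av - av.mean()
    bv = bv - bv.mean()
    denom = np.sqrt((av @ av) * (bv @ bv))
    if denom == 0:
        return -np.inf
    return float((av @ bv) / denom)


def _shifted_ncc(fixed: np.ndarray, moving: np.ndarray, dr: int, dc: int, mask) -> float:
    """NCC between fixed and moving shifted by integer (dr, dc), over the
    overlap region (array slicing, no interpolation)."""
    rows, cols = fixed.shape
    r0f, r1f = max(0, dr), min(rows, rows + dr)
    c0f, c1f = max(0, dc), min(cols, cols + dc)
    if r1f <= r0f or c1f <= c0f:
        return -np.inf
    f = fixed[r0f:r1f, c0f:c1f]
    m = moving[r0f - dr : r1f - dr, c0f - dc : c1f - dc]
    valid = np.ones(f.shape, bool)
    if mask is not None:
        valid &= mask[r0f:r1f, c0f:c1f]
    return _ncc(f, m, valid)


def register_frame(
    fixed: np.ndarray,
    moving: np.ndarray,
    mask: np.ndarray | None = None,
    max_shift_px: float = 4.0,
    max_rot_deg: float = 4.0,
    tol: float = 1e-3,
) -> RigidTransform2D:
    """Estimate the rigid transform that maps ``moving`` onto ``fixed``.

    Coarse search: integer shifts within ``±max_shift_px`` crossed with
    rotations within ``±max_rot_deg`` in 1-degree steps (each rotation
    resampled once, shifts evaluated by slicing). The best grid point seeds
    a Nelder-Mead refinement of (rotation, drow, dcol) with tolerance
    ``tol`` in px/deg.
    """
    fixed = np.asarray(fixed, float)
    moving = np.asarray(moving, float)
    center = ((fixed.shape[0] - 1) / 2.0, (fixed.shape[1] - 1) / 2.0)
    if mask is not None:
        mask = ndimage.binary_dilation(np.asarray(mask, bool), iterations=3)
    # keep the metric away from the borders, where warped frames carry
    # out-of-field zeros that would corrupt the correlation
    margin = int(
        np.ceil(max_shift_px + np.deg2rad(max_rot_deg) * 0.5 * np.hypot(*fixed.shape))
    ) + 2
    margin = min(margin, min(fixed.shape) // 4)
    if margin > 0:
        interior = np.zeros(fixed.shape, bool)
        interior[margin:-margin, margin:-margin] = True
        mask = interior if mask is None else (mask & interior)

    n_shift = int(np.floor(max_shift_px))
    shifts = range(-n_shift, n_shift + 1)
    n_rot = int(np.floor(max_rot_deg))
    angles = np.arange(-n_rot, n_rot + 1, dtype=float)

    best = (-np.inf, 0.0, 0.0, 0.0)
    for ang in angles:
        if ang == 0.0:
            rotated = moving
        else:
            rotated = apply_transform(
                moving, RigidTransform2D(rotation=ang, center=center)
            )
        for dr in shifts:
            for dc in shifts:
                score = _shifted_ncc(fixed, rotated, dr, dc, mask)
                if score > best[0]:
                    best = (score, ang, float(dr), float(dc))

    if not np.isfinite(best[0]):
        warnings.warn("registration metric degenerate; returning identity")
        t = RigidTransform2D(center=center)
        t.converged = False
        return t

    def negncc(x):
        ang, dr, dc = x
        t = RigidTransform2D(rotation=ang, translation=(dr, dc), center=center)
        warped, fp = apply_transform(moving, t, return_footprint=True)
        valid = fp if mask is None else (fp & mask)
        return -_ncc(fixed, warped, valid)

    x0 = np.array(best[1:])
    res = optimize.minimize(
        negncc,
        x0,
        method="Nelder-Mead",
        options={"xatol": tol, "fatol": 1e-10, "maxiter": 400},
    )
    if np.isfinite(res.fun) and -res.fun >= best[0]:
        ang, dr, dc = res.x
        t = RigidTransform2D(rotation=float(ang), translation=(float(dr), float(dc)), center=center)
        t.converged = bool(res.success)
    else:
        warnings.warn("registration refinement did not improve; using grid optimum")
        t = RigidTransform2D(
            rotation=best[1], translation=(best[2], best[3]), center=center
        )
        t.converged = True
    return t


def register_to_first(
    series: ImageSeries,
    mask: np.ndarray | None = None,
    max_shift_px: float = 4.0,
    max_rot_deg: float = 4.0,
) -> tuple[ImageSeries, list[RigidTransform2D]]:
    """Coregister every frame of a series to its first frame.

    Returns the registered series (frame 0 untouched, later frames
    bilinearly resampled into frame-0 coordinates) and the per-frame
    transforms, identity for frame 0.
    """
    fixed = series.frames[0]
    center = ((fixed.shape[0] - 1) / 2.0, (fixed.shape[1] - 1) / 2.0)
    transforms: list[RigidTransform2D] = [RigidTransform2D(center=center)]
    frames = [fixed.copy()]
    for k in range(1, series.n_frames):
        t = register_frame(
            fixed,
            series.frames[k],
            mask=mask,
            max_shift_px=max_shift_px,
            max_rot_deg=max_rot_deg,
        )
        if not t.converged:
            warnings.warn(f"frame {k}: registration flagged non-converged")
        transforms.append(t)
        frames.append(apply_transform(series.frames[k], t))
    registered = ImageSeries(
        frames=np.stack(frames),
        weight_times=series.weight_times.copy(),
        modality=series.modality,
        pixel_spacing=series.pixel_spacing,
        slice_index=series.slice_index,
    )
    return registered, transforms
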