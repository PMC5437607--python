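"""Pixelwise monoexponential relaxometry: S(t) = S0 * exp(-t / T).

For a T1rho series t is the spin-lock time (TSL) and T is T1rho; for a T2
series t is the echo time (TE) and T is T2, all in ms. Each pixel is fitted
in two stages: a log-linear least-squares pass on the positive samples
initializes (S0, T), then unweighted nonlinear least squares on the
monoexponential refines it. The model carries no Rician noise-floor term;
magnitude-noise bias is quantified by simulation instead of corrected.

Failed fits follow the zero-sentinel convention: the stored relaxation time
is 0 and the pixel is flagged invalid, to be excluded from every downstream
summary. A fit is invalid when fewer than 2 samples are positive, the
optimizer fails, the fitted T falls outside ``t_bounds`` (default (0, 2000]
ms, beyond the fittable range of an 80/91 ms maximum weighting time), or
the fitted amplitude is not positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .image_io import ImageSeries, Modality, RoiMask

T_BOUNDS_MS = (0.0, 2000.0)
MAX_ITER = 60
FTOL = 1e-12


@dataclass
class PixelFit:
    """One pixel's monoexponential fit."""

    s0: float
    t_relax: float
    valid: bool
    rss: float

    @classmethod
    def invalid(cls) -> "PixelFit":
        return cls(s0=0.0, t_relax=0.0, valid=False, rss=np.nan)


@dataclass
class ParameterMap:
    """Per-slice fitted relaxation-time map.

    ``values`` holds T in ms with 0 as the invalid/outside-ROI sentinel;
    ``valid_mask`` is true exactly where ``values > 0``.
    """

    values: np.ndarray
    s0_map: np.ndarray
    valid_mask: np.ndarray
    modality: Modality
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        self.s0_map = np.asarray(self.s0_map, float)
        self.valid_mask = np.asarray(self.valid_mask, bool)
        self.modality = Modality(self.modality)


def _loglinear_init(signals: np.ndarray, times: np.ndarray):
    """Vectorized log-linear LS on positive samples.

    Returns (s0, T, ok) arrays; ok is False where < 2 samples are positive
    or the slope is non-negative (no decay to initialize from).
    """
    n, m = signals.shape
    pos = signals > 0
    npos = pos.sum(axis=1)
    w = pos.astype(float)
    logs = np.where(pos, np.log(np.where(pos, signals, 1.0)), 0.0)
    sw = w.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tbar = (w * times).sum(axis=1) / sw
        ybar = (w * logs).sum(axis=1) / sw
        cov = (w * (times - tbar[:, None]) * (logs - ybar[:, None])).sum(axis=1)
        var = (w * (times - tbar[:, None]) ** 2).sum(axis=1)
        slope = cov / var
        intercept = ybar - slope * tbar
    ok = (npos >= 2) & (var > 0) & np.isfinite(slope) & (slope < 0)
    s0 = np.where(ok, np.exp(np.clip(intercept, -300, 300)), 0.0)
    T = np.where(ok, -1.0 / np.where(slope < 0, slope, -1.0), 0.0)
    return s0, T, ok, npos


def _fit_monoexp_bulk(
    signals: np.ndarray,
    times: np.ndarray,
    t_bounds: tuple[float, float] = T_BOUNDS_MS,
    max_iter: int = MAX_ITER,
    ftol: float = FTOL,
):
    """Levenberg-Marquardt over all pixels at once.

    Parameters per pixel are (S0, T); the normal equations are 2x2 and
    solved in closed form. Returns (s0, T, rss, valid).
    """
    signals = np.asarray(signals, float)
    times = np.asarray(times, float)
    n, m = signals.shape
    s0, T, active, npos = _loglinear_init(signals, times)
    # pixels with >=2 positive samples but a non-decaying log fit still get
    # an NLS attempt from a generic start
    attempt = (npos >= 2) & ~active
    s0 = np.where(attempt, np.maximum(signals.max(axis=1), 1e-6), s0)
    T = np.where(attempt, times[-1], T)
    active = active | attempt

    T = np.clip(T, 1e-3, 10.0 * t_bounds[1])
    lam = np.full(n, 1e-3)
    model = s0[:, None] * np.exp(-times[None, :] / T[:, None])
    resid = model - signals
    cost = (resid**2).sum(axis=1)
    cost = np.where(active, cost, np.nan)

    for _ in range(max_iter):
        if not active.any():
            break
        e = np.exp(-times[None, :] / T[:, None])
        j0 = e  # d model / d S0
        j1 = s0[:, None] * times[None, :] / T[:, None] ** 2 * e  # d model / d T
        r = s0[:, None] * e - signals
        a00 = (j0 * j0).sum(axis=1)
        a01 = (j0 * j1).sum(axis=1)
        a11 = (j1 * j1).sum(axis=1)
        g0 = (j0 * r).sum(axis=1)
        g1 = (j1 * r).sum(axis=1)
        d00 = a00 * (1 + lam)
        d11 = a11 * (1 + lam)
        det = d00 * d11 - a01 * a01
        bad = np.abs(det) < 1e-300
        det = np.where(bad, 1.0, det)
        step0 = -(d11 * g0 - a01 * g1) / det
        step1 = -(-a01 * g0 + d00 * g1) / det
        step0 = np.where(bad, 0.0, step0)
        step1 = np.where(bad, 0.0, step1)
        s0_new = s0 + np.where(active, step0, 0.0)
        T_new = np.clip(T + np.where(active, step1, 0.0), 1e-3, 10.0 * t_bounds[1])
        model_new = s0_new[:, None] * np.exp(-times[None, :] / T_new[:, None])
        cost_new = ((model_new - signals) ** 2).sum(axis=1)
        improved = active & (cost_new <= cost)
        s0 = np.where(improved, s0_new, s0)
        T = np.where(improved, T_new, T)
        lam = np.where(improved, lam * 0.3, np.where(active, lam * 3.0, lam))
        converged = improved & (np.abs(cost - cost_new) <= ftol * (1.0 + cost_new))
        tiny_step = improved & (
            (np.abs(step0) <= 1e-10 * (1 + np.abs(s0)))
            & (np.abs(step1) <= 1e-10 * (1 + np.abs(T)))
        )
        cost = np.where(improved, cost_new, cost)
        active = active & ~(converged | tiny_step) & (lam < 1e12)

    valid = (
        (npos >= 2)
        & np.isfinite(s0)
        & np.isfinite(T)
        & (s0 > 0)
        & (T > t_bounds[0])
        & (T <= t_bounds[1])
    )
    rss = np.where(valid, cost, np.nan)
    T = np.where(valid, T, 0.0)
    s0 = np.where(valid, s0, 0.0)
    return s0, T, rss, valid


def fit_monoexp(
    signal: np.ndarray,
    times: np.ndarray,
    t_bounds: tuple[float, float] = T_BOUNDS_MS,
    max_iter: int = MAX_ITER,
) -> PixelFit:
    """Fit one pixel's decay; see module docstring for the validity rules."""
    signal = np.asarray(signal, float).ravel()
    times = np.asarray(times, float).ravel()
    if signal.shape != times.shape:
        raise ValueError("signal and times must have equal length")
    if signal.size < 2:
        raise ValueError("need at least 2 samples")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    s0, T, rss, valid = _fit_monoexp_bulk(
        signal[None, :], times, t_bounds=t_bounds, max_iter=max_iter
    )
    if not valid[0]:
        return PixelFit.invalid()
    return PixelFit(s0=float(s0[0]), t_relax=float(T[0]), valid=True, rss=float(rss[0]))


def fit_pixels(
    signals: np.ndarray,
    times: np.ndarray,
    t_bounds: tuple[float, float] = T_BOUNDS_MS,
):
    """Fit many pixels at once.

    ``signals`` has shape (n_pixels, n_times). Returns arrays
    ``(s0, t_relax, rss, valid)``; invalid pixels carry the zero sentinel.
    """
    signals = np.atleast_2d(np.asarray(signals, float))
    times = np.asarray(times, float).ravel()
    if signals.shape[1] != times.size:
        raise ValueError("signals and times disagree on the number of samples")
    return _fit_monoexp_bulk(signals, times, t_bounds=t_bounds)


def compute_map(
    series: ImageSeries,
    roi: RoiMask,
    t_bounds: tuple[float, float] = T_BOUNDS_MS,
) -> ParameterMap:
    """Fit every ROI pixel of a (registered) series.

    Pixels outside the ROI are 0/invalid. The ROI grid must match the
    series frames.
    """
    if roi.mask.shape != series.shape:
        raise ValueError("ROI shape does not match series frames")
    shape = series.shape
    values = np.zeros(shape)
    s0_map = np.zeros(shape)
    valid_mask = np.zeros(shape, bool)
    idx = np.flatnonzero(roi.mask.ravel())
    if idx.size == 0:
        warnings.warn("empty ROI: returning empty parameter map")
    else:
        signals = series.frames.reshape(series.n_frames, -1)[:, idx].T
        s0, T, rss, valid = _fit_monoexp_bulk(
            signals, series.weight_times, t_bounds=t_bounds
        )
        values.ravel()[idx] = T
        s0_map.ravel()[idx] = s0
        valid_mask.ravel()[idx] = valid
    return ParameterMap(
        values=values,
        s0_map=s0_map,
        valid_mask=valid_mask,
        modality=series.modality,
        provenance={
            "slice_index": series.slice_index,
            "roi": f"{roi.side.value}{roi.segment.value}",
            "observer": roi.observer,
            "session": roi.session,
        },
    )


def exclude_invalid(pmap: ParameterMap) -> ParameterMap:
    """Clear the validity mask wherever the stored relaxation time is 0.

    This applies the zero-sentinel exclusion rule (misregistration or
    inadequate fitting). Idempotent.
    """
    valid = pmap.valid_mask & (pmap.values > 0)
    return ParameterMap(
        values=pmap.values.copy(),
        s0_map=pmap.s0_map.copy(),
        valid_mask=valid,
        modality=pmap.modality,
        provenance=dict(pmap.provenance),
    )
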