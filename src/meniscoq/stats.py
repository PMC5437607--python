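"""Per-zone relaxation summaries and between-zone comparisons.

Zone means pool the valid pixels of a parameter map (zero-sentinel pixels
excluded). Zones are compared with the two-sided Mann-Whitney U test:
exact when the pooled sample is small (n1+n2 <= 12) and tie-free, else the
normal approximation with tie and continuity corrections. Significance is
starred at p < 0.05, < 0.001 and < 0.0001. No multiple-testing correction
is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .relaxometry import ParameterMap
from .zones import ZoneLabelMap

EXACT_MAX_N = 12
ALPHA_STARS = ((0.0001, "***"), (0.001, "**"), (0.05, "*"))


@dataclass
class ZonalSummary:
    """Mean/SD of valid relaxation times in one zone."""

    zone: str
    mean_ms: float
    sd_ms: float
    n_pixels: int
    side: str = ""
    segment: str = ""
    sequence: str = ""
    empty: bool = False


@dataclass
class ComparisonResult:
    """Two-sided Mann-Whitney comparison of two zones."""

    u_statistic: float
    p_value: float
    n1: int
    n2: int
    group_labels: tuple[str, str]
    method: str = ""

    @property
    def stars(self) -> str:
        for alpha, mark in ALPHA_STARS:
            if self.p_value < alpha:
                return mark
        return ""


def summarize_values(values: np.ndarray, zone: str, **labels) -> ZonalSummary:
    values = np.asarray(values, float)
    n = values.size
    if n == 0:
        return ZonalSummary(zone=zone, mean_ms=np.nan, sd_ms=np.nan, n_pixels=0, empty=True, **labels)
    mean = float(values.mean())
    sd = 0.0 if n == 1 else float(values.std(ddof=1))
    return ZonalSummary(zone=zone, mean_ms=mean, sd_ms=sd, n_pixels=n, **labels)


def zone_values(pmap: ParameterMap, zones: ZoneLabelMap, zone) -> np.ndarray:
    """Valid relaxation times of the pixels in one zone."""
    if pmap.values.shape != (zones.horizontal if zones.horizontal is not None else zones.vertical).shape:
        raise ValueError("map and zone labels must share the grid")
    sel = zones.zone_mask(zone) & pmap.valid_mask
    return pmap.values[sel]


def zonal_mean(pmap: ParameterMap, zones: ZoneLabelMap, zone, **labels) -> ZonalSummary:
    """Mean/SD over pixels that are in ``zone`` and valid in the map."""
    return summarize_values(zone_values(pmap, zones, zone), zone=zone.name, **labels)


def mann_whitney(
    a: np.ndarray,
    b: np.ndarray,
    exact_max_n: int = EXACT_MAX_N,
    group_labels: tuple[str, str] = ("a", "b"),
) -> ComparisonResult:
    """Two-sided Mann-Whitney U of two samples.

    Exact-path p (full null distribution of U) when n1 + n2 <= exact_max_n
    and there are no ties; otherwise the normal approximation with tie
    correction and continuity correction.
    """
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    if tie_free and a.size + b.size <= exact_max_n:
        method = "exact"
    else:
        method = "asymptotic"
    res = sstats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return ComparisonResult(
        u_statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n1=int(a.size),
        n2=int(b.size),
        group_labels=group_labels,
        method=method,
    )


def compare_groups(a, b, group_labels=("a", "b")):
    """Summaries + Mann-Whitney test for two raw value groups."""
    sa = summarize_values(np.asarray(a, float), zone=group_labels[0])
    sb = summarize_values(np.asarray(b, float), zone=group_labels[1])
    test = mann_whitney(a, b, group_labels=group_labels)
    return sa, sb, test


def compare_zone_pair(
    pmap: ParameterMap,
    zones: ZoneLabelMap,
    zone_a,
    zone_b,
    **labels,
):
    """Compare the valid pixel values of two zones of one map.

    Returns ``(summary_a, summary_b, ComparisonResult | None)``; the test is
    skipped (None) when either zone holds no valid pixels.
    """
    va = zone_values(pmap, zones, zone_a)
    vb = zone_values(pmap, zones, zone_b)
    sa = summarize_values(va, zone=zone_a.name, **labels)
    sb = summarize_values(vb, zone=zone_b.name, **labels)
    if sa.empty or sb.empty:
        return sa, sb, None
    test = mann_whitney(va, vb, group_labels=(zone_a.name, zone_b.name))
    return sa, sb, test
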