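"""Observer-agreement statistics: intraclass correlation and Bland-Altman.

The ICC model is ICC(2,1) — two-way random effects, absolute agreement,
single measures — computed from the two-way ANOVA mean squares:

    ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

for n subjects and k raters (or sessions). Agreement strength is banded
with the Fleiss cutpoints: poor (< 0.40), fair (0.40-0.59), good
(0.60-0.74) and excellent (> 0.74); applied as icc < 0.40 POOR,
< 0.60 FAIR, <= 0.74 GOOD, else EXCELLENT, so the printed band edges are
honoured and the (0.59, 0.60) gap cannot produce an ambiguous category.

Bland-Altman agreement of paired measurements reports the bias (mean of
first-minus-second differences) and the 1.96-SD limits of agreement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd


class AgreementCategory(str, Enum):
    POOR = "POOR"
    FAIR = "FAIR"
    GOOD = "GOOD"
    EXCELLENT = "EXCELLENT"


class AgreementMode(str, Enum):
    INTER = "INTER"
    INTRA = "INTRA"


def categorize_icc(icc: float) -> AgreementCategory:
    if icc < 0.40:
        return AgreementCategory.POOR
    if icc < 0.60:
        return AgreementCategory.FAIR
    if icc <= 0.74:
        return AgreementCategory.GOOD
    return AgreementCategory.EXCELLENT


@dataclass
class AgreementResult:
    icc: float
    category: AgreementCategory | None
    n_subjects: int
    n_raters: int
    mode: AgreementMode
    defined: bool = True


@dataclass
class BlandAltmanResult:
    bias: float
    loa_low: float
    loa_high: float
    n: int
    means: np.ndarray = field(repr=False, default=None)
    diffs: np.ndarray = field(repr=False, default=None)


def icc(ratings: np.ndarray, mode: AgreementMode | str = AgreementMode.INTER) -> AgreementResult:
    """ICC(2,1) of an n_subjects x n_raters matrix (no missing cells).

    A constant matrix has no subject variance, leaving the ICC undefined;
    the result is then flagged ``defined=False`` with ``icc = nan``.
    """
    mode = AgreementMode(mode)
    x = np.asarray(ratings, float)
    if x.ndim != 2:
        raise ValueError("ratings must be a subjects x raters matrix")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 raters")
    if not np.isfinite(x).all():
        raise ValueError("missing cells are not supported")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((x - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0 or not np.isfinite(denom) or np.isclose(denom, 0.0):
        return AgreementResult(
            icc=np.nan, category=None, n_subjects=n, n_raters=k, mode=mode, defined=False
        )
    val = float((msr - mse) / denom)
    return AgreementResult(
        icc=val,
        category=categorize_icc(val),
        n_subjects=n,
        n_raters=k,
        mode=mode,
    )


def bland_altman(x: np.ndarray, y: np.ndarray) -> BlandAltmanResult:
    """Bias and 1.96-SD limits of agreement of paired measurements x, y.

    Differences are x - y; the SD uses the n-1 denominator. The per-pair
    means and differences are returned as the plot payload.
    """
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        n=int(x.size),
        means=(x + y) / 2.0,
        diffs=d,
    )


def reproducibility_tables(
    measurements: pd.DataFrame,
    value_col: str = "value",
    inter_pair: tuple[tuple[str, str], tuple[str, str]] = (("R1", "S1"), ("R2", "S1")),
    intra_pair: tuple[tuple[str, str], tuple[str, str]] = (("R1", "S1"), ("R1", "S2")),
    group_cols: tuple[str, ...] = ("sequence", "side", "segment"),
) -> pd.DataFrame:
    """Inter- and intra-observer ICC tables from long-format measurements.

    ``measurements`` needs columns ``subject``, ``observer``, ``session``,
    the grouping columns and ``value_col``. For each group, the inter-ICC
    compares the two observers' first sessions and the intra-ICC the first
    observer's two sessions, across subjects. Groups missing a rating are
    flagged absent (icc = NaN, category empty).
    """
    required = {"subject", "observer", "session", value_col, *group_cols}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"measurements missing columns: {sorted(missing)}")
    rows = []
    for keys, grp in measurements.groupby(list(group_cols), sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        for mode, (rater_a, rater_b) in (
            (AgreementMode.INTER, inter_pair),
            (AgreementMode.INTRA, intra_pair),
        ):
            pivots = []
            ok = True
            for obs, ses in (rater_a, rater_b):
                sub = grp[(grp["observer"] == obs) & (grp["session"] == ses)]
                sub = sub.set_index("subject")[value_col]
                if sub.empty:
                    ok = False
                    break
                pivots.append(sub)
            row = dict(zip(group_cols, keys))
            row["mode"] = mode.value
            if not ok:
                row.update(icc=np.nan, category="", n_subjects=0, absent=True)
            else:
                joined = pd.concat(pivots, axis=1, join="inner")
                if joined.shape[0] < 2 or joined.isna().any().any():
                    row.update(icc=np.nan, category="", n_subjects=int(joined.shape[0]), absent=True)
                else:
                    res = icc(joined.to_numpy(), mode=mode)
                    row.update(
                        icc=res.icc,
                        category=res.category.value if res.category else "",
                        n_subjects=res.n_subjects,
                        absent=not res.defined,
                    )
            rows.append(row)
    return pd.DataFrame(rows)
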