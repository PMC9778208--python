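"""Per-origin window quantification and strain comparison.

This module computes the quantities behind standard early-S origin-activity
displays: mean signal in fixed windows centered on origin midpoints, per-origin
differences between a reference and a test strain (dQBU), group distribution
summaries with Welch t-tests, peak widths (FWHM, a proxy for fork travel
distance under HU), feature-centered heatmap matrices, and least-squares
scatter fits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .origins import Origin, OriginSet
from .preprocess import StrainProfile

__all__ = [
    "window_signal",
    "window_signal_table",
    "delta_signal",
    "group_boxplot_stats",
    "two_sided_ttest",
    "PeakWidth",
    "peak_width_fwhm",
    "heatmap_matrix",
    "scatter_fit",
    "bh_qvalues",
]

FeatureLike = object  # anything with .chrom / .midpoint (Origin, Centromere)


def _feature_fields(feature) -> tuple[str, int, str]:
    chrom = getattr(feature, "chrom")
    mid = int(getattr(feature, "midpoint", getattr(feature, "position", None)))
    name = getattr(feature, "name", None) or f"{chrom}:{mid}"
    return chrom, mid, name


def window_signal(
    profile: StrainProfile,
    features: Sequence[FeatureLike],
    width_bp: int = 500,
) -> pd.Series:
    """Mean signal in a ``width_bp`` window centered on each feature midpoint.

    The window ``[mid - width/2, mid + width/2)`` is clipped to the
    chromosome; the mean is bp-overlap weighted over the covered bins, so a
    500 bp window at 50 bp bins is the plain mean of the 10 covered bins when
    midpoints are bin-aligned.
    """
    track = profile.track
    w = track.bin_width
    if width_bp < w:
        raise ValueError(f"window {width_bp} bp narrower than one bin ({w} bp)")
    out: dict[str, float] = {}
    for feature in features:
        chrom, mid, name = _feature_fields(feature)
        length = track.genome.length_of(chrom)  # KeyError on unknown chrom
        start = max(0, mid - width_bp // 2)
        end = min(length, mid + width_bp // 2)
        if end <= start:
            raise ValueError(f"{name}: window falls outside {chrom}")
        v = track.values[chrom]
        i0, i1 = start // w, (end - 1) // w
        idx = np.arange(i0, i1 + 1)
        overlap = np.minimum((idx + 1) * w, end) - np.maximum(idx * w, start)
        out[name] = float(np.sum(v[idx] * overlap) / np.sum(overlap))
    return pd.Series(out, name=profile.strain_label)


def window_signal_table(
    profiles: Sequence[StrainProfile],
    features: Sequence[FeatureLike],
    width_bp: int = 500,
) -> pd.DataFrame:
    """Origins x strains table of window means (one column per strain)."""
    cols = [window_signal(p, features, width_bp) for p in profiles]
    return pd.concat(cols, axis=1)


def delta_signal(reference: pd.Series, test: pd.Series) -> pd.Series:
    """Per-origin reference - test difference (positive = activity lost)."""
    if not reference.index.equals(test.index):
        raise ValueError("reference and test rows do not match")
    delta = reference - test
    delta.name = f"{reference.name}-{test.name}"
    return delta


def group_boxplot_stats(
    column: pd.Series, groups: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Five-number summaries per group (linear-interpolation quartiles)."""
    rows = []
    for group, names in groups.items():
        vals = column.loc[list(names)].to_numpy(dtype=float) if len(names) else np.array([])
        if vals.size == 0:
            rows.append(
                {"group": group, "n": 0, "min": np.nan, "q1": np.nan,
                 "median": np.nan, "q3": np.nan, "max": np.nan}
            )
            continue
        q = np.percentile(vals, [0, 25, 50, 75, 100], method="linear")
        rows.append(
            {"group": group, "n": vals.size, "min": q[0], "q1": q[1],
             "median": q[2], "q3": q[3], "max": q[4]}
        )
    return pd.DataFrame(rows).set_index("group")


def two_sided_ttest(a: Sequence[float], b: Sequence[float]) -> dict[str, float]:
    """Welch's unequal-variance t-test with Welch-Satterthwaite df.

    Degenerate case: both samples with zero variance and equal means gives
    t = 0, p = 1 (df = n1 + n2 - 2 by convention); zero variance with unequal
    means gives an infinite t and p = 0.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least two observations per sample")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in samples")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return {"t": 0.0, "df": float(x.size + y.size - 2), "p": 1.0}
        return {
            "t": float(np.sign(x.mean() - y.mean()) * np.inf),
            "df": float(x.size + y.size - 2),
            "p": 0.0,
        }
    res = stats.ttest_ind(x, y, equal_var=False)
    return {"t": float(res.statistic), "df": float(res.df), "p": float(res.pvalue)}


@dataclass(frozen=True)
class PeakWidth:
    """FWHM of a signal peak near an origin, in bp.

    ``censored`` marks widths truncated by the search span (a half-height
    crossing was not reached before the span edge).
    """

    width_bp: float
    peak_pos: float
    peak_height: float
    baseline: float
    censored: bool


def peak_width_fwhm(
    profile: StrainProfile, origin: FeatureLike, search_bp: int = 10_000
) -> PeakWidth:
    """Full width at half maximum of the peak nearest an origin midpoint.

    The baseline is the minimum within ``+-search_bp/2`` of the midpoint;
    half-height crossings are located by linear interpolation between bin
    centers. A flat span raises; a crossing not reached inside the span marks
    the result censored (width measured to the span edge).
    """
    track = profile.track
    w = track.bin_width
    chrom, mid, name = _feature_fields(origin)
    v = track.values[chrom]
    i0 = max(0, (mid - search_bp // 2) // w)
    i1 = min(len(v), (mid + search_bp // 2) // w + 1)
    span = v[i0:i1]
    if span.size < 3:
        raise ValueError(f"{name}: search span covers fewer than 3 bins")
    if np.ptp(span) == 0:
        raise ValueError(f"{name}: flat signal in search span, no peak")
    centers = (np.arange(i0, i1) + 0.5) * w
    peak = int(np.argmax(span))
    baseline = float(span.min())
    height = float(span[peak])
    half = baseline + (height - baseline) / 2.0

    def _cross(direction: int) -> tuple[float, bool]:
        j = peak
        while 0 <= j + direction < span.size:
            k = j + direction
            if span[k] < half:
                # interpolate between bin centers j and k
                frac = (span[j] - half) / (span[j] - span[k])
                return centers[j] + frac * (centers[k] - centers[j]), False
            j = k
        return centers[j], True  # ran off the span edge

    left, lcens = _cross(-1)
    right, rcens = _cross(+1)
    return PeakWidth(
        width_bp=float(right - left),
        peak_pos=float(centers[peak]),
        peak_height=height,
        baseline=baseline,
        censored=lcens or rcens,
    )


def heatmap_matrix(
    profile: StrainProfile,
    features: Sequence[FeatureLike],
    span_bp: int = 10_000,
    sort_by_mean: bool = False,
) -> pd.DataFrame:
    """Features x offset-bins matrix of signal centered on feature midpoints.

    Column ``j`` holds the bin value at offset ``(j - n/2) * bin_width`` from
    the feature midpoint; cells outside the genome are NaN. Columns are
    labelled by their bp offset.
    """
    track = profile.track
    w = track.bin_width
    if span_bp % w != 0:
        raise ValueError(f"span {span_bp} not a multiple of bin width {w}")
    ncols = span_bp // w
    offsets = (np.arange(ncols) - ncols // 2) * w
    rows = []
    names = []
    for feature in features:
        chrom, mid, name = _feature_fields(feature)
        v = track.values[chrom]
        center = mid // w
        idx = center + np.arange(ncols) - ncols // 2
        row = np.full(ncols, np.nan)
        ok = (idx >= 0) & (idx < len(v))
        row[ok] = v[idx[ok]]
        rows.append(row)
        names.append(name)
    mat = pd.DataFrame(rows, index=names, columns=offsets)
    if sort_by_mean:
        mat = mat.loc[mat.mean(axis=1).sort_values(ascending=False).index]
    return mat


def scatter_fit(x: pd.Series, y: pd.Series) -> dict[str, float]:
    """Ordinary least-squares line of best fit plus Pearson r."""
    if not x.index.equals(y.index):
        raise ValueError("x and y rows do not match")
    if len(x) < 2:
        raise ValueError("need at least 2 points")
    if np.ptp(x.to_numpy(dtype=float)) == 0:
        raise ValueError("constant x: slope undefined")
    res = stats.linregress(x.to_numpy(dtype=float), y.to_numpy(dtype=float))
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r": float(res.rvalue),
        "n": len(x),
    }


def bh_qvalues(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (reported as an extra column;
    the group tests themselves are raw two-sided t-tests)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]
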