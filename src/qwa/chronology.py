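"""Detrended site chronologies from per-tree annual series.

Long-term (ontogenetic) trends are removed with a cubic smoothing spline
whose stiffness is set so the implied low-pass filter passes 50 % of the
amplitude at a chosen wavelength (default 100 years) — the standard
dendrochronological parameterization (Cook & Peters). Indices are the
ratio observed/fitted, so a well-behaved tree's index series has mean ≈ 1.
The site chronology is the per-year Tukey biweight robust mean of the
tree indices, with sample depth tracked and years below a minimum depth
masked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import make_smoothing_spline

from .errors import AnalysisError

MIN_SERIES_LENGTH = 10


def spline_lambda(cutoff_years: float) -> float:
    """Smoothing-spline penalty weight giving a 50 % frequency response at
    wavelength ``cutoff_years`` (annual spacing).

    Derived from the equivalence of the smoothing spline to a low-pass
    filter: with p the classical smoothing parameter,
    p = 1 / (1 + (cos(2π/n) + 2) / (12 (1 − cos(2π/n))²)) at the 50 %
    point, and λ = (1 − p)/p. Numerically ≈ (n / 2π)⁴.
    """
    x = 2.0 * math.pi / cutoff_years
    return (math.cos(x) + 2.0) / (12.0 * (1.0 - math.cos(x)) ** 2)


def spline_detrend(
    series: pd.Series,
    cutoff_years: float = 100.0,
) -> pd.DataFrame:
    """Detrend one annual series with the 50 %-cutoff cubic smoothing spline.

    Parameters
    ----------
    series : values indexed by calendar year. Internal gaps split the
        series; each contiguous segment of at least
        :data:`MIN_SERIES_LENGTH` years is detrended separately, shorter
        segments are dropped (NaN in the output). All values must be
        positive (ratio indices).

    Returns
    -------
    DataFrame indexed by year with columns ``value``, ``fitted``,
    ``index`` (= value/fitted). Years where the fitted curve is not
    strictly positive are flagged NaN in ``index``.
    """
    ser = series.dropna().sort_index()
    if len(ser) < MIN_SERIES_LENGTH:
        raise AnalysisError(
            f"series has {len(ser)} years; at least {MIN_SERIES_LENGTH} required"
        )
    if (ser <= 0).any():
        raise AnalysisError("spline_detrend requires strictly positive values")
    years = ser.index.to_numpy(dtype=float)
    out = pd.DataFrame(
        {"value": ser.to_numpy(dtype=float)},
        index=pd.Index(ser.index, name="year"),
    )
    out["fitted"] = np.nan
    lam = spline_lambda(cutoff_years)
    # split on gaps
    breaks = np.flatnonzero(np.diff(years) != 1)
    segments = np.split(np.arange(len(years)), breaks + 1)
    for seg in segments:
        if len(seg) < MIN_SERIES_LENGTH:
            continue
        x = years[seg]
        y = out["value"].to_numpy()[seg]
        spl = make_smoothing_spline(x, y, lam=lam)
        out.iloc[seg, out.columns.get_loc("fitted")] = spl(x)
    with np.errstate(divide="ignore", invalid="ignore"):
        idx = out["value"] / out["fitted"]
    idx[out["fitted"] <= 0] = np.nan
    out["index"] = idx
    return out


def biweight_mean(values, c: float = 9.0, max_iter: int = 50, tol: float = 1e-12) -> float:
    """Tukey's biweight robust location estimate.

    Iteratively reweighted mean around the median with weights
    (1 − u²)² for |u| < 1, u = (x − m)/(c × MAD). With fewer than three
    values, or zero MAD, falls back to the arithmetic mean / median.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) == 0:
        return float("nan")
    if len(x) < 3:
        return float(x.mean())
    m = float(np.median(x))
    mad = float(np.median(np.abs(x - m)))
    if mad == 0.0:
        return m
    scale = c * mad
    for _ in range(max_iter):
        u = (x - m) / scale
        w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
        if w.sum() == 0:
            return m
        m_new = float(np.sum(w * x) / w.sum())
        if abs(m_new - m) <= tol * max(1.0, abs(m)):
            m = m_new
            break
        m = m_new
    return m


@dataclass
class Chronology:
    """Site-level detrended index chronology for one parameter."""

    site_id: str
    parameter: str
    index: pd.Series  # year -> biweight-mean index, NaN below min depth
    sample_depth: pd.Series  # year -> trees contributing
    tree_indices: pd.DataFrame = field(repr=False)  # year x tree detrended
    min_depth: int = 4

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"index": self.index, "sample_depth": self.sample_depth}
        ).rename_axis("year")


def build_chronology(
    tree_indices: pd.DataFrame,
    *,
    site_id: str = "",
    parameter: str = "",
    min_depth: int = 4,
    c: float = 9.0,
) -> Chronology:
    """Combine per-tree detrended index series into a site chronology.

    ``tree_indices`` is a DataFrame indexed by year, one column per tree.
    Per year the biweight robust mean of available indices is taken;
    years with sample depth below ``min_depth`` are masked (depth still
    recorded). An all-empty input yields an empty chronology.
    """
    if tree_indices.shape[1] == 0 or tree_indices.notna().sum().sum() == 0:
        empty = pd.Series(dtype=float)
        return Chronology(site_id, parameter, empty, empty.astype(int), tree_indices, min_depth)
    depth = tree_indices.notna().sum(axis=1)
    vals = {}
    for year, row in tree_indices.iterrows():
        avail = row.dropna().to_numpy()
        vals[year] = biweight_mean(avail, c=c) if len(avail) else np.nan
    index = pd.Series(vals).sort_index()
    index[depth < min_depth] = np.nan
    return Chronology(site_id, parameter, index, depth.sort_index(), tree_indices, min_depth)


def detrend_and_build(
    ring_table: pd.DataFrame,
    parameter: str,
    *,
    site_id: str = "",
    cutoff_years: float = 100.0,
    min_depth: int = 4,
) -> Chronology:
    """Detrend ``parameter`` per tree from a ring table and build the
    site chronology. Trees whose series are too short are skipped."""
    cols = {}
    for tree, grp in ring_table.groupby("tree_id"):
        ser = grp.set_index("year")[parameter].sort_index()
        try:
            cols[tree] = spline_detrend(ser, cutoff_years)["index"]
        except AnalysisError:
            continue
    if not cols:
        raise AnalysisError(f"no tree series long enough to detrend for {parameter!r}")
    tree_idx = pd.DataFrame(cols)
    return build_chronology(tree_idx, site_id=site_id, parameter=parameter, min_depth=min_depth)


def pearson_r(a: pd.Series, b: pd.Series, min_overlap: int = 5) -> tuple[float, float]:
    """Pearson correlation of two year-indexed series over common years.

    Returns (r, two-sided p). Raises on fewer than ``min_overlap`` common
    years or zero variance in either series.
    """
    joined = pd.concat({"a": a, "b": b}, axis=1).dropna()
    if len(joined) < min_overlap:
        raise AnalysisError(
            f"only {len(joined)} overlapping years; {min_overlap} required"
        )
    x = joined["a"].to_numpy()
    y = joined["b"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise AnalysisError("undefined correlation: zero variance")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
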