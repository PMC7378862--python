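"""Superposed-epoch quantification of outbreak impacts.

Per tree × event, each ring-level parameter in relative years k = 1…8
(k = 1 is the outbreak start year) is expressed as a deviation ratio
against the fixed reference mean of the five pre-event years. Deviations
are pooled within site × severity and tested against the pooled
pre-window deviations with Welch's unequal-variance t-test; effect
duration is the run of consecutive significant years from k = 1.

Intra-ring impacts are assessed on profiles: a locally weighted (loess)
regression of a cell trait on the cell's relative position in the ring
(0–100 % distance from the ring border), with pointwise standard-error
envelopes; outbreak-year profiles are superposed against the mean
pre-event profile.

Finally, biomass-loss estimates from ring width (RW) and from ring wall
area (RWA) are contrasted with a paired test: RWA compounds the cell
number and wall-area reductions, while RW tracks cell number × radial
cell extents, so wall thinning opens a gap between the two.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError

DEFAULT_HORIZON = 8
DEFAULT_REF_WINDOW = 5
ALPHA = 0.05

SIGNIFICANCE_STARS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def stars(p: float) -> str:
    """Significance stars at 0.05 / 0.01 / 0.001 (empty if ns or NaN)."""
    if not np.isfinite(p):
        return ""
    for thr, s in SIGNIFICANCE_STARS:
        if p < thr:
            return s
    return ""


# --------------------------------------------------------------------------
# Welch's t-test
# --------------------------------------------------------------------------

@dataclass
class WelchResult:
    t: float
    df: float
    p: float
    testable: bool = True


def welch_test(a, b) -> WelchResult:
    """Welch's unequal-variance two-sample t-test (two-sided).

    Groups with fewer than two finite values, or both with zero
    variance, are reported not-testable (NaN statistics) rather than as a
    silent p of 0 or 1. Identical samples with positive variance give
    t = 0, p = 1.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if len(x) < 2 or len(y) < 2:
        return WelchResult(math.nan, math.nan, math.nan, testable=False)
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    if vx == 0 and vy == 0:
        return WelchResult(math.nan, math.nan, math.nan, testable=False)
    sx = vx / len(x)
    sy = vy / len(y)
    t = (x.mean() - y.mean()) / math.sqrt(sx + sy)
    df = (sx + sy) ** 2 / (
        (sx**2 / (len(x) - 1)) + (sy**2 / (len(y) - 1))
    )
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(float(t), float(df), float(p))


# --------------------------------------------------------------------------
# deviation ratios
# --------------------------------------------------------------------------

def tree_event_deviations(
    ring_table: pd.DataFrame,
    parameter: str,
    start_years: list[int],
    *,
    horizon: int = DEFAULT_HORIZON,
    ref_window: int = DEFAULT_REF_WINDOW,
) -> pd.DataFrame:
    """Per tree × event deviation ratios for one parameter.

    For every tree with a complete ``ref_window``-year pre-event record,
    the reference is the mean over those years (fixed across k) and the
    deviation at relative year k is value(start + k − 1) / reference.
    Pre-window per-year deviations (k = −ref_window … 0 → labelled
    negative) are returned too; they form the comparison sample for the
    significance tests. Trees missing any reference year are dropped for
    that event.

    Returns a tidy frame: tree_id, start_year, relative_year, deviation.
    """
    rows = []
    for tree, grp in ring_table.groupby("tree_id"):
        ser = grp.set_index("year")[parameter].sort_index()
        for start in start_years:
            ref_years = [start - j for j in range(1, ref_window + 1)]
            if not all(y in ser.index and np.isfinite(ser.loc[y]) for y in ref_years):
                continue
            ref = float(np.mean([ser.loc[y] for y in ref_years]))
            if not ref > 0:
                continue
            for j, y in enumerate(ref_years):
                rows.append((tree, start, -j - 1, float(ser.loc[y]) / ref))
            for k in range(1, horizon + 1):
                y = start + k - 1
                if y in ser.index and np.isfinite(ser.loc[y]):
                    rows.append((tree, start, k, float(ser.loc[y]) / ref))
    return pd.DataFrame(
        rows, columns=["tree_id", "start_year", "relative_year", "deviation"]
    )


def deviation_series(
    ring_table: pd.DataFrame,
    events: pd.DataFrame,
    parameters: list[str],
    *,
    site_id: str = "",
    horizon: int = DEFAULT_HORIZON,
    ref_window: int = DEFAULT_REF_WINDOW,
) -> pd.DataFrame:
    """Pooled epoch deviation table per site × severity × parameter.

    ``events`` needs columns ``start_year`` and ``severity``; tree × event
    deviations are pooled within each severity class. Per relative year
    k = 1…horizon the table reports the mean deviation ratio, percent
    deviation ((ratio − 1) × 100), Welch p-value against the pooled
    pre-window deviations, sample size and significance stars.
    """
    out = []
    for severity, ev_grp in events.groupby("severity"):
        starts = sorted(ev_grp["start_year"].astype(int))
        for param in parameters:
            dev = tree_event_deviations(
                ring_table, param, starts, horizon=horizon, ref_window=ref_window
            )
            if dev.empty:
                continue
            pre = dev.loc[dev["relative_year"] < 0, "deviation"].to_numpy()
            for k in range(1, horizon + 1):
                vals = dev.loc[dev["relative_year"] == k, "deviation"].to_numpy()
                if len(vals) == 0:
                    continue
                res = welch_test(vals, pre)
                ratio = float(vals.mean())
                out.append(
                    {
                        "site_id": site_id,
                        "severity": severity,
                        "parameter": param,
                        "relative_year": k,
                        "ratio": ratio,
                        "percent": (ratio - 1.0) * 100.0,
                        "p": res.p,
                        "n": len(vals),
                        "stars": stars(res.p),
                    }
                )
    if not out:
        return pd.DataFrame(
            columns=[
                "site_id", "severity", "parameter", "relative_year",
                "ratio", "percent", "p", "n", "stars",
            ]
        )
    return pd.DataFrame(out)


def effect_duration(p_values, alpha: float = ALPHA, mode: str = "consecutive") -> int:
    """Years of significant deviation.

    ``consecutive`` (default): length of the run of significant years
    starting at k = 1 — a non-significant (or untestable) year stops the
    count. ``total``: total number of significant years over the horizon.
    """
    ps = np.asarray(p_values, dtype=float)
    sig = np.isfinite(ps) & (ps < alpha)
    if mode == "total":
        return int(sig.sum())
    if mode != "consecutive":
        raise ValueError(f"unknown duration mode {mode!r}")
    n = 0
    for s in sig:
        if not s:
            break
        n += 1
    return n


def epoch_summary(
    deviations: pd.DataFrame, alpha: float = ALPHA, duration_mode: str = "consecutive"
) -> pd.DataFrame:
    """Duration and maximum deviation per site × severity × parameter.

    Maximum deviation is the percent deviation in the year of strongest
    reduction (most negative percent) over the horizon.
    """
    rows = []
    for (site, sev, param), grp in deviations.groupby(
        ["site_id", "severity", "parameter"]
    ):
        grp = grp.sort_values("relative_year")
        rows.append(
            {
                "site_id": site,
                "severity": sev,
                "parameter": param,
                "duration": effect_duration(grp["p"], alpha, duration_mode),
                "max_deviation": float(grp["percent"].min()),
                "year1_percent": float(
                    grp.loc[grp["relative_year"] == 1, "percent"].iloc[0]
                )
                if (grp["relative_year"] == 1).any()
                else np.nan,
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# intra-ring profiles (loess with SE envelopes)
# --------------------------------------------------------------------------

def relative_positions(ring_cells: pd.DataFrame) -> pd.Series:
    """Percent distance of each cell from the ring border at ring start.

    Uses the stored ``relative_position_pct`` when present; otherwise the
    cumulative radial extent (CLD + 2 × radial wall thickness) of the
    preceding cells in the cell's radial file, at the cell's midpoint,
    over the file's total extent, × 100.
    """
    if (
        "relative_position_pct" in ring_cells.columns
        and ring_cells["relative_position_pct"].notna().all()
    ):
        return ring_cells["relative_position_pct"].astype(float)
    if "radial_file_id" not in ring_cells.columns:
        raise AnalysisError("relative_positions needs radial_file_id or stored positions")
    rank_col = "file_rank" if "file_rank" in ring_cells.columns else "cell_index"
    out = pd.Series(np.nan, index=ring_cells.index)
    for _, grp in ring_cells.groupby(["tree_id", "year", "radial_file_id"]):
        g = grp.sort_values(rank_col)
        width = g["CLD"].to_numpy() + 2.0 * g["CWT_rad"].to_numpy()
        cum = np.cumsum(width)
        mid = cum - width / 2.0
        out.loc[g.index] = 100.0 * mid / cum[-1]
    return out


def loess_fit(
    x: np.ndarray,
    y: np.ndarray,
    grid: np.ndarray,
    *,
    span: float = 0.3,
) -> tuple[np.ndarray, np.ndarray]:
    """Local linear regression with tricube weights, evaluated on ``grid``.

    Returns (fit, se). The bandwidth at each grid point is the distance to
    the ⌈span·n⌉-th nearest data point. Pointwise standard errors are
    σ̂ ‖l(x₀)‖ with l the equivalent-kernel weights of the local fit and
    σ̂² the residual variance of the data around the interpolated fit.
    With span = 1 and exactly linear data the fit equals the ordinary
    least-squares line.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 10:
        raise AnalysisError(f"loess_fit needs at least 10 points, got {n}")
    k = max(2, int(math.ceil(span * n)))
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    fit = np.empty(len(grid))
    l2 = np.empty(len(grid))  # sum of squared equivalent-kernel weights
    for j, x0 in enumerate(grid):
        d = np.abs(xs - x0)
        h = np.partition(d, k - 1)[k - 1]
        if h == 0:
            h = max(d.max(), 1.0) * 1e-9
        u = d / h
        w = np.where(u < 1.0, (1.0 - u**3) ** 3, 0.0)
        if w.sum() == 0 or (w > 0).sum() < 2:
            fit[j] = np.nan
            l2[j] = np.nan
            continue
        # weighted linear fit centred on x0: value at x0 is the intercept
        xc = xs - x0
        sw = w.sum()
        swx = (w * xc).sum()
        swxx = (w * xc * xc).sum()
        det = sw * swxx - swx * swx
        if det <= 0:
            wt = w / sw
            fit[j] = float((wt * ys).sum())
            l2[j] = float((wt**2).sum())
            continue
        # equivalent kernel for the intercept
        l = (swxx * w - swx * w * xc) / det
        fit[j] = float((l * ys).sum())
        l2[j] = float((l * l).sum())
    # residual variance around the interpolated fit
    ok = np.isfinite(fit)
    if ok.sum() >= 2:
        interp = np.interp(xs, grid[ok], fit[ok])
        resid = ys - interp
        dof = max(n - 2, 1)
        sigma2 = float((resid**2).sum()) / dof
    else:
        sigma2 = float("nan")
    se = np.sqrt(sigma2 * l2)
    return fit, se


def intra_ring_profile(
    cells: pd.DataFrame,
    parameter: str,
    *,
    grid_step: float = 1.0,
    span: float = 0.3,
) -> pd.DataFrame:
    """Loess profile of a cell trait versus relative ring position.

    Cells from all rings in ``cells`` are pooled; positions come from
    :func:`relative_positions`. Returns a frame with ``position_pct``,
    ``fit`` and ``se`` on the fixed grid 0…100 % in ``grid_step`` steps.
    Fewer than 10 cells raises :class:`~qwa.errors.AnalysisError`.
    """
    pos = relative_positions(cells).to_numpy(dtype=float)
    val = cells[parameter].to_numpy(dtype=float)
    ok = np.isfinite(pos) & np.isfinite(val)
    if ok.sum() < 10:
        raise AnalysisError(
            f"too few cells ({int(ok.sum())}) to fit an intra-ring profile"
        )
    grid = np.arange(0.0, 100.0 + 1e-9, grid_step)
    fit, se = loess_fit(pos[ok], val[ok], grid, span=span)
    return pd.DataFrame({"position_pct": grid, "fit": fit, "se": se})


def superpose_profiles(
    year_profiles: dict[str, pd.DataFrame],
    reference_labels: list[str],
) -> pd.DataFrame:
    """Difference of each profile from the mean pre-event reference profile.

    All profiles must share the same position grid. The reference is the
    pointwise mean of the profiles named in ``reference_labels``; its SE
    is the propagated sqrt(Σ se²)/m. Output is tidy: label, position_pct,
    fit, se, diff, diff_se (reference rows carry diff = 0).
    """
    grids = [tuple(np.round(p["position_pct"].to_numpy(), 9)) for p in year_profiles.values()]
    if len(set(grids)) != 1:
        raise AnalysisError("profile grids do not match; cannot superpose")
    refs = [year_profiles[lbl] for lbl in reference_labels]
    if not refs:
        raise AnalysisError("no reference profiles given")
    ref_fit = np.mean([r["fit"].to_numpy() for r in refs], axis=0)
    ref_se = np.sqrt(np.sum([r["se"].to_numpy() ** 2 for r in refs], axis=0)) / len(refs)
    rows = []
    for label, prof in year_profiles.items():
        diff = prof["fit"].to_numpy() - ref_fit
        diff_se = np.sqrt(prof["se"].to_numpy() ** 2 + ref_se**2)
        rows.append(
            pd.DataFrame(
                {
                    "label": label,
                    "position_pct": prof["position_pct"].to_numpy(),
                    "fit": prof["fit"].to_numpy(),
                    "se": prof["se"].to_numpy(),
                    "diff": diff,
                    "diff_se": diff_se,
                    "is_reference": label in reference_labels,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


# --------------------------------------------------------------------------
# RW vs RWA biomass-loss contrast
# --------------------------------------------------------------------------

@dataclass
class PairedContrast:
    mean_gap_pct: float  # mean (RW deviation − RWA deviation) × 100
    t: float
    df: float
    p: float
    n_pairs: int
    pairs: pd.DataFrame  # tree_id, start_year, rw_dev, rwa_dev
    testable: bool = True


def rw_vs_rwa_contrast(
    ring_table: pd.DataFrame,
    start_years: list[int],
    *,
    ref_window: int = DEFAULT_REF_WINDOW,
) -> PairedContrast:
    """Contrast year-1 biomass-loss estimates from RW and from RWA.

    Per tree × event the year-1 deviation ratio of ring width and of ring
    wall area (same reference convention as the epoch analysis) form a
    pair; the paired differences are tested against zero (one-sample t on
    the differences — the paired form of the Welch convention). Returns
    the mean percent gap (positive when RW underestimates the loss).
    """
    rw = tree_event_deviations(ring_table, "RW", start_years, horizon=1, ref_window=ref_window)
    rwa = tree_event_deviations(ring_table, "RWA", start_years, horizon=1, ref_window=ref_window)
    rw1 = rw[rw["relative_year"] == 1].set_index(["tree_id", "start_year"])["deviation"]
    rwa1 = rwa[rwa["relative_year"] == 1].set_index(["tree_id", "start_year"])["deviation"]
    pairs = pd.concat({"rw_dev": rw1, "rwa_dev": rwa1}, axis=1).dropna().reset_index()
    n = len(pairs)
    if n < 3:
        return PairedContrast(math.nan, math.nan, math.nan, math.nan, n, pairs, testable=False)
    d = (pairs["rw_dev"] - pairs["rwa_dev"]).to_numpy()
    mean_gap = float(d.mean()) * 100.0
    sd = d.std(ddof=1)
    if sd == 0:
        return PairedContrast(mean_gap, 0.0, float(n - 1), 1.0, n, pairs)
    t = float(d.mean() / (sd / math.sqrt(n)))
    df = float(n - 1)
    p = float(2.0 * stats.t.sf(abs(t), df))
    return PairedContrast(mean_gap, t, df, p, n, pairs)
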