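"""Bootstrap correlations between chronologies and monthly climate.

For each month in the growing-season window (April–October by default)
and each climate variable (mean temperature, precipitation sum), the
Pearson correlation with the chronology is bootstrapped by resampling
year pairs with replacement; the reported r is the bootstrap mean and
significance means the 95 % percentile interval excludes zero.
Correlations can be run both including and excluding outbreak years
(optionally with a configurable number of carry-over years after each
start year), to separate defoliation signal from climate signal.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import AnalysisError

DEFAULT_MONTHS: tuple[int, ...] = (4, 5, 6, 7, 8, 9, 10)
MIN_OVERLAP = 25

_VARIABLES = {
    "T": "temperature_mean_C",
    "P": "precipitation_sum_mm",
}


def expand_event_years(start_years: Iterable[int], following: int = 2) -> set[int]:
    """Outbreak exclusion window: each start year plus ``following`` years
    (defoliation effects carry over for several seasons)."""
    out: set[int] = set()
    for y in start_years:
        out.update(range(int(y), int(y) + following + 1))
    return out


def _bootstrap_r(x: np.ndarray, y: np.ndarray, n_boot: int, rng: np.random.Generator):
    n = len(x)
    idx = rng.integers(0, n, size=(n_boot, n))
    xb = x[idx]
    yb = y[idx]
    xc = xb - xb.mean(axis=1, keepdims=True)
    yc = yb - yb.mean(axis=1, keepdims=True)
    num = (xc * yc).sum(axis=1)
    den = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    ok = den > 0
    rs = np.full(n_boot, np.nan)
    rs[ok] = num[ok] / den[ok]
    rs = rs[np.isfinite(rs)]
    return float(np.mean(rs)), float(np.percentile(rs, 2.5)), float(np.percentile(rs, 97.5))


def monthly_correlations(
    chronology: pd.Series,
    climate: pd.DataFrame,
    *,
    chronology_id: str = "",
    months: Sequence[int] = DEFAULT_MONTHS,
    n_boot: int = 1000,
    seed: int | None = None,
    exclude_years: Iterable[int] | None = None,
) -> pd.DataFrame:
    """Bootstrap monthly climate correlations for one chronology.

    Parameters
    ----------
    chronology : detrended index series keyed by year (NaNs ignored).
    climate : validated monthly climate table
        (year, month, temperature_mean_C, precipitation_sum_mm).
    months : calendar months analysed (default April–October).
    n_boot : bootstrap replicates per cell.
    seed : seed for the resampling RNG; identical seed and inputs give
        identical results.
    exclude_years : years removed before resampling (e.g. outbreak start
        years expanded with :func:`expand_event_years`).

    Returns
    -------
    Tidy frame: chronology_id, variable (``T``/``P``), month, r, ci_low,
    ci_high, significant, n_years, outbreaks_excluded.

    Raises
    ------
    AnalysisError : fewer than 25 overlapping years after exclusions.
    """
    rng = np.random.default_rng(seed)
    chron = chronology.dropna()
    excluded = set(int(y) for y in exclude_years) if exclude_years else set()
    if excluded:
        chron = chron[~chron.index.isin(excluded)]
    rows = []
    wide = climate.pivot(index="year", columns="month")
    for var, col in _VARIABLES.items():
        for month in months:
            if (col, month) not in wide.columns:
                raise AnalysisError(f"climate table lacks month {month} for {col!r}")
            clim = wide[(col, month)].dropna()
            joined = pd.concat({"c": chron, "x": clim}, axis=1).dropna()
            n = len(joined)
            if n < MIN_OVERLAP:
                raise AnalysisError(
                    f"only {n} overlapping years for {var} month {month}; "
                    f"{MIN_OVERLAP} required"
                )
            r, lo, hi = _bootstrap_r(
                joined["c"].to_numpy(), joined["x"].to_numpy(), n_boot, rng
            )
            rows.append(
                {
                    "chronology_id": chronology_id,
                    "variable": var,
                    "month": month,
                    "r": r,
                    "ci_low": lo,
                    "ci_high": hi,
                    "significant": bool(lo > 0 or hi < 0),
                    "n_years": n,
                    "outbreaks_excluded": bool(excluded),
                }
            )
    return pd.DataFrame(rows)
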