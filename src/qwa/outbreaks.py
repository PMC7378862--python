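"""Outbreak detection and severity classification.

Defoliator outbreaks depress wall thickening; candidate start years are
years where the host's cell-wall-thickness (CWT) chronology drops by more
than a threshold fraction relative to the mean of the preceding five
years. A synchronous decline in a non-host (climate control) chronology
vetoes the candidate, since both species share the climate signal but
only the host is defoliated. Candidates closer together than a minimum
separation are merged, keeping the strongest decline. Detected events are
split into equal-size high/low severity classes on the first-year CWT
ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AnalysisError

DEFAULT_DELTA = 0.10
DEFAULT_MIN_SEPARATION = 6
REF_WINDOW = 5


@dataclass
class OutbreakEvent:
    """A detected outbreak start year with its detection trace."""

    site_id: str
    start_year: int
    first_year_cwt_ratio: float
    severity: str = "unclassified"  # "high" | "low" | "unclassified"
    vetoed_by_nonhost: bool = False
    trace: dict = field(default_factory=dict, repr=False)


def _candidate_ratios(
    chron: pd.Series, delta: float, ref_window: int
) -> pd.Series:
    """Ratio value(t) / mean(value(t-ref_window .. t-1)) for each year with
    a complete reference window; NaN elsewhere."""
    ser = chron.dropna().sort_index()
    ratios = {}
    for t in ser.index:
        ref_years = [t - k for k in range(1, ref_window + 1)]
        if all(y in ser.index for y in ref_years):
            ref = float(np.mean([ser.loc[y] for y in ref_years]))
            if ref > 0:
                ratios[t] = float(ser.loc[t]) / ref
    return pd.Series(ratios, dtype=float)


def detect_outbreaks(
    host_chronology: pd.Series,
    nonhost_chronology: pd.Series | None = None,
    *,
    site_id: str = "",
    delta: float = DEFAULT_DELTA,
    min_separation: int = DEFAULT_MIN_SEPARATION,
    ref_window: int = REF_WINDOW,
) -> list[OutbreakEvent]:
    """Detect outbreak start years from a host CWT chronology.

    A year t is a candidate when host(t) < (1 − delta) × mean(host over
    the ``ref_window`` preceding years). If a non-host chronology is
    given, candidates where the non-host declines by at least the same
    fraction in the same year are vetoed as climate-driven. Among
    candidates closer than ``min_separation`` years the strongest
    relative decline wins. The detection rule is invariant to scaling the
    chronology by a positive constant.
    """
    ser = host_chronology.dropna()
    if len(ser) == 0:
        raise AnalysisError("empty host chronology")
    if len(ser) < ref_window + 10:
        raise AnalysisError(
            f"host chronology has {len(ser)} years; at least {ref_window + 10} required"
        )
    ratios = _candidate_ratios(ser, delta, ref_window)
    candidates = ratios[ratios < 1.0 - delta]

    vetoed: set[int] = set()
    if nonhost_chronology is not None and len(candidates):
        nh_ratios = _candidate_ratios(nonhost_chronology.dropna(), delta, ref_window)
        for t in candidates.index:
            if t in nh_ratios.index and nh_ratios.loc[t] < 1.0 - delta:
                vetoed.add(int(t))
    kept = candidates.drop(index=list(vetoed), errors="ignore")

    # greedy strongest-first selection enforcing min_separation
    selected: list[int] = []
    for t in kept.sort_values().index:  # ascending ratio = strongest first
        if all(abs(t - s) >= min_separation for s in selected):
            selected.append(int(t))
    events = [
        OutbreakEvent(
            site_id=site_id,
            start_year=t,
            first_year_cwt_ratio=float(ratios.loc[t]),
            trace={
                "candidates": {int(y): float(r) for y, r in candidates.items()},
                "vetoed": sorted(vetoed),
            },
        )
        for t in sorted(selected)
    ]
    return events


def classify_severity(events: list[OutbreakEvent]) -> list[OutbreakEvent]:
    """Split events into equal-size high/low severity classes.

    Events are ranked by first-year CWT ratio ascending (strongest
    reduction first; ties broken by earlier year); the lower ⌊n/2⌋ are
    labelled ``high``, the rest ``low`` (odd counts put the median event
    in ``low``). With fewer than two events all stay ``unclassified``.
    """
    if len(events) < 2:
        for ev in events:
            ev.severity = "unclassified"
        return events
    order = sorted(events, key=lambda e: (e.first_year_cwt_ratio, e.start_year))
    n_high = len(order) // 2
    for i, ev in enumerate(order):
        ev.severity = "high" if i < n_high else "low"
    return sorted(events, key=lambda e: e.start_year)


def events_to_frame(events: list[OutbreakEvent]) -> pd.DataFrame:
    """Tabulate events (site_id, start_year, severity, first_year_cwt_ratio)."""
    return pd.DataFrame(
        [
            {
                "site_id": e.site_id,
                "start_year": e.start_year,
                "severity": e.severity,
                "first_year_cwt_ratio": e.first_year_cwt_ratio,
            }
            for e in events
        ]
    )


def events_from_years(
    years_and_sites: pd.DataFrame,
    host_chronology: pd.Series | None = None,
    *,
    ref_window: int = REF_WINDOW,
) -> list[OutbreakEvent]:
    """Build events from known outbreak start years (published record mode).

    ``years_and_sites`` needs columns ``site_id`` and ``start_year``.
    First-year CWT ratios are scored from the host chronology when
    supplied (NaN otherwise), so severity classification still applies.
    """
    events = []
    ratios = (
        _candidate_ratios(host_chronology.dropna(), 0.0, ref_window)
        if host_chronology is not None
        else pd.Series(dtype=float)
    )
    for _, row in years_and_sites.iterrows():
        t = int(row["start_year"])
        events.append(
            OutbreakEvent(
                site_id=str(row["site_id"]),
                start_year=t,
                first_year_cwt_ratio=float(ratios.get(t, np.nan)),
            )
        )
    return sorted(events, key=lambda e: e.start_year)
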