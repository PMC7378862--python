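"""Readers and writers for the external formats used by the pipeline.

Cell-level anatomical measurements arrive as delimited text with one row
per tracheid (the layout produced by image-analysis tools such as ROXAS,
whose column names vary by version — hence the alias mechanism). Ring
widths use the Tucson decadal (.rwl) format, the community standard for
dendrochronological series. Monthly climate is a plain delimited table.
"""

from __future__ import annotations

import io as _stdio
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError, ValidationError

# --------------------------------------------------------------------------
# cell tables
# --------------------------------------------------------------------------

#: canonical cell-table columns (CellTableSchema)
REQUIRED_CELL_COLUMNS: tuple[str, ...] = (
    "tree_id",
    "year",
    "cell_index",
    "lumen_radial_diameter_um",
    "lumen_area_um2",
    "wall_thickness_radial_um",
    "wall_thickness_tangential_um",
    "wall_area_um2",
)

OPTIONAL_CELL_COLUMNS: tuple[str, ...] = (
    "radial_file_id",
    "relative_position_pct",
)

#: columns that must be strictly positive
_POSITIVE_CELL_COLUMNS: tuple[str, ...] = (
    "lumen_radial_diameter_um",
    "lumen_area_um2",
    "wall_thickness_radial_um",
    "wall_thickness_tangential_um",
    "wall_area_um2",
)

#: common ROXAS-style header spellings mapped onto the canonical schema;
#: extendable via the ``aliases`` argument of :func:`read_cell_table`.
DEFAULT_COLUMN_ALIASES: dict[str, str] = {
    "tree": "tree_id",
    "id": "tree_id",
    "yr": "year",
    "cid": "cell_index",
    "cell": "cell_index",
    "rrad": "radial_file_id",
    "radfile": "radial_file_id",
    "dr": "lumen_radial_diameter_um",
    "ldrad": "lumen_radial_diameter_um",
    "la": "lumen_area_um2",
    "lum_area": "lumen_area_um2",
    "cwtrad": "wall_thickness_radial_um",
    "cwttan": "wall_thickness_tangential_um",
    "cwa": "wall_area_um2",
    "wall_area": "wall_area_um2",
    "relpos": "relative_position_pct",
    "rraddistr": "relative_position_pct",
}


def read_cell_table(
    path: str | Path,
    *,
    delimiter: str = ",",
    aliases: Mapping[str, str] | None = None,
    year_range: tuple[int, int] = (1400, 2100),
) -> pd.DataFrame:
    """Read and validate a cell-level anatomical measurement table.

    Parameters
    ----------
    path : path to a delimited text file with one row per tracheid.
    delimiter : field separator, default comma.
    aliases : extra header-name → canonical-name mappings (case-insensitive),
        merged over :data:`DEFAULT_COLUMN_ALIASES`.
    year_range : plausible calendar-year window; years outside it raise
        :class:`~qwa.errors.ValidationError`.

    Returns
    -------
    DataFrame with canonical column names, sorted by
    ``(tree_id, year, cell_index)``. Row count equals the file's row count.

    Raises
    ------
    SchemaError : a required column is absent (the message names it).
    ValidationError : a non-positive dimension, duplicate key, or
        out-of-range year (the message cites the offending data row number,
        1-based, excluding the header).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=delimiter)
    alias_map = {k.lower(): v for k, v in DEFAULT_COLUMN_ALIASES.items()}
    if aliases:
        alias_map.update({k.lower(): v for k, v in aliases.items()})
    canonical = set(REQUIRED_CELL_COLUMNS) | set(OPTIONAL_CELL_COLUMNS)
    rename: dict[str, str] = {}
    for col in df.columns:
        low = col.strip().lower()
        if low in canonical:
            rename[col] = low
        elif low in alias_map:
            rename[col] = alias_map[low]
    df = df.rename(columns=rename)

    for col in REQUIRED_CELL_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"cell table {path.name!r} is missing required column {col!r}")

    # validation with 1-based data-row numbers
    for col in _POSITIVE_CELL_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = ~(vals > 0)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise ValidationError(
                f"column {col!r} must be strictly positive; first violation at data row {row}"
            )
        df[col] = vals.astype(float)

    df["year"] = df["year"].astype(int)
    lo, hi = year_range
    bad = ~df["year"].between(lo, hi)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise ValidationError(
            f"year outside plausible range [{lo}, {hi}] at data row {row}"
        )
    df["cell_index"] = df["cell_index"].astype(int)

    dup = df.duplicated(subset=["tree_id", "year", "cell_index"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0]) + 1
        raise ValidationError(
            f"duplicate (tree_id, year, cell_index) at data row {row}"
        )

    if "relative_position_pct" in df.columns:
        pos = pd.to_numeric(df["relative_position_pct"], errors="coerce")
        bad = pos.notna() & ~pos.between(0, 100)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise ValidationError(
                f"relative_position_pct outside [0, 100] at data row {row}"
            )

    return df.sort_values(["tree_id", "year", "cell_index"], kind="stable").reset_index(drop=True)


def write_cell_table(cells: pd.DataFrame, path: str | Path, *, delimiter: str = ",") -> None:
    """Write a cell table in the canonical delimited layout (UTF-8)."""
    cols = [c for c in REQUIRED_CELL_COLUMNS if c in cells.columns]
    cols += [c for c in OPTIONAL_CELL_COLUMNS if c in cells.columns]
    cols += [c for c in cells.columns if c not in cols]
    cells.to_csv(path, sep=delimiter, index=False, columns=cols, encoding="utf-8")


# --------------------------------------------------------------------------
# Tucson .rwl ring-width files
# --------------------------------------------------------------------------

_STOP_001MM = -9999  # sentinel for 0.001 mm units
_STOP_01MM = 999  # sentinel for 0.01 mm units


def read_rwl(path: str | Path) -> pd.DataFrame:
    """Read a Tucson decadal-format ring-width file.

    Each line carries a series id, the decade's first year, and up to ten
    values. The end-of-series sentinel identifies the units: ``999`` means
    values are hundredths of a millimetre, ``-9999`` thousandths.

    Returns a DataFrame indexed by calendar year with one column per
    series, values in millimetres; years are contiguous per series.
    """
    path = Path(path)
    series: dict[str, dict[int, float]] = {}
    units: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            sid = line[:8].strip()
            rest = line[8:].split()
            if not sid or len(rest) < 2:
                raise ParseError(f"{path.name}:{lineno}: malformed decade line")
            try:
                decade = int(rest[0])
                vals = [int(v) for v in rest[1:]]
            except ValueError as exc:
                raise ParseError(f"{path.name}:{lineno}: non-numeric field ({exc})") from exc
            store = series.setdefault(sid, {})
            for i, v in enumerate(vals):
                if v == _STOP_001MM:
                    units[sid] = 0.001
                    break
                if v == _STOP_01MM:
                    units[sid] = 0.01
                    break
                store[decade + i] = float(v)
    if not series:
        raise ParseError(f"{path.name}: no series found")
    frames = {}
    for sid, store in series.items():
        scale = units.get(sid, 0.01)
        years = sorted(store)
        if years and years[-1] - years[0] + 1 != len(years):
            raise ParseError(f"{path.name}: series {sid!r} has non-contiguous years")
        frames[sid] = pd.Series(
            [store[y] * scale for y in years], index=pd.Index(years, name="year")
        )
    return pd.DataFrame(frames).sort_index()


def write_rwl(rw: pd.DataFrame, path: str | Path, *, units: str = "0.01mm") -> None:
    """Write ring widths (mm) to a Tucson decadal file.

    ``units`` is ``"0.01mm"`` (sentinel 999) or ``"0.001mm"`` (sentinel
    -9999); the latter preserves 0.001 mm precision on round-trip.
    """
    if units == "0.01mm":
        scale, stop = 100.0, _STOP_01MM
    elif units == "0.001mm":
        scale, stop = 1000.0, _STOP_001MM
    else:
        raise ValueError(f"unknown units {units!r}")
    buf = _stdio.StringIO()
    for sid in rw.columns:
        ser = rw[sid].dropna()
        years = ser.index.to_numpy(dtype=int)
        first, last = int(years.min()), int(years.max())
        y = first
        while y <= last:
            decade_end = (y // 10) * 10 + 9
            row_years = range(y, min(decade_end, last) + 1)
            fields = [f"{int(round(ser.loc[yy] * scale)):>6d}" for yy in row_years]
            if row_years[-1] == last:
                fields.append(f"{stop:>6d}")
            buf.write(f"{str(sid)[:8]:<8s}{y:>6d}" + "".join(fields) + "\n")
            y = decade_end + 1
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


# --------------------------------------------------------------------------
# climate tables
# --------------------------------------------------------------------------

CLIMATE_COLUMNS = ("year", "month", "temperature_mean_C", "precipitation_sum_mm")


def read_climate(path: str | Path, *, delimiter: str = ",") -> pd.DataFrame:
    """Read and validate a monthly climate table.

    Expects columns ``year, month, temperature_mean_C, precipitation_sum_mm``
    (case-insensitive). One row per (year, month); months must be in 1–12
    and contiguous within the covered span; precipitation non-negative.
    """
    df = pd.read_csv(path, sep=delimiter)
    df = df.rename(columns={c: c.strip().lower() if c.strip().lower() in ("year", "month") else c for c in df.columns})
    low = {c.lower(): c for c in df.columns}
    rename = {}
    for want in CLIMATE_COLUMNS:
        if want in df.columns:
            continue
        if want.lower() in low:
            rename[low[want.lower()]] = want
        else:
            raise SchemaError(f"climate table is missing column {want!r}")
    df = df.rename(columns=rename)[list(CLIMATE_COLUMNS)]
    df["year"] = df["year"].astype(int)
    df["month"] = df["month"].astype(int)
    if not df["month"].between(1, 12).all():
        bad = df.loc[~df["month"].between(1, 12)].index[0] + 1
        raise ValidationError(f"month outside 1..12 at data row {bad}")
    if (df["precipitation_sum_mm"] < 0).any():
        bad = df.loc[df["precipitation_sum_mm"] < 0].index[0] + 1
        raise ValidationError(f"negative precipitation at data row {bad}")
    if df.duplicated(subset=["year", "month"]).any():
        raise ValidationError("duplicate (year, month) entries in climate table")
    df = df.sort_values(["year", "month"]).reset_index(drop=True)
    # contiguity across the covered span
    idx = df["year"] * 12 + (df["month"] - 1)
    if len(idx) > 1 and not (np.diff(idx.to_numpy()) == 1).all():
        raise ValidationError("climate months are not contiguous across the covered span")
    return df


def write_climate(climate: pd.DataFrame, path: str | Path, *, delimiter: str = ",") -> None:
    climate.to_csv(path, sep=delimiter, index=False, columns=list(CLIMATE_COLUMNS), encoding="utf-8")


# --------------------------------------------------------------------------
# generic result tables
# --------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path, *, delimiter: str = ",") -> None:
    """Write an analysis result table (UTF-8, period decimal separator)."""
    df.to_csv(path, sep=delimiter, index=False, encoding="utf-8")


def read_events_table(path: str | Path, *, delimiter: str = ",") -> pd.DataFrame:
    """Read a known-outbreak-years table with columns site_id, start_year."""
    df = pd.read_csv(path, sep=delimiter)
    for col in ("site_id", "start_year"):
        if col not in df.columns:
            raise SchemaError(f"events table is missing column {col!r}")
    df["start_year"] = df["start_year"].astype(int)
    return df
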