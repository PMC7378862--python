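"""Synthetic tracheidogram, ring-width and climate generator.

The generator emulates the statistical structure of a two-site,
century-long conifer quantitative-wood-anatomy study: several host
(larch-like) and non-host (spruce-like) trees per site, realistic
earlywood→latewood intra-ring gradients of lumen diameter and wall
thickness, monthly climate with AR(1) temperature anomalies forcing cell
number (May–August) and latewood wall thickness (late summer), and a
schedule of defoliator-outbreak pulses that hit only the host species:
cell number strongly reduced, wall thickness moderately (weighted toward
the latewood, with a 3 µm biomechanical floor), early-ring lumen diameter
slightly reduced and late-ring slightly increased, all recovering
geometrically over the following years.

Every dataset carries a *truth record* (event years, injected multipliers,
climate coupling coefficients) sufficient to score detection, parameter
recovery and climate-coupling tests without any other information.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

import yaml

from . import io as qio
from .errors import ConfigurationError

# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

#: default outbreak schedule (20th-century events at the study sites)
DEFAULT_HIGH_YEARS: tuple[int, ...] = (1908, 1945, 1963, 1972)
DEFAULT_LOW_YEARS: tuple[int, ...] = (1915, 1935, 1954, 1981)


@dataclass
class OutbreakPulse:
    """One outbreak: first year, severity label and year-1 multipliers.

    ``cwt_mult`` is the *ring-mean* wall-thickness multiplier; within the
    ring it is redistributed toward the latewood (see
    :func:`latewood_weight`). ``cld_early_mult``/``cld_late_mult`` apply
    to the lumen diameter at ring start/end, linearly interpolated in
    between. Multipliers recover geometrically toward 1 with the
    per-parameter rates in :class:`SimulationConfig`.
    """

    start_year: int
    severity: str = "high"  # "high" | "low"
    cn_mult: float = 0.45
    cwt_mult: float = 0.70
    cld_early_mult: float = 0.93
    cld_late_mult: float = 1.05


def default_schedule() -> list[OutbreakPulse]:
    events = [OutbreakPulse(y, "high") for y in DEFAULT_HIGH_YEARS]
    events += [
        OutbreakPulse(y, "low", cn_mult=0.70, cwt_mult=0.85,
                      cld_early_mult=0.97, cld_late_mult=1.02)
        for y in DEFAULT_LOW_YEARS
    ]
    return sorted(events, key=lambda e: e.start_year)


@dataclass
class ClimateConfig:
    """Monthly climate model: seasonal means plus AR(1) anomalies.

    Seasonal temperature means approximate a subalpine station
    (~1,400 m a.s.l.); precipitation is lognormal around its seasonal
    mean. Anomaly truth is retained for coupling tests.
    """

    t_seasonal_mean_C: tuple[float, ...] = (
        -2.5, -1.8, 1.0, 4.0, 8.5, 12.0, 14.5, 14.0, 10.5, 6.5, 1.5, -1.5
    )
    t_anom_sd_C: float = 1.5
    t_anom_ar1: float = 0.3
    p_seasonal_mean_mm: tuple[float, ...] = (
        70, 65, 70, 70, 80, 90, 85, 90, 75, 80, 80, 70
    )
    p_log_sd: float = 0.4


@dataclass
class SimulationConfig:
    """All generator knobs; defaults define the emulated study conditions."""

    site_id: str = "S19"
    species: str = "host"  # "host" | "nonhost"
    n_trees: int = 7
    year_start: int = 1900
    year_end: int = 2017
    n_files: int = 3  # radial files measured per tree and ring

    # baseline ring structure
    cn_mean: float = 50.0  # mean cells per radial file
    # earlywood -> latewood profiles along relative (rank) position in [0, 1]
    cld_earlywood_um: float = 42.0
    cld_latewood_um: float = 8.0
    cld_onset: float = 0.68  # transition midpoint
    cld_width: float = 0.07
    cwt_earlywood_um: float = 3.5
    cwt_latewood_um: float = 8.0
    cwt_onset: float = 0.75
    cwt_width: float = 0.06
    cwt_floor_um: float = 3.0  # biomechanical minimum wall thickness
    cwt_tan_ratio: float = 0.9  # tangential / radial wall thickness
    lumen_eccentricity: float = 0.9  # tangential / radial lumen diameter

    # noise (lognormal sigmas)
    tree_sd_cn: float = 0.10
    tree_sd_cwt: float = 0.05
    tree_sd_cld: float = 0.05
    ring_sd_cn: float = 0.08
    ring_sd_cwt: float = 0.04
    ring_sd_cld: float = 0.03
    cell_sd: float = 0.08
    file_count_sd: float = 0.05  # lognormal jitter of cells per radial file

    # climate coupling (per °C of the relevant seasonal anomaly)
    beta_cn_host: float = 0.05  # May-Aug temperature -> cell number
    beta_cn_nonhost: float = 0.02
    beta_cwt_latewood: float = 0.04  # Aug-Sep temperature -> latewood CWT

    # outbreak carry-over: geometric recovery rate toward 1 per parameter
    recovery_cn: float = 0.65
    recovery_cwt: float = 0.45
    recovery_cld: float = 0.30

    climate: ClimateConfig = field(default_factory=ClimateConfig)
    outbreaks: list[OutbreakPulse] = field(default_factory=default_schedule)

    def __post_init__(self):
        if self.species not in ("host", "nonhost"):
            raise ConfigurationError(f"unknown species {self.species!r}")
        for ev in self.outbreaks:
            for m in (ev.cn_mult, ev.cwt_mult, ev.cld_early_mult, ev.cld_late_mult):
                if not m > 0:
                    raise ConfigurationError("outbreak multipliers must be positive")
        if self.cn_mean < 3:
            raise ConfigurationError("cn_mean must be at least 3")
        if self.cwt_earlywood_um * min(1.0, 1.0) <= 0:
            raise ConfigurationError("wall thickness baseline must be positive")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)

    # -- (de)serialization ---------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        d = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if "climate" in d and isinstance(d["climate"], dict):
            for k in ("t_seasonal_mean_C", "p_seasonal_mean_mm"):
                if k in d["climate"]:
                    d["climate"][k] = tuple(d["climate"][k])
            d["climate"] = ClimateConfig(**d["climate"])
        if "outbreaks" in d:
            d["outbreaks"] = [
                OutbreakPulse(**ev) if isinstance(ev, dict) else ev
                for ev in d["outbreaks"]
            ]
        return cls(**d)


# ---------------------------------------------------------------------------
# baseline intra-ring profiles
# ---------------------------------------------------------------------------

def _logistic(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def cld_profile(p: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    """Baseline radial lumen diameter (µm) vs relative position p ∈ [0, 1]."""
    s = _logistic((np.asarray(p) - cfg.cld_onset) / cfg.cld_width)
    return cfg.cld_earlywood_um + (cfg.cld_latewood_um - cfg.cld_earlywood_um) * s


def cwt_profile(p: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    """Baseline radial wall thickness (µm) vs relative position p ∈ [0, 1]."""
    s = _logistic((np.asarray(p) - cfg.cwt_onset) / cfg.cwt_width)
    return cfg.cwt_earlywood_um + (cfg.cwt_latewood_um - cfg.cwt_earlywood_um) * s


def latewood_weight(p: np.ndarray) -> np.ndarray:
    """Mean-one weight concentrating wall effects toward the latewood:
    w(p) = (0.6 + 0.4 p) / 0.8."""
    return (0.6 + 0.4 * np.asarray(p)) / 0.8


# ---------------------------------------------------------------------------
# outbreak multiplier series
# ---------------------------------------------------------------------------

def outbreak_multipliers(cfg: SimulationConfig) -> pd.DataFrame:
    """Year-by-year effective multipliers from the outbreak schedule.

    Year k of an event (k = 1 at the start year) has multiplier
    m_k = 1 − (1 − m₁)·r^(k−1) with the per-parameter recovery rate r;
    carry-over stops once within 0.5 % of 1. Overlapping events combine
    multiplicatively (does not occur with the default schedule).
    Non-host series receive no outbreak multipliers.
    """
    years = cfg.years
    cols = {
        "cn": np.ones(len(years)),
        "cwt": np.ones(len(years)),
        "cld_early": np.ones(len(years)),
        "cld_late": np.ones(len(years)),
    }
    if cfg.species == "host":
        rates = {"cn": cfg.recovery_cn, "cwt": cfg.recovery_cwt,
                 "cld_early": cfg.recovery_cld, "cld_late": cfg.recovery_cld}
        for ev in cfg.outbreaks:
            m1 = {"cn": ev.cn_mult, "cwt": ev.cwt_mult,
                  "cld_early": ev.cld_early_mult, "cld_late": ev.cld_late_mult}
            for name, m in m1.items():
                r = rates[name]
                k = 1
                while True:
                    mk = 1.0 - (1.0 - m) * r ** (k - 1)
                    if abs(1.0 - mk) < 0.005 or k > 12:
                        break
                    y = ev.start_year + k - 1
                    if cfg.year_start <= y <= cfg.year_end:
                        cols[name][y - cfg.year_start] *= mk
                    k += 1
    out = pd.DataFrame(cols, index=pd.Index(years, name="year"))
    return out


# ---------------------------------------------------------------------------
# climate
# ---------------------------------------------------------------------------

def simulate_climate(
    cfg: SimulationConfig, seed: int | np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the monthly climate table and return (climate, anomalies).

    Temperature is seasonal mean + AR(1) anomaly (month-to-month);
    precipitation is lognormal around its seasonal mean. ``anomalies`` is
    the temperature-anomaly truth, wide (year × month).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cc = cfg.climate
    years = cfg.years
    n = len(years) * 12
    eps = rng.normal(0.0, 1.0, size=n)
    anom = np.empty(n)
    innov_sd = cc.t_anom_sd_C * math.sqrt(max(1.0 - cc.t_anom_ar1**2, 1e-12))
    anom[0] = cc.t_anom_sd_C * eps[0]
    for i in range(1, n):
        anom[i] = cc.t_anom_ar1 * anom[i - 1] + innov_sd * eps[i]
    month = np.tile(np.arange(1, 13), len(years))
    year = np.repeat(years, 12)
    t_mean = np.asarray(cc.t_seasonal_mean_C)[month - 1] + anom
    p_mean = np.asarray(cc.p_seasonal_mean_mm)[month - 1]
    precip = p_mean * np.exp(
        rng.normal(-0.5 * cc.p_log_sd**2, cc.p_log_sd, size=n)
    )
    climate = pd.DataFrame(
        {
            "year": year,
            "month": month,
            "temperature_mean_C": t_mean,
            "precipitation_sum_mm": precip,
        }
    )
    anomalies = pd.DataFrame(
        anom.reshape(len(years), 12),
        index=pd.Index(years, name="year"),
        columns=pd.Index(np.arange(1, 13), name="month"),
    )
    return climate, anomalies


def seasonal_anomaly(anomalies: pd.DataFrame, months: tuple[int, ...]) -> pd.Series:
    """Mean temperature anomaly over the given months, per year."""
    return anomalies[list(months)].mean(axis=1)


# ---------------------------------------------------------------------------
# ring-level drivers shared by both generation paths
# ---------------------------------------------------------------------------

@dataclass
class _Drivers:
    """Deterministic + stochastic ring-level drivers for one simulation."""

    cn_target: np.ndarray  # (n_years, n_trees)
    cld_field: np.ndarray  # (n_years, n_trees, n_grid) lumen diameter before cell noise
    cwt_field: np.ndarray  # (n_years, n_trees, n_grid) radial wall thickness
    grid: np.ndarray


def _build_drivers(
    cfg: SimulationConfig,
    anomalies: pd.DataFrame,
    rng: np.random.Generator,
    n_grid: int = 40,
) -> _Drivers:
    years = cfg.years
    n_y, n_t = len(years), cfg.n_trees
    grid = (np.arange(n_grid) + 0.5) / n_grid

    beta_cn = cfg.beta_cn_host if cfg.species == "host" else cfg.beta_cn_nonhost
    mjja = seasonal_anomaly(anomalies, (5, 6, 7, 8)).reindex(years).to_numpy()
    late = seasonal_anomaly(anomalies, (8, 9)).reindex(years).to_numpy()
    mult = outbreak_multipliers(cfg)

    def logn(sd, size):
        return np.exp(rng.normal(-0.5 * sd**2, sd, size=size))

    tree_cn = logn(cfg.tree_sd_cn, n_t)
    tree_cwt = logn(cfg.tree_sd_cwt, n_t)
    tree_cld = logn(cfg.tree_sd_cld, n_t)
    ring_cn = logn(cfg.ring_sd_cn, (n_y, n_t))
    ring_cwt = logn(cfg.ring_sd_cwt, (n_y, n_t))
    ring_cld = logn(cfg.ring_sd_cld, (n_y, n_t))

    cn_target = (
        cfg.cn_mean
        * np.exp(beta_cn * mjja)[:, None]
        * mult["cn"].to_numpy()[:, None]
        * tree_cn[None, :]
        * ring_cn
    )

    w = latewood_weight(grid)  # mean-one latewood weighting
    base_cld = cld_profile(grid, cfg)
    base_cwt = cwt_profile(grid, cfg)

    cld_mult = (
        mult["cld_early"].to_numpy()[:, None]
        + (mult["cld_late"].to_numpy() - mult["cld_early"].to_numpy())[:, None]
        * grid[None, :]
    )  # (n_y, n_grid)
    cwt_mult = 1.0 - (1.0 - mult["cwt"].to_numpy()[:, None]) * w[None, :]
    # climate forces latewood wall thickening specifically: the coupling
    # weight is the latewood share of the wall-thickness transition, ~1 in
    # latewood and ~0 in earlywood (not mean-one like the outbreak weight)
    lw_share = _logistic((grid - cfg.cwt_onset) / cfg.cwt_width)
    cwt_clim = np.exp(cfg.beta_cwt_latewood * late[:, None] * lw_share[None, :])

    cld_field = (
        base_cld[None, None, :]
        * cld_mult[:, None, :]
        * tree_cld[None, :, None]
        * ring_cld[:, :, None]
    )
    cwt_field = (
        base_cwt[None, None, :]
        * cwt_mult[:, None, :]
        * cwt_clim[:, None, :]
        * tree_cwt[None, :, None]
        * ring_cwt[:, :, None]
    )
    return _Drivers(cn_target, cld_field, cwt_field, grid)


def _cell_geometry(cfg: SimulationConfig, cld: np.ndarray, cwt_rad: np.ndarray):
    """Closed-form cell geometry from lumen diameter and radial wall.

    Lumen: ellipse with tangential diameter = eccentricity × CLD, so
    CLA = π·a·b. Wall area uses the rectangular-perimeter approximation
    CWA = 2·CWT_rad·TLD + 2·CWT_tan·CLD + 4·CWT_rad·CWT_tan, which ties
    wall area to wall thickness so density co-varies realistically.
    """
    cwt_rad = np.maximum(cwt_rad, cfg.cwt_floor_um)
    cwt_tan = cfg.cwt_tan_ratio * cwt_rad
    tld = cfg.lumen_eccentricity * cld
    cla = math.pi * (cld / 2.0) * (tld / 2.0)
    cwa = 2.0 * cwt_rad * tld + 2.0 * cwt_tan * cld + 4.0 * cwt_rad * cwt_tan
    return cwt_rad, cwt_tan, tld, cla, cwa


# ---------------------------------------------------------------------------
# cell-level generation
# ---------------------------------------------------------------------------

def simulate_tracheidogram(
    cfg: SimulationConfig,
    cn_target: float,
    cld_at: callable,
    cwt_at: callable,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Generate the cells of one ring (all radial files).

    ``cld_at``/``cwt_at`` map relative positions in [0, 1] to the ring's
    noise-free lumen diameter / radial wall thickness (baseline profile ×
    outbreak and climate multipliers). Integer cell counts per file are
    drawn around ``cn_target``; per-cell lognormal noise is added; the
    wall-thickness floor is applied last, so it binds whatever drives the
    wall down.
    """
    if cn_target < 3:
        raise ConfigurationError("cn_target must be at least 3")
    frames = []
    for f in range(cfg.n_files):
        n = max(3, int(round(cn_target * np.exp(rng.normal(0.0, cfg.file_count_sd))))) if cfg.file_count_sd > 0 else max(3, int(round(cn_target)))
        p = (np.arange(n) + 0.5) / n
        noise_cld = np.exp(rng.normal(-0.5 * cfg.cell_sd**2, cfg.cell_sd, n))
        noise_cwt = np.exp(rng.normal(-0.5 * cfg.cell_sd**2, cfg.cell_sd, n))
        cld = cld_at(p) * noise_cld
        cwt = cwt_at(p) * noise_cwt
        cwt_rad, cwt_tan, tld, cla, cwa = _cell_geometry(cfg, cld, cwt)
        extent = cld + 2.0 * cwt_rad
        cum = np.cumsum(extent)
        relpos = 100.0 * (cum - extent / 2.0) / cum[-1]
        frames.append(
            pd.DataFrame(
                {
                    "radial_file_id": f + 1,
                    "file_rank": np.arange(1, n + 1),
                    "relative_position_pct": relpos,
                    "lumen_radial_diameter_um": cld,
                    "lumen_area_um2": cla,
                    "wall_thickness_radial_um": cwt_rad,
                    "wall_thickness_tangential_um": cwt_tan,
                    "wall_area_um2": cwa,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    if not np.isfinite(out.select_dtypes(float).to_numpy()).all():
        raise ConfigurationError("simulated ring produced non-finite dimensions")
    out["cell_index"] = np.arange(1, len(out) + 1)
    return out


@dataclass
class SiteData:
    """One simulated site/species dataset with its ground truth."""

    cells: pd.DataFrame
    rw: pd.DataFrame  # year × tree ring widths (mm)
    climate: pd.DataFrame
    truth: dict


def simulate_site(
    cfg: SimulationConfig,
    seed: int | None = None,
    *,
    years: np.ndarray | None = None,
    anomalies: pd.DataFrame | None = None,
) -> SiteData:
    """Simulate a full multi-tree cell-level dataset for one site/species.

    ``years`` optionally restricts cell generation to a subset of
    calendar years (drivers are still built for the full span, so
    outbreak carry-over and climate forcing are consistent); an external
    ``anomalies`` truth lets several species share one climate.
    Fixed seed → identical output.
    """
    ss = np.random.SeedSequence(seed)
    rng_clim, rng_drv, rng_cells = [np.random.default_rng(s) for s in ss.spawn(3)]
    if anomalies is None:
        climate, anomalies = simulate_climate(cfg, rng_clim)
    else:
        climate, _ = simulate_climate(cfg, rng_clim)  # placeholder table, same span
        climate["temperature_mean_C"] = (
            np.asarray(cfg.climate.t_seasonal_mean_C)[climate["month"] - 1]
            + anomalies.stack().reindex(
                pd.MultiIndex.from_frame(climate[["year", "month"]])
            ).to_numpy()
        )
    drv = _build_drivers(cfg, anomalies, rng_drv)
    all_years = cfg.years
    wanted = set(int(y) for y in (years if years is not None else all_years))

    cell_frames = []
    rw_data: dict[str, dict[int, float]] = {}
    for ti in range(cfg.n_trees):
        tree_id = f"{cfg.site_id}{'H' if cfg.species == 'host' else 'N'}{ti + 1:02d}"
        rw_data[tree_id] = {}
        for yi, year in enumerate(all_years):
            if int(year) not in wanted:
                continue
            cld_vals = drv.cld_field[yi, ti]
            cwt_vals = drv.cwt_field[yi, ti]
            grid = drv.grid

            def cld_at(p, v=cld_vals, g=grid):
                return np.interp(p, g, v)

            def cwt_at(p, v=cwt_vals, g=grid):
                return np.interp(p, g, v)

            ring = simulate_tracheidogram(
                cfg, float(drv.cn_target[yi, ti]), cld_at, cwt_at, rng_cells
            )
            ring.insert(0, "year", int(year))
            ring.insert(0, "tree_id", tree_id)
            cn_actual = len(ring) / cfg.n_files
            extent = (
                ring["lumen_radial_diameter_um"]
                + 2.0 * ring["wall_thickness_radial_um"]
            ).mean()
            rw_data[tree_id][int(year)] = cn_actual * float(extent) / 1000.0
            cell_frames.append(ring)
    cells = pd.concat(cell_frames, ignore_index=True)
    rw = pd.DataFrame(rw_data).sort_index()
    rw.index.name = "year"
    truth = {
        "site_id": cfg.site_id,
        "species": cfg.species,
        "seed": seed,
        "events": [asdict(ev) for ev in cfg.outbreaks] if cfg.species == "host" else [],
        "climate_coupling": {
            "beta_cn": cfg.beta_cn_host if cfg.species == "host" else cfg.beta_cn_nonhost,
            "beta_cn_months": [5, 6, 7, 8],
            "beta_cwt_latewood": cfg.beta_cwt_latewood,
            "beta_cwt_months": [8, 9],
        },
        "recovery": {
            "cn": cfg.recovery_cn, "cwt": cfg.recovery_cwt, "cld": cfg.recovery_cld
        },
    }
    return SiteData(cells=cells, rw=rw, climate=climate, truth=truth)


def write_site(data: SiteData, out_dir: str | Path, *, prefix: str = "site") -> dict[str, Path]:
    """Write a simulated dataset (cells, .rwl, climate, truth) to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "cells": out / f"{prefix}_cells.csv",
        "rwl": out / f"{prefix}.rwl",
        "climate": out / f"{prefix}_climate.csv",
        "truth": out / f"{prefix}_truth.json",
    }
    qio.write_cell_table(data.cells, paths["cells"])
    qio.write_rwl(data.rw, paths["rwl"], units="0.001mm")
    qio.write_climate(data.climate, paths["climate"])
    paths["truth"].write_text(json.dumps(data.truth, indent=2), encoding="utf-8")
    return paths


# ---------------------------------------------------------------------------
# fast ring-level generation (no individual cells)
# ---------------------------------------------------------------------------

def simulate_ring_table(
    cfg: SimulationConfig,
    seed: int | None = None,
    *,
    n_grid: int = 40,
    anomalies: pd.DataFrame | None = None,
    return_climate: bool = False,
):
    """Simulate per-tree, per-year ring records directly.

    Ring means are computed by integrating the same intra-ring driver
    fields used by the cell-level path over a relative-position grid
    (cell-level measurement noise, which averages out over ~CN cells per
    file, is omitted; ring- and tree-level noise are identical to the
    cell path). Columns: tree_id, year, RW, CN, mean_CLD, mean_CWT,
    mean_CWA, mean_CLA, mean_CTA, mean_CWD, mean_Khc, RWA, Kh_r, HCUE,
    ew_CWT, lw_CWT.

    ``anomalies`` optionally supplies an existing temperature-anomaly
    truth (year × month), so host and non-host series at one site share
    a single climate realization — the premise of the non-host control.
    """
    from .traits import WATER_VISCOSITY_MPA_S, elliptical_poiseuille_kh

    ss = np.random.SeedSequence(seed)
    rng_clim, rng_drv = [np.random.default_rng(s) for s in ss.spawn(2)]
    if anomalies is None:
        climate, anomalies = simulate_climate(cfg, rng_clim)
    else:
        climate = None
    drv = _build_drivers(cfg, anomalies, rng_drv, n_grid=n_grid)

    cwt_rad, cwt_tan, tld, cla, cwa = _cell_geometry(cfg, drv.cld_field, drv.cwt_field)
    cld = drv.cld_field
    a = cld / 2.0
    b = tld / 2.0
    khc = elliptical_poiseuille_kh(a, b, WATER_VISCOSITY_MPA_S)
    cwt_mean_cell = 0.5 * (cwt_rad + cwt_tan)
    cta = cla + cwa
    cwd = cwa / cta
    extent = cld + 2.0 * cwt_rad
    lw = (4.0 * cwt_rad / cld) >= 1.0

    def ringmean(x):
        return x.mean(axis=2)

    cn = drv.cn_target
    mean_cwa = ringmean(cwa)
    mean_khc = ringmean(khc)
    rec = {
        "CN": cn,
        "RW": cn * ringmean(extent) / 1000.0,
        "mean_CLD": ringmean(cld),
        "mean_CWT": ringmean(cwt_mean_cell),
        "mean_CLA": ringmean(cla),
        "mean_CWA": mean_cwa,
        "mean_CTA": ringmean(cta),
        "mean_CWD": ringmean(cwd),
        "mean_Khc": mean_khc,
        "RWA": cn * mean_cwa,
        "Kh_r": cn * mean_khc,
    }
    rec["HCUE"] = rec["Kh_r"] / rec["RWA"]
    with np.errstate(invalid="ignore"):
        lw_w = lw.astype(float)
        ew_w = 1.0 - lw_w
        rec["lw_CWT"] = (cwt_mean_cell * lw_w).sum(axis=2) / np.maximum(lw_w.sum(axis=2), 1e-12)
        rec["ew_CWT"] = (cwt_mean_cell * ew_w).sum(axis=2) / np.maximum(ew_w.sum(axis=2), 1e-12)

    years = cfg.years
    rows = []
    for ti in range(cfg.n_trees):
        tree_id = f"{cfg.site_id}{'H' if cfg.species == 'host' else 'N'}{ti + 1:02d}"
        df = pd.DataFrame({k: v[:, ti] for k, v in rec.items()})
        df.insert(0, "year", years)
        df.insert(0, "tree_id", tree_id)
        rows.append(df)
    table = pd.concat(rows, ignore_index=True)
    if return_climate:
        return table, climate, anomalies
    return table


def simulate_pair(
    cfg_host: SimulationConfig | None = None,
    cfg_nonhost: SimulationConfig | None = None,
    seed: int | None = None,
    *,
    n_grid: int = 40,
):
    """Simulate host and non-host ring tables sharing one climate.

    Returns ``(host_table, nonhost_table, climate, anomalies)``. Both
    species see the same temperature-anomaly realization (they grow on
    the same slope); only the host receives outbreak multipliers. This is
    the setting in which the non-host veto of
    :func:`qwa.outbreaks.detect_outbreaks` separates climate-driven from
    defoliation-driven wall-thickness declines.
    """
    cfg_host = cfg_host or SimulationConfig()
    cfg_nonhost = cfg_nonhost or dataclasses.replace(
        cfg_host, species="nonhost", outbreaks=list(cfg_host.outbreaks)
    )
    ss = np.random.SeedSequence(seed)
    s_clim, s_h, s_nh = ss.spawn(3)
    climate, anomalies = simulate_climate(cfg_host, np.random.default_rng(s_clim))
    host = simulate_ring_table(
        cfg_host, seed=int(s_h.generate_state(1)[0] % (2**31)),
        n_grid=n_grid, anomalies=anomalies,
    )
    nonhost = simulate_ring_table(
        cfg_nonhost, seed=int(s_nh.generate_state(1)[0] % (2**31)),
        n_grid=n_grid, anomalies=anomalies,
    )
    return host, nonhost, climate, anomalies
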