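import dataclasses

import numpy as np
import pandas as pd
import pytest

import qwa
from qwa import (
    ConfigurationError,
    SimulationConfig,
    simulate_climate,
    simulate_pair,
    simulate_ring_table,
    simulate_site,
    simulate_tracheidogram,
    write_site,
)
from qwa.simulate import cld_profile, cwt_profile, outbreak_multipliers


class TestClimate:
    def test_zero_variance_reproduces_seasonal_means(self):
        cfg = SimulationConfig(year_start=1950, year_end=1960)
        cfg.climate.t_anom_sd_C = 0.0
        cfg.climate.p_log_sd = 0.0
        climate, anoms = simulate_climate(cfg, seed=0)
        for m in range(1, 13):
            t = climate[climate.month == m]["temperature_mean_C"]
            assert np.allclose(t, cfg.climate.t_seasonal_mean_C[m - 1])
            p = climate[climate.month == m]["precipitation_sum_mm"]
            assert np.allclose(p, cfg.climate.p_seasonal_mean_mm[m - 1])
        assert np.allclose(anoms.to_numpy(), 0.0)

    def test_fixed_seed_identical(self):
        cfg = SimulationConfig()
        a, _ = simulate_climate(cfg, seed=5)
        b, _ = simulate_climate(cfg, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_ar_zero_gives_uncorrelated_anomalies(self):
        cfg = SimulationConfig(year_start=1900, year_end=1999)  # 1200 months
        cfg.climate.t_anom_ar1 = 0.0
        _, anoms = simulate_climate(cfg, seed=8)
        x = anoms.to_numpy().ravel()
        lag1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert abs(lag1) < 0.05


class TestOutbreakMultipliers:
    def test_nonhost_receives_none(self):
        cfg = SimulationConfig(species="nonhost")
        mult = outbreak_multipliers(cfg)
        assert np.allclose(mult.to_numpy(), 1.0)

    def test_geometric_recovery_toward_one(self):
        cfg = SimulationConfig()
        mult = outbreak_multipliers(cfg)
        ev = cfg.outbreaks[0]
        y = ev.start_year
        assert mult.loc[y, "cn"] == pytest.approx(ev.cn_mult)
        expected_y2 = 1 - (1 - ev.cn_mult) * cfg.recovery_cn
        assert mult.loc[y + 1, "cn"] == pytest.approx(expected_y2)
        # monotone recovery
        series = mult.loc[y : y + 6, "cn"].to_numpy()
        assert np.all(np.diff(series) > 0)

    def test_invalid_multiplier_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(outbreaks=[qwa.OutbreakPulse(1950, cn_mult=0.0)])


class TestTracheidogram:
    def _noise_free(self):
        cfg = SimulationConfig()
        cfg = dataclasses.replace(cfg, cell_sd=0.0)
        return cfg

    def test_noise_free_cells_on_baseline_curves(self):
        cfg = self._noise_free()
        rng = np.random.default_rng(0)
        ring = simulate_tracheidogram(
            cfg,
            40.0,
            lambda p: cld_profile(p, cfg),
            lambda p: cwt_profile(p, cfg),
            rng,
        )
        n = (ring.radial_file_id == 1).sum()
        p = (np.arange(n) + 0.5) / n
        file1 = ring[ring.radial_file_id == 1]
        assert np.allclose(
            file1["lumen_radial_diameter_um"], cld_profile(p, cfg), rtol=1e-12
        )
        assert np.allclose(
            file1["wall_thickness_radial_um"],
            np.maximum(cwt_profile(p, cfg), cfg.cwt_floor_um),
            rtol=1e-12,
        )

    def test_latewood_weighted_thinning(self):
        cfg = self._noise_free()
        rng = np.random.default_rng(0)
        mult = 0.7
        from qwa.simulate import latewood_weight

        base = simulate_tracheidogram(
            cfg, 40.0,
            lambda p: cld_profile(p, cfg),
            lambda p: cwt_profile(p, cfg),
            np.random.default_rng(0),
        )
        thinned = simulate_tracheidogram(
            cfg, 40.0,
            lambda p: cld_profile(p, cfg),
            lambda p: cwt_profile(p, cfg) * (1 - (1 - mult) * latewood_weight(p)),
            np.random.default_rng(0),
        )
        ratio = (
            thinned["wall_thickness_radial_um"] / base["wall_thickness_radial_um"]
        )
        pos = base["relative_position_pct"]
        assert ratio[pos > 90].mean() < ratio[pos < 10].mean()

    def test_floor_binds_under_extreme_thinning(self):
        cfg = self._noise_free()
        ring = simulate_tracheidogram(
            cfg, 40.0,
            lambda p: cld_profile(p, cfg),
            lambda p: cwt_profile(p, cfg) * 0.1,
            np.random.default_rng(0),
        )
        assert (ring["wall_thickness_radial_um"] >= cfg.cwt_floor_um - 1e-12).all()

    def test_tiny_cn_rejected(self):
        cfg = SimulationConfig()
        with pytest.raises(ConfigurationError):
            simulate_tracheidogram(
                cfg, 2.0, lambda p: p, lambda p: p, np.random.default_rng(0)
            )


class TestSite:
    def test_outputs_pass_io_validation_and_are_deterministic(self, tmp_path):
        cfg = SimulationConfig(year_start=1990, year_end=2010, n_trees=3)
        data = simulate_site(cfg, seed=4)
        p1 = write_site(data, tmp_path / "a")
        data2 = simulate_site(cfg, seed=4)
        p2 = write_site(data2, tmp_path / "b")
        for key in ("cells", "rwl", "climate"):
            assert p1[key].read_bytes() == p2[key].read_bytes()
        cells = qwa.read_cell_table(p1["cells"])
        assert len(cells) == len(data.cells)
        rw = qwa.read_rwl(p1["rwl"])
        assert rw.shape[1] == 3
        qwa.read_climate(p1["climate"])

    def test_cn_rw_strongly_coupled(self):
        table = simulate_ring_table(SimulationConfig(), seed=3)
        one_tree = table[table.tree_id == table.tree_id.iloc[0]]
        r, p = qwa.pearson_r(
            one_tree.set_index("year")["CN"], one_tree.set_index("year")["RW"]
        )
        assert r > 0.9

    def test_truth_record_carries_events_and_couplings(self):
        data = simulate_site(
            SimulationConfig(year_start=1990, year_end=2005, n_trees=2), seed=0
        )
        assert {"events", "climate_coupling", "recovery"} <= set(data.truth)
        assert len(data.truth["events"]) == 8

    def test_ring_and_cell_paths_agree_without_noise(self):
        cfg = SimulationConfig(
            year_start=1995, year_end=2005, n_trees=2,
            tree_sd_cn=0.0, tree_sd_cwt=0.0, tree_sd_cld=0.0,
            ring_sd_cn=0.0, ring_sd_cwt=0.0, ring_sd_cld=0.0, cell_sd=0.0,
            file_count_sd=0.0, outbreaks=[],
        )
        cfg.climate.t_anom_sd_C = 0.0
        ring_fast = simulate_ring_table(cfg, seed=1)
        site = simulate_site(cfg, seed=1)
        cells = qwa.derive_cell_traits(site.cells)
        ring_cell = qwa.build_ring_table(cells, rw=site.rw)
        merged = ring_fast.merge(
            ring_cell, on=["tree_id", "year"], suffixes=("_fast", "_cells")
        )
        for col in ("CN", "RW", "mean_CWT", "mean_CLD", "RWA", "Kh_r"):
            ratio = merged[f"{col}_fast"] / merged[f"{col}_cells"]
            assert np.allclose(ratio, 1.0, atol=0.05), col


def test_yaml_round_trip(tmp_path):
    cfg = SimulationConfig(n_trees=5, cn_mean=40.0)
    path = tmp_path / "cfg.yml"
    cfg.to_yaml(path)
    back = SimulationConfig.from_yaml(path)
    assert back == cfg


def test_null_schedule_pair_has_no_detectable_events():
    cfg = SimulationConfig(outbreaks=[])
    host, nonhost, _, _ = simulate_pair(cfg, seed=12)
    hc = qwa.detrend_and_build(host, "mean_CWT").index
    nc = qwa.detrend_and_build(nonhost, "mean_CWT").index
    assert qwa.detect_outbreaks(hc, nc) == []
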