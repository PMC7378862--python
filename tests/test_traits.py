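import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qwa import (
    WATER_VISCOSITY_MPA_S,
    AnalysisError,
    ConfigurationError,
    aggregate_ring,
    assign_radial_files,
    average_radial_file,
    build_ring_table,
    classify_mork,
    derive_cell_traits,
    elliptical_poiseuille_kh,
    mork_index,
)
from conftest import synthetic_ring

ETA = WATER_VISCOSITY_MPA_S


class TestDeriveCellTraits:
    def test_area_identities_round_numbers(self, toy_cells):
        row = toy_cells.iloc[[1]].copy()
        row["lumen_area_um2"] = 700.0
        row["wall_area_um2"] = 300.0
        out = derive_cell_traits(row)
        assert out["CTA"].iloc[0] == 1000.0
        assert out["CWD"].iloc[0] == pytest.approx(0.30)

    def test_mean_wall_thickness(self, toy_cells_derived):
        expected = 0.5 * (
            toy_cells_derived["CWT_rad"] + toy_cells_derived["CWT_tan"]
        )
        assert np.allclose(toy_cells_derived["CWT"], expected)

    def test_circular_limit_is_hagen_poiseuille(self):
        # a = b = 20 µm: CLD = 40, CLA = 400π
        cells = pd.DataFrame(
            {
                "tree_id": ["t"],
                "year": [2000],
                "cell_index": [1],
                "lumen_radial_diameter_um": [40.0],
                "lumen_area_um2": [400.0 * math.pi],
                "wall_thickness_radial_um": [4.0],
                "wall_thickness_tangential_um": [4.0],
                "wall_area_um2": [500.0],
            }
        )
        out = derive_cell_traits(cells)
        classical = math.pi * 20.0**4 / (8.0 * ETA)
        assert out["Kh_c"].iloc[0] == pytest.approx(classical, rel=1e-12)

    def test_elliptical_formula_against_direct_arithmetic(self):
        # independent re-evaluation of pi a^3 b^3 / (4 eta (a^2+b^2))
        a, b = 20.0, 10.0
        expected = (
            math.pi * a**3 * b**3 / (4.0 * ETA * (a**2 + b**2))
        )
        assert elliptical_poiseuille_kh(a, b, ETA) == pytest.approx(expected, rel=1e-14)

    def test_kh_monotone_in_lumen_area_at_fixed_eccentricity(self):
        a = np.linspace(5, 40, 20)
        kh = elliptical_poiseuille_kh(a, 0.9 * a)
        assert np.all(np.diff(kh) > 0)

    def test_implausible_eccentricity_flagged_not_fatal(self, toy_cells):
        weird = toy_cells.copy()
        weird.loc[0, "lumen_area_um2"] = 1e6  # implies b/a far above band
        out = derive_cell_traits(weird)
        assert bool(out["flagged"].iloc[0])
        assert np.isnan(out["Kh_c"].iloc[0])
        assert not out["flagged"].iloc[1:].any()


class TestMork:
    @pytest.mark.parametrize(
        "cwt_rad, cld, latewood",
        [(3.0, 12.0, True), (3.0, 40.0, False), (6.0, 10.0, True)],
    )
    def test_index_and_boundary(self, cwt_rad, cld, latewood):
        cells = pd.DataFrame({"CWT_rad": [cwt_rad], "CLD": [cld]})
        assert bool(classify_mork(cells).iloc[0]) is latewood
        assert mork_index(cwt_rad, cld) == pytest.approx(4 * cwt_rad / cld)


class TestAssignRadialFiles:
    def test_existing_ids_pass_through(self, toy_cells):
        out = assign_radial_files(toy_cells)
        assert (out["radial_file_id"] == toy_cells["radial_file_id"]).all()

    def test_grid_with_jitter_fully_recovered(self):
        rng = np.random.default_rng(42)
        spacing = 30.0
        rows = []
        for f in range(3):
            for i in range(25):
                rows.append(
                    {
                        "tree_id": "t",
                        "year": 2000,
                        "cell_index": len(rows) + 1,
                        "centroid_x_um": f * spacing
                        + rng.uniform(-spacing / 4, spacing / 4),
                        "centroid_y_um": i * 25.0,
                        "true_file": f,
                    }
                )
        cells = pd.DataFrame(rows)
        out = assign_radial_files(cells)
        # 100% recovery up to label permutation
        table = pd.crosstab(out["true_file"], out["radial_file_id"])
        assert (table.gt(0).sum(axis=1) == 1).all()
        assert out["radial_file_id"].nunique() == 3

    def test_single_column_is_one_file(self):
        cells = pd.DataFrame(
            {
                "tree_id": "t",
                "year": 2000,
                "cell_index": range(1, 11),
                "centroid_x_um": np.random.default_rng(0).normal(0, 1.0, 10),
                "centroid_y_um": np.arange(10) * 25.0,
            }
        )
        out = assign_radial_files(cells)
        assert out["radial_file_id"].nunique() == 1
        assert list(out.sort_values("centroid_y_um")["file_rank"]) == list(range(1, 11))

    def test_no_ids_no_coordinates_is_config_error(self, toy_cells):
        with pytest.raises(ConfigurationError):
            assign_radial_files(toy_cells.drop(columns=["radial_file_id"]))


class TestAverageRadialFile:
    def test_identical_files_average_to_themselves(self, toy_cells_derived):
        two = pd.concat(
            [
                toy_cells_derived,
                toy_cells_derived.assign(
                    radial_file_id=2, cell_index=lambda d: d.cell_index + 3
                ),
            ],
            ignore_index=True,
        )
        avg, cn = average_radial_file(two)
        assert cn == 3.0
        assert np.allclose(avg["CLA"], toy_cells_derived["CLA"])

    def test_unequal_constant_files(self):
        ring = synthetic_ring(n_files=1, n_cells=4, jitter_counts=False)
        ring2 = synthetic_ring(n_files=1, n_cells=6, jitter_counts=False)
        ring2["radial_file_id"] = 2
        for df in (ring, ring2):
            df["lumen_area_um2"] = 500.0
        cells = derive_cell_traits(pd.concat([ring, ring2], ignore_index=True))
        cells["file_rank"] = cells.groupby("radial_file_id").cumcount() + 1
        avg, cn = average_radial_file(cells, traits=("CLA",))
        assert cn == pytest.approx(0.5 * (len(ring) + len(ring2)))
        assert np.allclose(avg["CLA"], 500.0)

    def test_scaled_sum_matches_per_file_total_oracle(self):
        rng = np.random.default_rng(7)
        rings = []
        for f in range(1, 25):
            n = int(rng.integers(15, 30))
            part = synthetic_ring(n_files=1, n_cells=n, rng=rng)
            part["radial_file_id"] = f
            rings.append(part)
        cells = derive_cell_traits(pd.concat(rings, ignore_index=True))
        cells["file_rank"] = cells.groupby("radial_file_id").cumcount() + 1
        avg, cn = average_radial_file(cells)
        scaled_sum = float(avg["CWA"].sum()) * cn / len(avg)
        oracle = cells["CWA"].sum() / cells["radial_file_id"].nunique()
        assert scaled_sum == pytest.approx(oracle, rel=0.01)

    def test_empty_ring_raises(self):
        with pytest.raises(AnalysisError):
            average_radial_file(pd.DataFrame(columns=["radial_file_id", "CLA"]))


class TestAggregateRing:
    def test_rwa_is_direct_sum(self):
        ring = synthetic_ring(n_files=1, n_cells=3, jitter_counts=False)
        ring["wall_area_um2"] = [500.0, 400.0, 300.0]
        rec = aggregate_ring(derive_cell_traits(ring))
        assert rec["CN"] == 3
        assert rec["RWA"] == pytest.approx(1200.0)

    def test_hcue_is_ratio(self, toy_cells_derived):
        rec = aggregate_ring(toy_cells_derived)
        assert rec["HCUE"] * rec["RWA"] == pytest.approx(rec["Kh_r"], rel=1e-12)
        assert rec["carbon_proxy"] / rec["RWA"] == pytest.approx(0.508)

    def test_doubling_wall_area_linearity(self):
        ring = synthetic_ring()
        rec1 = aggregate_ring(derive_cell_traits(ring))
        ring2 = ring.assign(wall_area_um2=ring["wall_area_um2"] * 2)
        rec2 = aggregate_ring(derive_cell_traits(ring2))
        assert rec2["RWA"] == pytest.approx(2 * rec1["RWA"], rel=1e-12)
        assert rec2["Kh_r"] == pytest.approx(rec1["Kh_r"], rel=1e-12)
        assert rec2["HCUE"] == pytest.approx(0.5 * rec1["HCUE"], rel=1e-12)

    def test_file_permutation_invariance(self):
        ring = synthetic_ring(n_files=4)
        rec1 = aggregate_ring(derive_cell_traits(ring))
        permuted = ring.copy()
        permuted["radial_file_id"] = permuted["radial_file_id"].map(
            {1: 3, 2: 1, 3: 4, 4: 2}
        )
        rec2 = aggregate_ring(derive_cell_traits(permuted))
        for key in ("CN", "RWA", "Kh_r", "HCUE", "mean_CWA"):
            assert rec2[key] == pytest.approx(rec1[key], rel=1e-12)

    def test_conservation_of_areas(self):
        cells = derive_cell_traits(synthetic_ring())
        assert (cells["CLA"] + cells["CWA"]).sum() == pytest.approx(
            cells["CTA"].sum(), rel=1e-14
        )


@settings(deadline=None, max_examples=25, derandomize=True)
@given(s=st.floats(min_value=0.2, max_value=5.0))
def test_scale_equivariance(s):
    """Scaling all linear dimensions by s scales areas by s², conductivities
    by s⁴, RWA by s², Kh_r by s⁴ and HCUE by s²."""
    ring = synthetic_ring(n_files=2, n_cells=8)
    scaled = ring.copy()
    for col in ("lumen_radial_diameter_um", "wall_thickness_radial_um",
                "wall_thickness_tangential_um"):
        scaled[col] = scaled[col] * s
    for col in ("lumen_area_um2", "wall_area_um2"):
        scaled[col] = scaled[col] * s**2
    r1 = aggregate_ring(derive_cell_traits(ring))
    r2 = aggregate_ring(derive_cell_traits(scaled))
    assert r2["RWA"] == pytest.approx(s**2 * r1["RWA"], rel=1e-9)
    assert r2["Kh_r"] == pytest.approx(s**4 * r1["Kh_r"], rel=1e-9)
    assert r2["HCUE"] == pytest.approx(s**2 * r1["HCUE"], rel=1e-9)
    assert r2["mean_CTA"] == pytest.approx(s**2 * r1["mean_CTA"], rel=1e-9)


def test_build_ring_table_one_row_per_tree_year(toy_cells):
    cells = pd.concat(
        [toy_cells, toy_cells.assign(year=2001)], ignore_index=True
    )
    table = build_ring_table(cells)
    assert len(table) == 2
    assert set(table["year"]) == {2000, 2001}
    assert (table["RW"] > 0).all()
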