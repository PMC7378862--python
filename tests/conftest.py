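import numpy as np
import pandas as pd
import pytest

from qwa import SimulationConfig, derive_cell_traits


@pytest.fixture
def toy_cells() -> pd.DataFrame:
    """Three hand-written tracheids of one ring (one radial file)."""
    return pd.DataFrame(
        {
            "tree_id": ["t1"] * 3,
            "year": [2000] * 3,
            "cell_index": [1, 2, 3],
            "radial_file_id": [1, 1, 1],
            "lumen_radial_diameter_um": [40.0, 30.0, 10.0],
            "lumen_area_um2": [1200.0, 700.0, 80.0],
            "wall_thickness_radial_um": [3.0, 4.0, 7.0],
            "wall_thickness_tangential_um": [3.0, 4.0, 7.0],
            "wall_area_um2": [300.0, 300.0, 300.0],
        }
    )


@pytest.fixture
def toy_cells_derived(toy_cells) -> pd.DataFrame:
    return derive_cell_traits(toy_cells)


@pytest.fixture
def toy_cell_file(tmp_path, toy_cells):
    path = tmp_path / "cells.csv"
    toy_cells.to_csv(path, index=False)
    return path


def synthetic_ring(
    n_files: int = 3,
    n_cells: int = 20,
    rng: np.random.Generator | None = None,
    tree: str = "t1",
    year: int = 2000,
    jitter_counts: bool = True,
) -> pd.DataFrame:
    """Random but valid multi-file ring for aggregation tests."""
    rng = rng or np.random.default_rng(0)
    rows = []
    idx = 1
    for f in range(1, n_files + 1):
        n = n_cells + (int(rng.integers(-2, 3)) if jitter_counts else 0)
        cld = rng.uniform(8, 42, n)
        cla = np.pi * (cld / 2) * (0.9 * cld / 2)
        cwt = rng.uniform(3, 8, n)
        cwa = 2 * cwt * 0.9 * cld + 2 * cwt * cld + 4 * cwt * cwt
        for i in range(n):
            rows.append(
                dict(
                    tree_id=tree,
                    year=year,
                    cell_index=idx,
                    radial_file_id=f,
                    file_rank=i + 1,
                    lumen_radial_diameter_um=cld[i],
                    lumen_area_um2=cla[i],
                    wall_thickness_radial_um=cwt[i],
                    wall_thickness_tangential_um=cwt[i],
                    wall_area_um2=cwa[i],
                )
            )
            idx += 1
    return pd.DataFrame(rows)


@pytest.fixture
def fast_config() -> SimulationConfig:
    """Full-default simulation configuration (the study conditions)."""
    return SimulationConfig()
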