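"""Derive functional traits for a handful of measured tracheids.

Builds a three-cell ring (wide thin-walled earlywood to narrow
thick-walled latewood), derives the per-cell traits and aggregates the
ring. Kh_c falls steeply toward the latewood (fourth-power dependence on
lumen size); CWD (relative density) rises; RWA sums the wall material of
the average radial file.
"""

import pandas as pd

import qwa

cells = pd.DataFrame(
    {
        "tree_id": ["t1"] * 3,
        "year": [2000] * 3,
        "cell_index": [1, 2, 3],
        "radial_file_id": [1, 1, 1],
        "lumen_radial_diameter_um": [40.0, 30.0, 10.0],
        "lumen_area_um2": [1200.0, 700.0, 80.0],
        "wall_thickness_radial_um": [3.0, 4.0, 7.0],
        "wall_thickness_tangential_um": [3.0, 4.0, 7.0],
        "wall_area_um2": [300.0, 350.0, 400.0],
    }
)

derived = qwa.derive_cell_traits(cells)
derived["is_latewood"] = qwa.classify_mork(derived)
print(derived[["CLD", "CWT", "CLA", "CWA", "CTA", "CWD", "Kh_c", "is_latewood"]]
      .to_string(index=False))

ring = qwa.aggregate_ring(derived)
print(f"\nCN = {ring['CN']:.0f} cells per file")
print(f"RWA = {ring['RWA']:.0f} um^2   (wall material of the average file; biomass proxy)")
print(f"Kh_r = {ring['Kh_r']:.3e} um^4 MPa^-1 s^-1")
print(f"HCUE = {ring['HCUE']:.3e}   (conductivity per unit wall area)")
print(f"carbon proxy = {ring['carbon_proxy']:.0f} um^2 (0.508 x RWA)")
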