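"""Bundled measurements from the aquifer field/laboratory study.

These are the scalar inputs and the measured swimming-speed replicates that
drive the transport and attachment-capacity calculations: eleven amphipods
filmed in a 16.34 cm petri dish at 30 frames per second, five speed
replicates each, reported on the 10^4 m yr^-1 scale; plus the morphometric
and microbiological scalars (body dimensions, imaged surface area, mean
prokaryote cell dimensions, groundwater cell concentration) and the physical
bounds used for the advection comparison (tortuosity 2-4, groundwater
advection 1-1000 m yr^-1).
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "load_swimming_speeds",
    "STUDY_PARAMETERS",
]

# Measured amphipod swimming-speed replicates, units of 1e4 m yr^-1.
# One row per individual: body length (mm) then five replicate speeds.
_SPEED_ROWS = [
    ("Amphipoda 1", 2.5, [12.68, 11.75, 7.77, 10.91, 4.30]),
    ("Amphipoda 2", 2.5, [11.68, 11.40, 11.51, 8.28, 3.92]),
    ("Amphipoda 3", 2.5, [5.25, 3.91, 4.19, 4.37, 4.10]),
    ("Amphipoda 4", 2.5, [2.34, 2.06, 1.94, 1.84, 1.80]),
    ("Amphipoda 5", 2.5, [10.32, 11.51, 8.74, 14.84, 13.03]),
    ("Amphipoda 6", 2.5, [2.28, 1.70, 2.38, 2.23, 2.34]),
    ("Amphipoda 7", 2.5, [11.64, 21.89, 13.36, 14.27, 12.08]),
    ("Amphipoda 8", 3.0, [10.32, 11.51, 8.74, 14.84, 13.03]),
    ("Amphipoda 9", 3.0, [2.70, 6.89, 1.99, 2.47, 2.45]),
    ("Amphipoda 10", 2.5, [3.64, 2.53, 3.38, 2.26, 2.37]),
    ("Amphipoda 11", 3.5, [6.18, 1.95, 5.35, 2.72, 3.42]),
]


def load_swimming_speeds() -> pd.DataFrame:
    """Measured per-replicate swimming speeds of the eleven amphipods.

    Returns
    -------
    pandas.DataFrame
        Indexed by individual label, columns ``length_mm`` and
        ``replicate_1`` .. ``replicate_5``; speeds in 1e4 m yr^-1.
    """
    records = {}
    for label, length, speeds in _SPEED_ROWS:
        rec = {"length_mm": length}
        rec.update({f"replicate_{i + 1}": s for i, s in enumerate(speeds)})
        records[label] = rec
    return pd.DataFrame.from_dict(records, orient="index")


#: Scalar study parameters with units in the key names.
STUDY_PARAMETERS: dict[str, float] = {
    # amphipod morphometrics (means)
    "body_length_mm": 2.7,
    "body_width_mm": 0.5,
    "body_height_mm": 0.5,
    "surface_area_mm2": 20.0,  # imaged, leg-width corrected
    # mixed-community prokaryote cell geometry
    "cell_length_um": 1.25,
    "cell_width_um": 0.36,
    "ultrasmall_volume_factor": 56.0,
    # groundwater microbiology (flow cytometry)
    "groundwater_cells_per_l": 2.4e8,
    # porous-medium / flow bounds
    "tortuosity_min": 2.0,
    "tortuosity_max": 4.0,
    "advection_min_m_yr": 1.0,
    "advection_max_m_yr": 1000.0,
    # video setup
    "arena_diameter_cm": 16.34,
    "fps": 30.0,
}
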