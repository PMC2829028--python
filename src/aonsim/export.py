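"""CSV export of censuses, grid results and signal time series.

Column orders and headers are frozen; numeric columns carry their units in
the header (mm, days, percent, units).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .architecture import PlantTopology, nodule_depth

CENSUS_COLUMNS = ["day", "genotype", "organ_id", "kind", "depth_mm", "status"]


def census_frame(plant: PlantTopology) -> pd.DataFrame:
    """Per-nodule/primordium rows of the current plant state."""
    rows = []
    for o in plant.iter_kind("nodule", "nodule_primordium"):
        rows.append(
            {
                "day": plant.day,
                "genotype": o.genotype or plant.genotype_name,
                "organ_id": o.id,
                "kind": o.kind,
                "depth_mm": nodule_depth(plant, o.id),
                "status": o.status,
            }
        )
    return pd.DataFrame(rows, columns=CENSUS_COLUMNS)


def write_census_csv(plant: PlantTopology, path: str | Path) -> Path:
    path = Path(path)
    census_frame(plant).to_csv(path, index=False)
    return path


def write_signal_series_csv(series: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    cols = [
        "day",
        "organ_id",
        "kind",
        "q_amount_units",
        "sdi_amount_units",
        "sdi_concentration_units_per_mm",
    ]
    frame = series if not series.empty else pd.DataFrame(columns=cols)
    frame.to_csv(path, index=False, columns=cols)
    return path
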