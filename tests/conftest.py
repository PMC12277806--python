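from __future__ import annotations

import pandas as pd
import pytest

from mtscreen.screen_data import ScreenDataset, Well


def make_well(
    role: str,
    platform: str = "spinal_microtissue",
    compound_id: str = "",
    position: str = "A01",
    plate_id: str = "plate1",
    analytes: dict | None = None,
    diameter: float | None = 100.0,
    dose: float | None = 5.0,
) -> Well:
    return Well(
        plate_id=plate_id,
        position=position,
        role=role,
        platform=platform,
        compound_id=compound_id,
        dose_um=dose,
        analyte_values=analytes or {},
        diameter_um=diameter,
    )


def toy_dataset(
    compound_values: dict[str, float],
    vehicle_values: tuple[float, ...] = (100.0, 100.0, 100.0),
    negative_values: tuple[float, ...] = (80.0, 80.0, 80.0),
    positive_values: tuple[float, ...] = (800.0, 800.0, 800.0),
    analyte: str = "IL-6",
    platform: str = "spinal_microtissue",
    diameters: dict[str, float | None] | None = None,
) -> ScreenDataset:
    """Single-analyte, single-platform dataset for hand-checkable examples."""
    diameters = diameters or {}
    wells = []
    pos = iter(f"{r}{c:02d}" for r in "ABCDEFGH" for c in range(1, 13))
    for v in vehicle_values:
        wells.append(
            make_well("vehicle", platform, position=next(pos), analytes={analyte: v})
        )
    for v in negative_values:
        wells.append(
            make_well("negative", platform, position=next(pos), analytes={analyte: v})
        )
    for v in positive_values:
        wells.append(
            make_well("positive", platform, position=next(pos), analytes={analyte: v})
        )
    for cid, v in compound_values.items():
        wells.append(
            make_well(
                "compound",
                platform,
                compound_id=cid,
                position=next(pos),
                analytes={analyte: v},
                diameter=diameters.get(cid, 100.0),
            )
        )
    return ScreenDataset(wells=wells, analyte_panel=(analyte,))


@pytest.fixture
def toy_csv(tmp_path):
    """6-row toy table: 3 DMSO vehicle + 3 LPS positive wells."""
    df = pd.DataFrame(
        {
            "plate_id": ["p1"] * 6,
            "position": ["A01", "A02", "A03", "B01", "B02", "B03"],
            "role": ["vehicle"] * 3 + ["positive"] * 3,
            "compound_id": [""] * 6,
            "dose_um": [0.01] * 3 + [1.0] * 3,
            "platform": ["spinal_microtissue"] * 6,
            "diameter_um": [100.0, 101.0, 99.0, 98.0, 100.0, 102.0],
            "IL-6": [90.0, 100.0, 110.0, 800.0, 820.0, 780.0],
            "IL-8": [200.0, 210.0, 190.0, 1500.0, 1600.0, 1400.0],
        }
    )
    path = tmp_path / "toy.csv"
    df.to_csv(path, index=False)
    return path
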