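"""Per-tile cell tables: the substrate of all spatial computation.

A :class:`CellMap` wraps a :class:`pandas.DataFrame` with one row per
segmented nucleus.  Required columns are the centroid, the TIL/non-TIL
class and the basic morphology descriptors; color and texture descriptor
columns are optional and are attached either by the synthetic generator
or by :func:`phenotil.segmentation.extract_descriptors`.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

TIL = "TIL"
NONTIL = "nonTIL"
UNASSIGNED = "unassigned"
CLASSES = (TIL, NONTIL, UNASSIGNED)

#: shape descriptors computed per nucleus
MORPH_COLS = ["area", "perimeter", "eccentricity", "equiv_diameter", "solidity"]
#: per-nucleus mean intensity per RGB channel
COLOR_COLS = ["mean_R", "mean_G", "mean_B"]
#: the 12 gray-level co-occurrence statistics (see phenotil._haralick)
HARALICK_STATS = [
    "asm",
    "contrast",
    "correlation",
    "variance",
    "idm",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",
]
HARALICK_COLS = [f"har_{s}" for s in HARALICK_STATS]

REQUIRED_COLS = ["cell_id", "x", "y", "class"] + MORPH_COLS
#: columns written to / read from the canonical cell-table CSV
CSV_COLS = REQUIRED_COLS + COLOR_COLS

DESCRIPTOR_COLS = MORPH_COLS + COLOR_COLS + HARALICK_COLS


@dataclasses.dataclass
class CellMap:
    """Table of segmented nuclei for one tile.

    Parameters
    ----------
    cells
        One row per nucleus.  Must contain :data:`REQUIRED_COLS`;
        ``class`` values are ``"TIL"``, ``"nonTIL"`` or ``"unassigned"``.
    tile_id
        Identifier of the source tile.
    microns_per_pixel
        Physical resolution; 0.5 corresponds to 20x magnification.
    shape
        Tile dimensions ``(height, width)`` in pixels.
    """

    cells: pd.DataFrame
    tile_id: str = "tile"
    microns_per_pixel: float = 0.5
    shape: tuple[int, int] = (2048, 2048)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLS if c not in self.cells.columns]
        if missing:
            raise ValueError(f"cell table missing columns: {missing}")
        if self.cells["cell_id"].duplicated().any():
            raise ValueError("cell_ids must be unique")
        bad = ~self.cells["class"].isin(CLASSES)
        if bad.any():
            raise ValueError(f"unknown classes: {self.cells.loc[bad, 'class'].unique()}")
        self.cells = self.cells.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def n_til(self) -> int:
        return int((self.cells["class"] == TIL).sum())

    @property
    def n_nontil(self) -> int:
        return int((self.cells["class"] == NONTIL).sum())

    @property
    def tissue_area_mm2(self) -> float:
        """Tile area in mm^2 (the tile is treated as fully tissue)."""
        h, w = self.shape
        return h * w * (self.microns_per_pixel / 1000.0) ** 2

    def coords(self, cls: str | None = None) -> np.ndarray:
        df = self.cells if cls is None else self.cells[self.cells["class"] == cls]
        return df[["x", "y"]].to_numpy(float)

    def til_ids(self) -> np.ndarray:
        return self.cells.loc[self.cells["class"] == TIL, "cell_id"].to_numpy()

    def has_descriptors(self) -> bool:
        return all(c in self.cells.columns for c in DESCRIPTOR_COLS)

    def to_csv(self, path: str | Path) -> None:
        cols = [c for c in self.cells.columns if c in set(CSV_COLS + HARALICK_COLS)]
        self.cells[cols].to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        tile_id: str | None = None,
        microns_per_pixel: float = 0.5,
        shape: tuple[int, int] = (2048, 2048),
    ) -> "CellMap":
        df = pd.read_csv(path)
        return cls(
            cells=df,
            tile_id=tile_id or Path(path).stem,
            microns_per_pixel=microns_per_pixel,
            shape=shape,
        )


def empty_cell_table(with_descriptors: bool = True) -> pd.DataFrame:
    """Zero-row table with the canonical columns."""
    cols = REQUIRED_COLS + (COLOR_COLS + HARALICK_COLS if with_descriptors else [])
    df = pd.DataFrame({c: pd.Series(dtype=float) for c in cols})
    df["cell_id"] = df["cell_id"].astype(int)
    df["class"] = df["class"].astype(str)
    return df
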