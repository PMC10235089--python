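"""Contextual TIL features: 96 neighborhood descriptors at three radii.

Each tumor-infiltrating lymphocyte is characterized by the cells
surrounding it.  Three nested closed discs of radius dL*10, dL*20 and
dL*30 pixels (dL = 20 px, the average lymphocyte diameter at 20x) are
centered on the TIL's centroid; within each disc, with the index cell
excluded, five descriptor families are computed over the TIL and
non-TIL neighbor groups:

A. density (6): neighbor counts, TIL fraction, counts per mm^2;
B. graph distance (8): centroid-distance statistics to each class;
C. neighbor morphology (40): area, perimeter, eccentricity,
   equivalent diameter, solidity x {mean, std, min, max} x class;
D. neighbor color (18): per-nucleus mean R/G/B x {mean, std, max} x class;
E. neighbor texture (24): 12 co-occurrence statistics of each
   neighbor's nucleus patch, averaged per class.

6 + 8 + 40 + 18 + 24 = 96 per radius; 3 radii give the 288-feature
contextual vector.  Empty neighbor groups contribute zeros (the fill
convention, applied before any standardization downstream).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage.color import rgb2gray

from ._haralick import haralick_features
from .cellmap import (
    COLOR_COLS,
    HARALICK_COLS,
    HARALICK_STATS,
    MORPH_COLS,
    NONTIL,
    TIL,
    CellMap,
)

LYMPHOCYTE_DIAMETER_PX = 20  # dL: average lymphocyte diameter at 20x


@dataclasses.dataclass(frozen=True)
class NeighborhoodSpec:
    """Nested-disc neighborhood geometry around each index TIL."""

    dL: int = LYMPHOCYTE_DIAMETER_PX
    multipliers: tuple[int, ...] = (10, 20, 30)

    def __post_init__(self) -> None:
        if self.dL <= 0:
            raise ValueError("dL must be positive")
        if any(b <= a for a, b in zip(self.multipliers, self.multipliers[1:])):
            raise ValueError("radii must be strictly increasing")

    @property
    def radii(self) -> tuple[int, ...]:
        return tuple(self.dL * m for m in self.multipliers)


DEFAULT_SPEC = NeighborhoodSpec()

_CLS = ("til", "nontil")
_FULL_STATS = ("mean", "std", "min", "max")


def _per_radius_names() -> list[str]:
    names = ["n_til", "n_nontil", "n_total", "frac_til", "til_per_mm2", "nontil_per_mm2"]
    for c in _CLS:
        names += [f"dist_{c}_{s}" for s in _FULL_STATS]
    for m in MORPH_COLS:
        for c in _CLS:
            names += [f"{m}_{c}_{s}" for s in _FULL_STATS]
    for col in COLOR_COLS:
        for c in _CLS:
            names += [f"{col}_{c}_{s}" for s in ("mean", "std", "max")]
    for stat in HARALICK_STATS:
        for c in _CLS:
            names.append(f"har_{stat}_{c}_mean")
    return names


def feature_catalog(spec: NeighborhoodSpec = DEFAULT_SPEC) -> list[str]:
    """The ordered 288 contextual feature names.

    Names encode family, statistic, neighbor class and radius, e.g.
    ``area_til_mean_r200``.  96 names per radius, radii ordered
    innermost first.
    """
    return [f"{base}_r{r}" for r in spec.radii for base in _per_radius_names()]


def attach_image_descriptors(cell_map: CellMap, image: np.ndarray) -> CellMap:
    """Fill missing color / texture descriptor columns from an image.

    Per-nucleus color means are sampled over a square patch of side
    ``equiv_diameter`` centered at the centroid, and texture over the
    grayscale patch.  When a label mask is available, prefer
    :func:`phenotil.segmentation.extract_descriptors`, which uses exact
    regions.
    """
    cells = cell_map.cells.copy()
    gray = (rgb2gray(image) * 255).astype(np.uint8)
    h, w = gray.shape
    need_color = any(c not in cells.columns for c in COLOR_COLS)
    need_har = any(c not in cells.columns for c in HARALICK_COLS)
    if not (need_color or need_har):
        return cell_map
    color = np.zeros((len(cells), 3))
    har = np.zeros((len(cells), len(HARALICK_COLS)))
    for i, row in enumerate(cells.itertuples(index=False)):
        half = max(int(round(row.equiv_diameter / 2)), 1)
        y0, y1 = max(int(row.y) - half, 0), min(int(row.y) + half + 1, h)
        x0, x1 = max(int(row.x) - half, 0), min(int(row.x) + half + 1, w)
        patch = image[y0:y1, x0:x1]
        color[i] = patch.reshape(-1, 3).mean(axis=0)
        har[i] = haralick_features(gray[y0:y1, x0:x1])
    if need_color:
        cells[COLOR_COLS] = color
    if need_har:
        cells[HARALICK_COLS] = har
    return CellMap(cells, tile_id=cell_map.tile_id,
                   microns_per_pixel=cell_map.microns_per_pixel, shape=cell_map.shape)


def _group_block(vals: np.ndarray, stats: tuple[str, ...]) -> list[float]:
    """Statistics of one descriptor over one neighbor group (0-fill when empty)."""
    out = []
    for s in stats:
        if len(vals) == 0:
            out.append(0.0)
        elif s == "mean":
            out.append(float(vals.mean()))
        elif s == "std":
            out.append(float(vals.std()))  # population (ddof=0)
        elif s == "min":
            out.append(float(vals.min()))
        else:
            out.append(float(vals.max()))
    return out


def _radius_features(
    dist: np.ndarray,
    is_til: np.ndarray,
    desc: np.ndarray,
    radius: float,
    microns_per_pixel: float,
) -> list[float]:
    """The 96 values for one disc; ``desc`` columns follow MORPH+COLOR+HARALICK."""
    til_m = is_til
    non_m = ~is_til
    n_til, n_non = int(til_m.sum()), int(non_m.sum())
    n_tot = n_til + n_non
    disc_mm2 = np.pi * radius**2 * (microns_per_pixel / 1000.0) ** 2
    vals = [
        float(n_til),
        float(n_non),
        float(n_tot),
        n_til / n_tot if n_tot else 0.0,
        n_til / disc_mm2,
        n_non / disc_mm2,
    ]
    for m in (til_m, non_m):
        vals += _group_block(dist[m], _FULL_STATS)
    n_morph = len(MORPH_COLS)
    for j in range(n_morph):
        for m in (til_m, non_m):
            vals += _group_block(desc[m, j], _FULL_STATS)
    for j in range(n_morph, n_morph + 3):
        for m in (til_m, non_m):
            vals += _group_block(desc[m, j], ("mean", "std", "max"))
    off = n_morph + 3
    for j in range(off, off + len(HARALICK_STATS)):
        for m in (til_m, non_m):
            vals += _group_block(desc[m, j], ("mean",))
    return vals


_DESC_ORDER = MORPH_COLS + COLOR_COLS + HARALICK_COLS


class _Extractor:
    def __init__(self, cell_map: CellMap, image: np.ndarray | None,
                 spec: NeighborhoodSpec):
        if image is not None and not cell_map.has_descriptors():
            cell_map = attach_image_descriptors(cell_map, image)
        if not cell_map.has_descriptors():
            missing = [c for c in _DESC_ORDER if c not in cell_map.cells.columns]
            raise ValueError(
                f"cell map lacks descriptor columns {missing}; pass the tile image "
                "or attach descriptors first"
            )
        self.cm = cell_map
        self.spec = spec
        cells = cell_map.cells
        self.coords = cells[["x", "y"]].to_numpy(float)
        self.is_til = (cells["class"] == TIL).to_numpy()
        self.desc = cells[_DESC_ORDER].to_numpy(float)
        self.cell_ids = cells["cell_id"].to_numpy()
        self.tree = cKDTree(self.coords) if len(cells) else None

    def features_for(self, idx: int) -> np.ndarray:
        center = self.coords[idx]
        out: list[float] = []
        r_max = self.spec.radii[-1]
        cand = np.array(self.tree.query_ball_point(center, r_max), int)
        cand = cand[cand != idx]
        d = np.linalg.norm(self.coords[cand] - center, axis=1)
        for r in self.spec.radii:
            sel = d <= r  # closed disc
            out += _radius_features(
                d[sel], self.is_til[cand[sel]], self.desc[cand[sel]],
                r, self.cm.microns_per_pixel,
            )
        return np.asarray(out)


def compute_til_features(
    cell_map: CellMap,
    image: np.ndarray | None = None,
    til_id: int | None = None,
    spec: NeighborhoodSpec = DEFAULT_SPEC,
) -> pd.Series:
    """Contextual feature vector of one TIL.

    Raises
    ------
    ValueError
        If ``til_id`` does not refer to a TIL-class cell.
    """
    ex = _Extractor(cell_map, image, spec)
    pos = np.nonzero(ex.cell_ids == til_id)[0]
    if len(pos) == 0:
        raise ValueError(f"cell {til_id} not found")
    idx = int(pos[0])
    if not ex.is_til[idx]:
        raise ValueError(f"cell {til_id} is not TIL-class")
    return pd.Series(ex.features_for(idx), index=feature_catalog(spec), name=til_id)


def extract_all(
    cell_map: CellMap,
    image: np.ndarray | None = None,
    spec: NeighborhoodSpec = DEFAULT_SPEC,
) -> pd.DataFrame:
    """Contextual feature table for every TIL in a cell map.

    Rows follow the cell map's TIL order (index = til_id); columns are
    :func:`feature_catalog`.  Identical to per-cell calls of
    :func:`compute_til_features`.
    """
    catalog = feature_catalog(spec)
    if len(cell_map) == 0 or cell_map.n_til == 0:
        return pd.DataFrame(columns=catalog, dtype=float)
    ex = _Extractor(cell_map, image, spec)
    til_idx = np.nonzero(ex.is_til)[0]
    rows = np.vstack([ex.features_for(int(i)) for i in til_idx])
    return pd.DataFrame(rows, index=pd.Index(ex.cell_ids[til_idx], name="til_id"),
                        columns=catalog)


def write_feature_table(table: pd.DataFrame, path, tile_id: str = "tile") -> None:
    """Persist a feature table (CSV or Parquet by extension) with provenance."""
    out = table.reset_index()
    out.insert(0, "tile_id", tile_id)
    if str(path).endswith(".parquet"):
        out.to_parquet(path, index=False)
    else:
        out.to_csv(path, index=False)
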