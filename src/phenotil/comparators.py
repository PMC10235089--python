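"""Comparator feature families: denTIL density and spaTIL spatial features.

denTIL summarizes a tile by 19 density descriptors (TIL counts, areas
and their ratios against nuclei and tissue area); spaTIL summarizes
spatial architecture through connected-component cluster statistics of
the within-class centroid graph (a reduced family of counts, hull
areas and intermixing).  Patient-level vectors aggregate each
tile-level feature by mean, median, skewness and kurtosis across the
patient's tiles.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import ConvexHull, QhullError, cKDTree
from shapely.geometry import MultiPoint

from .cellmap import NONTIL, TIL, CellMap

DENTIL_NAMES = [
    "til_per_mm2",            # n_TIL / tissue area
    "til_frac_nuclei",        # n_TIL / n_nuclei
    "til_area_frac_tissue",   # TIL area / tissue area
    "n_til",
    "n_nontil",
    "n_nuclei",
    "tissue_area_mm2",
    "til_area_mm2",
    "nontil_area_mm2",
    "nuclear_area_frac_tissue",
    "nontil_per_mm2",
    "nontil_frac_nuclei",
    "nontil_area_frac_tissue",
    "til_area_frac_nuclear",
    "til_nontil_count_ratio",
    "til_nontil_area_ratio",
    "mean_til_area_mm2",
    "mean_nontil_area_mm2",
    "til_per_1000_nuclei",
]


def _guard(num: float, den: float, flags: list[str], name: str) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def dentil_features(cell_map: CellMap,
                    tissue_mask: np.ndarray | None = None
                    ) -> tuple[pd.Series, list[str]]:
    """The 19 tile-level TIL density features.

    Areas are in mm^2 via the cell map's resolution; the tissue area is
    the tile area unless a boolean ``tissue_mask`` restricts it.
    Ratios with zero denominators return 0 and the feature name is
    flagged.

    Returns the named length-19 vector and the list of flagged names.
    """
    cells = cell_map.cells
    mpp = cell_map.microns_per_pixel
    px2mm2 = (mpp / 1000.0) ** 2
    if tissue_mask is not None:
        tissue_mm2 = float(tissue_mask.sum()) * px2mm2
    else:
        tissue_mm2 = cell_map.tissue_area_mm2
    til = cells[cells["class"] == TIL]
    non = cells[cells["class"] == NONTIL]
    n_til, n_non = len(til), len(non)
    n_nuc = len(cells)
    til_area = float(til["area"].sum()) * px2mm2
    non_area = float(non["area"].sum()) * px2mm2
    nuc_area = float(cells["area"].sum()) * px2mm2
    flags: list[str] = []
    g = lambda num, den, name: _guard(num, den, flags, name)
    vals = {
        "til_per_mm2": g(n_til, tissue_mm2, "til_per_mm2"),
        "til_frac_nuclei": g(n_til, n_nuc, "til_frac_nuclei"),
        "til_area_frac_tissue": g(til_area, tissue_mm2, "til_area_frac_tissue"),
        "n_til": float(n_til),
        "n_nontil": float(n_non),
        "n_nuclei": float(n_nuc),
        "tissue_area_mm2": tissue_mm2,
        "til_area_mm2": til_area,
        "nontil_area_mm2": non_area,
        "nuclear_area_frac_tissue": g(nuc_area, tissue_mm2, "nuclear_area_frac_tissue"),
        "nontil_per_mm2": g(n_non, tissue_mm2, "nontil_per_mm2"),
        "nontil_frac_nuclei": g(n_non, n_nuc, "nontil_frac_nuclei"),
        "nontil_area_frac_tissue": g(non_area, tissue_mm2, "nontil_area_frac_tissue"),
        "til_area_frac_nuclear": g(til_area, nuc_area, "til_area_frac_nuclear"),
        "til_nontil_count_ratio": g(n_til, n_non, "til_nontil_count_ratio"),
        "til_nontil_area_ratio": g(til_area, non_area, "til_nontil_area_ratio"),
        "mean_til_area_mm2": g(til_area, n_til, "mean_til_area_mm2"),
        "mean_nontil_area_mm2": g(non_area, n_non, "mean_nontil_area_mm2"),
        "til_per_1000_nuclei": 1000.0 * g(n_til, n_nuc, "til_per_1000_nuclei"),
    }
    return pd.Series(vals, index=DENTIL_NAMES), flags


def _components(coords: np.ndarray, radius: float) -> np.ndarray:
    """Connected-component labels of the radius graph over ``coords``."""
    n = len(coords)
    if n == 0:
        return np.zeros(0, int)
    tree = cKDTree(coords)
    pairs = np.array(list(tree.query_pairs(radius)), int)
    if len(pairs) == 0:
        return np.arange(n)
    adj = coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    _, labels = connected_components(adj, directed=False)
    return labels


def _hulls(coords: np.ndarray, labels: np.ndarray):
    """Per-component shapely hull geometry and hull area (0 if degenerate)."""
    geoms, areas, cents = [], [], []
    for lab in np.unique(labels):
        pts = coords[labels == lab]
        geom = MultiPoint(pts).convex_hull  # point/line for degenerate clusters
        geoms.append(geom)
        cents.append(pts.mean(axis=0))
        try:
            areas.append(float(ConvexHull(pts).volume) if len(pts) >= 3 else 0.0)
        except QhullError:
            areas.append(0.0)
    return geoms, np.asarray(areas), np.asarray(cents)


SPATIL_NAMES = [
    "n_til_clusters", "n_nontil_clusters",
    "til_hull_area_mean", "til_hull_area_std", "til_hull_area_max",
    "nontil_hull_area_mean", "nontil_hull_area_std", "nontil_hull_area_max",
    "intermix_fraction", "mean_cross_centroid_dist",
]


def spatil_features(cell_map: CellMap, linkage_radius: float = 50.0) -> pd.Series:
    """Reduced spaTIL spatial-architecture family (10 features).

    TIL and non-TIL clusters are connected components of the
    within-class centroid graph at ``linkage_radius``.  Features:
    cluster counts, convex-hull area statistics (mean/std/max, px^2)
    per class, the fraction of TIL clusters whose hull intersects at
    least one non-TIL hull, and the mean pairwise hull-centroid
    distance between classes.
    """
    out = dict.fromkeys(SPATIL_NAMES, 0.0)
    til_xy = cell_map.coords(TIL)
    non_xy = cell_map.coords(NONTIL)
    tl = _components(til_xy, linkage_radius)
    nl = _components(non_xy, linkage_radius)
    out["n_til_clusters"] = float(len(np.unique(tl))) if len(tl) else 0.0
    out["n_nontil_clusters"] = float(len(np.unique(nl))) if len(nl) else 0.0
    tg = ta = tc = ng = na = nc = None
    if len(tl):
        tg, ta, tc = _hulls(til_xy, tl)
        out["til_hull_area_mean"] = float(ta.mean())
        out["til_hull_area_std"] = float(ta.std())
        out["til_hull_area_max"] = float(ta.max())
    if len(nl):
        ng, na, nc = _hulls(non_xy, nl)
        out["nontil_hull_area_mean"] = float(na.mean())
        out["nontil_hull_area_std"] = float(na.std())
        out["nontil_hull_area_max"] = float(na.max())
    if tg and ng:
        inter = sum(any(t.intersects(nn) for nn in ng) for t in tg)
        out["intermix_fraction"] = inter / len(tg)
        d = np.linalg.norm(tc[:, None, :] - nc[None, :, :], axis=-1)
        out["mean_cross_centroid_dist"] = float(d.mean())
    return pd.Series(out, index=SPATIL_NAMES)


AGG_STATS = ("mean", "median", "skewness", "kurtosis")


def aggregate_patient(tile_table: pd.DataFrame) -> tuple[pd.Series, list[str]]:
    """Patient-level 4-moment aggregation of tile features.

    For every tile-level feature, compute mean, median, skewness and
    kurtosis across the patient's tiles (adjusted sample estimators;
    kurtosis is excess).  With fewer than 3 tiles the higher moments
    are undefined: they are set to 0 and flagged.

    Returns a flat Series named ``<feature>_<stat>`` and the flag list.
    """
    flags: list[str] = []
    n = len(tile_table)
    out = {}
    for col in tile_table.columns:
        v = tile_table[col].to_numpy(float)
        out[f"{col}_mean"] = float(v.mean()) if n else 0.0
        out[f"{col}_median"] = float(np.median(v)) if n else 0.0
        ok = False
        if n >= 3 and np.std(v) > 0:
            out[f"{col}_skewness"] = float(sps.skew(v, bias=False))
            ok = True
        else:
            out[f"{col}_skewness"] = 0.0
        if n >= 4 and np.std(v) > 0:  # adjusted kurtosis needs 4 samples
            out[f"{col}_kurtosis"] = float(sps.kurtosis(v, bias=False))
        else:
            out[f"{col}_kurtosis"] = 0.0
            ok = False
        if not ok:
            flags.append(col)
    return pd.Series(out), flags
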