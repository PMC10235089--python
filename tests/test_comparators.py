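"""denTIL density features, spaTIL spatial features, patient aggregation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from phenotil import aggregate_patient, dentil_features, spatil_features
from phenotil.cellmap import DESCRIPTOR_COLS, CellMap, empty_cell_table
from phenotil.comparators import DENTIL_NAMES, SPATIL_NAMES

from _oracles import union_find_components
from conftest import random_cell_map


def _point_map(points, classes, tile=1000, mpp=0.5, area=100.0):
    df = pd.DataFrame(np.full((len(points), len(DESCRIPTOR_COLS)), 1.0),
                      columns=DESCRIPTOR_COLS)
    df["area"] = area
    df.insert(0, "cell_id", np.arange(1, len(points) + 1))
    df.insert(1, "x", [p[0] for p in points])
    df.insert(2, "y", [p[1] for p in points])
    df.insert(3, "class", classes)
    return CellMap(df, microns_per_pixel=mpp, shape=(tile, tile))


class TestDenTil:
    def test_vector_has_19_named_features(self):
        cm = random_cell_map(50, seed=0)
        v, flags = dentil_features(cm)
        assert len(v) == 19
        assert list(v.index) == DENTIL_NAMES
        assert not flags

    def test_til_fraction_example(self):
        pts = [(i * 10.0, 50.0) for i in range(40)]
        classes = ["TIL"] * 10 + ["nonTIL"] * 30
        v, _ = dentil_features(_point_map(pts, classes))
        assert v["til_frac_nuclei"] == pytest.approx(0.25)

    def test_empty_tile_guarded(self):
        cm = CellMap(empty_cell_table())
        v, flags = dentil_features(cm)
        assert v["n_til"] == 0
        assert v["til_frac_nuclei"] == 0.0
        assert "til_frac_nuclei" in flags
        assert "til_nontil_count_ratio" in flags

    def test_matches_brute_force(self):
        cm = random_cell_map(80, seed=1)
        v, _ = dentil_features(cm)
        cells = cm.cells
        til = cells[cells["class"] == "TIL"]
        px2mm2 = (cm.microns_per_pixel / 1000.0) ** 2
        tissue = cm.shape[0] * cm.shape[1] * px2mm2
        assert v["til_per_mm2"] == pytest.approx(len(til) / tissue)
        assert v["til_area_frac_tissue"] == pytest.approx(til.area.sum() * px2mm2 / tissue)
        assert v["til_per_1000_nuclei"] == pytest.approx(1000 * len(til) / len(cells))
        assert v["mean_til_area_mm2"] == pytest.approx(til.area.mean() * px2mm2)

    def test_scale_consistency(self):
        """Doubling microns/px quadruples mm^2 areas, fixes dimensionless ratios."""
        cm1 = random_cell_map(60, seed=2)
        cm2 = CellMap(cm1.cells.copy(), microns_per_pixel=1.0, shape=cm1.shape)
        v1, _ = dentil_features(cm1)
        v2, _ = dentil_features(cm2)
        assert v2["tissue_area_mm2"] == pytest.approx(4 * v1["tissue_area_mm2"])
        assert v2["til_area_mm2"] == pytest.approx(4 * v1["til_area_mm2"])
        for name in ("til_frac_nuclei", "til_area_frac_tissue",
                     "til_nontil_count_ratio", "til_per_1000_nuclei"):
            assert v2[name] == pytest.approx(v1[name])


class TestSpaTil:
    def test_single_clump_no_nontil(self):
        pts = [(100 + dx, 100 + dy) for dx in (0, 10, 20) for dy in (0, 10)]
        v = spatil_features(_point_map(pts, ["TIL"] * 6), linkage_radius=30)
        assert v["n_til_clusters"] == 1
        assert v["intermix_fraction"] == 0.0

    def test_interleaved_lattice_fully_intermixed(self):
        pts, classes = [], []
        for i in range(6):
            for j in range(6):
                pts.append((100 + 20.0 * i, 100 + 20.0 * j))
                classes.append("TIL" if (i + j) % 2 == 0 else "nonTIL")
        v = spatil_features(_point_map(pts, classes), linkage_radius=40)
        assert v["intermix_fraction"] == 1.0

    def test_components_match_union_find(self):
        cm = random_cell_map(60, seed=3, tile=400)
        for radius in (30.0, 60.0):
            v = spatil_features(cm, linkage_radius=radius)
            til_xy = cm.coords("TIL")
            non_xy = cm.coords("nonTIL")
            assert v["n_til_clusters"] == len(np.unique(union_find_components(til_xy, radius)))
            assert v["n_nontil_clusters"] == len(np.unique(union_find_components(non_xy, radius)))

    def test_component_count_monotone_in_radius(self):
        cm = random_cell_map(80, seed=4, tile=400)
        counts = [spatil_features(cm, linkage_radius=r)["n_til_clusters"]
                  for r in (10, 25, 50, 100, 200)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_names_stable(self):
        cm = random_cell_map(30, seed=5)
        assert list(spatil_features(cm).index) == SPATIL_NAMES


class TestAggregation:
    def test_four_stats_per_feature(self):
        tiles = pd.DataFrame({"f1": [1.0, 2.0, 3.0, 4.0], "f2": [0.0, 1.0, 0.5, 2.0]})
        agg, flags = aggregate_patient(tiles)
        assert len(agg) == 2 * 4
        for f in ("f1", "f2"):
            for s in ("mean", "median", "skewness", "kurtosis"):
                assert f"{f}_{s}" in agg.index
        assert not flags

    def test_identical_tiles_flagged(self):
        tiles = pd.DataFrame({"f": [3.0, 3.0, 3.0, 3.0]})
        agg, flags = aggregate_patient(tiles)
        assert agg["f_mean"] == 3.0 and agg["f_median"] == 3.0
        assert agg["f_skewness"] == 0.0 and agg["f_kurtosis"] == 0.0
        assert flags == ["f"]

    def test_single_tile_flagged(self):
        agg, flags = aggregate_patient(pd.DataFrame({"f": [5.0]}))
        assert agg["f_mean"] == 5.0 and agg["f_median"] == 5.0
        assert agg["f_skewness"] == 0.0 and agg["f_kurtosis"] == 0.0
        assert flags == ["f"]

    def test_moments_match_adjusted_estimators(self):
        rng = np.random.default_rng(6)
        v = rng.normal(size=10)
        agg, flags = aggregate_patient(pd.DataFrame({"f": v}))
        assert not flags
        assert agg["f_mean"] == pytest.approx(v.mean())
        assert agg["f_median"] == pytest.approx(np.median(v))
        assert agg["f_skewness"] == pytest.approx(sps.skew(v, bias=False))
        assert agg["f_kurtosis"] == pytest.approx(sps.kurtosis(v, bias=False))
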