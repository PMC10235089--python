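"""Piecewise-linear registration and IF subtype pairing."""

import numpy as np
import pandas as pd
import pytest

from phenotil import (
    cluster_subtype_composition,
    fit_registration,
    gen_cell_map,
    gen_if_stack,
    quantify_subtype,
    render_tile,
)
from phenotil.qmif import DegenerateGeometryError

from conftest import small_sim_config

AQUA1 = {"CD4": 1.0, "CD8": 1.0, "CD20": 1.0}


@pytest.fixture(scope="module")
def grid_points():
    rng = np.random.default_rng(0)
    xs, ys = np.meshgrid(np.linspace(0, 500, 5), np.linspace(0, 500, 5))
    pts = np.column_stack([xs.ravel(), ys.ravel()])
    return pts + rng.uniform(-10, 10, pts.shape)


class TestRegistration:
    def test_identity_mapping(self, grid_points):
        tf = fit_registration(grid_points, grid_points)
        mapped, outside = tf(grid_points)
        assert np.abs(mapped - grid_points).max() <= 1e-9
        assert not outside.any()

    def test_exact_at_control_points(self, grid_points):
        rng = np.random.default_rng(1)
        dst = grid_points + rng.uniform(-15, 15, grid_points.shape)
        tf = fit_registration(grid_points, dst)
        assert tf.max_control_residual() <= 1e-9

    def test_recovers_global_affine_inside_hull(self, grid_points):
        A = np.array([[0.97, 0.08], [-0.05, 1.03]])
        t = np.array([12.0, -4.0])
        dst = grid_points @ A.T + t
        tf = fit_registration(grid_points, dst)
        rng = np.random.default_rng(2)
        probe = rng.uniform(60, 440, (300, 2))
        mapped, outside = tf(probe)
        inside = ~outside
        assert inside.sum() > 200
        assert np.abs(mapped[inside] - (probe[inside] @ A.T + t)).max() < 1e-6

    def test_three_points_rejected(self):
        pts = np.array([[0.0, 0], [1, 0], [0, 1]])
        with pytest.raises(DegenerateGeometryError):
            fit_registration(pts, pts)

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.arange(5.0), np.arange(5.0)])
        with pytest.raises(DegenerateGeometryError):
            fit_registration(pts, pts + 1.0)

    def test_inverse_composition_returns_points(self, grid_points):
        rng = np.random.default_rng(3)
        dst = grid_points + rng.uniform(-8, 8, grid_points.shape)
        fwd = fit_registration(grid_points, dst)
        inv = fwd.inverse()
        probe = rng.uniform(100, 400, (100, 2))
        mapped, out_f = fwd(probe)
        back, out_b = inv(mapped)
        ok = ~(out_f | out_b)
        assert ok.sum() > 50
        assert np.abs(back[ok] - probe[ok]).max() < 1e-6

    def test_swapped_role_fit_matches_inverse_on_mild_distortion(self, grid_points):
        """When the distortion preserves the Delaunay topology, re-fitting
        with swapped point roles is the exact inverse."""
        from scipy.spatial import Delaunay

        rng = np.random.default_rng(0)
        src = rng.uniform(0, 500, (16, 2))
        dst = src + rng.uniform(-1, 1, src.shape)
        same_topology = np.array_equal(
            np.sort(Delaunay(src).simplices, axis=1),
            np.sort(Delaunay(dst).simplices, axis=1),
        )
        assert same_topology  # precondition of the identity
        fwd = fit_registration(src, dst)
        swapped = fit_registration(dst, src)
        probe = rng.uniform(100, 400, (100, 2))
        mapped, out_f = fwd(probe)
        back, out_b = swapped(mapped)
        ok = ~(out_f | out_b)
        assert ok.sum() > 50
        assert np.abs(back[ok] - probe[ok]).max() < 1e-6


def _ring_fixture():
    """One nucleus disc; CD8 channel bright on its surrounding ring."""
    H = W = 64
    mask = np.zeros((H, W), np.int32)
    yy, xx = np.mgrid[:H, :W]
    d2 = (yy - 32) ** 2 + (xx - 32) ** 2
    mask[d2 <= 8**2] = 1
    stack = np.zeros((3, H, W))
    ring = (d2 > 8**2) & (d2 <= 11**2)
    stack[1][ring] = 100.0
    return stack, mask


class TestQuantifySubtype:
    def test_uniform_cd8_ring(self):
        stack, mask = _ring_fixture()
        calls = quantify_subtype(stack, mask, None, AQUA1, ring_width=2)
        row = calls.iloc[0]
        assert row.label == "CD8"
        assert row.norm_CD8 == pytest.approx(100.0)
        assert row.norm_CD4 == 0.0

    def test_aqua_normalization_can_flip_label(self):
        stack, mask = _ring_fixture()
        stack[0] = stack[1] * 0.9  # CD4 slightly dimmer
        calls = quantify_subtype(stack, mask, None,
                                 {"CD4": 0.5, "CD8": 1.0, "CD20": 1.0})
        assert calls.iloc[0].label == "CD4"

    def test_exact_tie_is_unassigned(self):
        stack, mask = _ring_fixture()
        stack[0] = stack[1].copy()
        stack[2] = stack[1].copy()
        calls = quantify_subtype(stack, mask, None, AQUA1)
        assert calls.iloc[0].label == "unassigned"

    def test_label_scale_invariant(self):
        stack, mask = _ring_fixture()
        stack[0] = stack[1] * 0.4
        a = quantify_subtype(stack, mask, None, AQUA1)
        b = quantify_subtype(stack * 7.3, mask, None, AQUA1)
        assert a.iloc[0].label == b.iloc[0].label

    def test_nonpositive_aqua_rejected(self):
        stack, mask = _ring_fixture()
        with pytest.raises(ValueError):
            quantify_subtype(stack, mask, None, {"CD4": 0.0, "CD8": 1.0, "CD20": 1.0})

    def test_noise_free_synthetic_calls_are_perfect(self):
        cfg = small_sim_config(tile_size=256, n_til_hotspots=2,
                               offspring_mean=10, lambda_nontil=200)
        cm, truth = gen_cell_map(cfg, seed=13)
        stack, _ = gen_if_stack(cm, truth)
        _, mask = render_tile(cm, cfg, seed=13)
        calls = quantify_subtype(stack, mask, None, AQUA1, cell_ids=cm.til_ids())
        labels = calls.set_index("til_id")["label"]
        assert all(labels[c] == truth.true_subtype[c] for c in cm.til_ids())


class TestComposition:
    def test_percentages_from_calls(self):
        calls = pd.DataFrame({"til_id": [1, 2, 3, 4],
                              "label": ["CD8", "CD8", "CD4", "CD20"]})
        labels = pd.Series([4, 4, 4, 4], index=[1, 2, 3, 4])
        pct, counts = cluster_subtype_composition(labels, calls)
        assert pct.loc["C4", ["CD4", "CD8", "CD20"]].tolist() == [25.0, 50.0, 25.0]
        assert counts.loc["C4"].sum() == 4

    def test_empty_cluster_flagged_zero_row(self):
        calls = pd.DataFrame({"til_id": [1], "label": ["CD4"]})
        pct, _ = cluster_subtype_composition(pd.Series([2], index=[1]), calls)
        assert pct.loc["C1", "flagged_empty"]
        assert pct.loc["C1", ["CD4", "CD8", "CD20"]].sum() == 0.0

    def test_counts_reconcile_with_percentages(self):
        rng = np.random.default_rng(4)
        ids = np.arange(1, 101)
        calls = pd.DataFrame({
            "til_id": ids,
            "label": rng.choice(["CD4", "CD8", "CD20", "unassigned"], 100),
        })
        labels = pd.Series(rng.integers(1, 9, 100), index=ids)
        pct, counts = cluster_subtype_composition(labels, calls)
        for c in counts.index:
            tot = counts.loc[c].sum()
            if tot:
                back = pct.loc[c, ["CD4", "CD8", "CD20"]].to_numpy(float) * tot / 100.0
                np.testing.assert_allclose(back, counts.loc[c].to_numpy(float),
                                           atol=1e-9)
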