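"""Stain normalization, watershed segmentation, descriptors, TIL classing."""

import numpy as np
import pandas as pd
import pytest
from skimage.draw import disk

from phenotil import classify_tils, extract_descriptors, gen_cell_map, render_tile, segment_nuclei
from phenotil.cellmap import CellMap, empty_cell_table
from phenotil.segmentation import match_objects, train_til_classifier
from phenotil.stain import InsufficientTissueError, estimate_stain_profile, macenko_normalize

from conftest import small_sim_config


@pytest.fixture(scope="module")
def rendered():
    cfg = small_sim_config(offspring_mean=15, lambda_nontil=400,
                           min_separation_factor=1.2)
    cm, _ = gen_cell_map(cfg, seed=21)
    img, mask = render_tile(cm, cfg, seed=21)
    return cfg, cm, img, mask


def pure_stain_tile(seed=0, shape=(128, 128)):
    """Tile whose optical densities lie exactly in a two-stain plane."""
    rng = np.random.default_rng(seed)
    h_vec = np.array([0.65, 0.70, 0.29])
    e_vec = np.array([0.07, 0.99, 0.11])
    c = np.zeros((shape[0] * shape[1], 2))
    tissue = rng.random(len(c)) < 0.6
    c[tissue, 0] = rng.uniform(0.2, 1.2, tissue.sum())
    c[tissue, 1] = rng.uniform(0.1, 0.9, tissue.sum())
    od = c @ np.vstack([h_vec, e_vec])
    img = np.clip(256.0 * np.exp(-od) - 1.0, 0, 255)
    return img.reshape(*shape, 3).astype(np.uint8)


class TestMacenko:
    def test_self_normalization_is_near_identity(self):
        """Normalizing a two-stain tile onto its own profile changes
        each pixel by at most ~2 gray levels (8-bit quantization)."""
        img = pure_stain_tile()
        own = estimate_stain_profile(img)
        out = macenko_normalize(img, reference=own)
        diff = np.abs(out.astype(int) - img.astype(int))
        assert diff.max() <= 2

    def test_white_tile_insufficient_tissue(self):
        white = np.full((64, 64, 3), 255, np.uint8)
        with pytest.raises(InsufficientTissueError):
            macenko_normalize(white)

    def test_scaled_concentrations_normalize_back(self, rendered):
        """Globally scaling stain concentrations is undone by normalization."""
        _, _, img, _ = rendered
        od = -np.log((img.astype(float) + 1) / 256.0)
        scaled = np.clip(256.0 * np.exp(-1.4 * od) - 1.0, 0, 255).astype(np.uint8)
        ref = estimate_stain_profile(img)
        a = macenko_normalize(img, reference=ref).astype(float)
        b = macenko_normalize(scaled, reference=ref).astype(float)
        assert np.quantile(np.abs(a - b), 0.95) <= 10


class TestSegmentNuclei:
    def test_blank_tile_empty_mask(self):
        blank = np.full((128, 128, 3), 230, np.uint8)
        assert segment_nuclei(blank).max() == 0

    def test_object_f1_on_rendered_tile(self, rendered):
        _, _, img, mask = rendered
        pred = segment_nuclei(img)
        assert match_objects(pred, mask)["f1"] >= 0.9

    def test_touching_nuclei_split_by_watershed(self):
        """Two overlapping dark discs are separated into 2 labels."""
        img = np.full((96, 96, 3), (234, 198, 214), np.uint8)
        for c in ((48, 36), (48, 58)):
            rr, cc = disk(c, 12, shape=(96, 96))
            img[rr, cc] = (90, 60, 140)
        labels = segment_nuclei(img)
        assert labels.max() == 2

    def test_label_count_invariant_to_rotation(self, rendered):
        _, _, img, _ = rendered
        n0 = segment_nuclei(img).max()
        for k in (1, 2, 3):
            assert segment_nuclei(np.rot90(img, k)).max() == n0


class TestDescriptors:
    def test_disc_shape_descriptors(self):
        img = np.full((64, 64, 3), 240, np.uint8)
        mask = np.zeros((64, 64), np.int32)
        rr, cc = disk((32, 32), 14)
        mask[rr, cc] = 1
        img[rr, cc] = 50
        cm = extract_descriptors(img, mask)
        rec = cm.cells.iloc[0]
        assert rec.eccentricity <= 0.05
        assert rec.solidity >= 0.98
        assert rec.x == pytest.approx(32, abs=0.5)

    def test_square_area(self):
        img = np.full((32, 32, 3), 240, np.uint8)
        mask = np.zeros((32, 32), np.int32)
        mask[10:20, 5:15] = 1
        cm = extract_descriptors(img, mask)
        assert cm.cells.iloc[0].area == 100.0

    def test_color_stats_match_per_pixel_recomputation(self, rendered):
        _, _, img, mask = rendered
        cm = extract_descriptors(img, mask)
        rec = cm.cells.iloc[5]
        pix = img[mask == rec.cell_id]
        for k, ch in enumerate("RGB"):
            assert rec[f"mean_{ch}"] == pytest.approx(pix[:, k].mean())
            assert rec[f"std_{ch}"] == pytest.approx(pix[:, k].std())
            assert rec[f"min_{ch}"] == pix[:, k].min()
            assert rec[f"max_{ch}"] == pix[:, k].max()


class TestClassifyTils:
    def test_rule_mode_accuracy_on_separated_populations(self, rendered):
        cfg, cm, img, mask = rendered
        seg = extract_descriptors(img, mask)
        seg = classify_tils(seg)
        truth = cm.cells.set_index("cell_id")["class"]
        pred = seg.cells.set_index("cell_id")["class"]
        common = truth.index.intersection(pred.index)
        acc = (truth.loc[common] == pred.loc[common]).mean()
        assert acc >= 0.95

    def test_rule_mode_leaves_none_unassigned(self, rendered):
        _, _, img, mask = rendered
        cm = classify_tils(extract_descriptors(img, mask))
        assert set(cm.cells["class"]) <= {"TIL", "nonTIL"}

    def test_empty_record_list(self):
        cm = CellMap(empty_cell_table())
        assert len(classify_tils(cm)) == 0

    def test_training_accuracy_at_least_holdout(self, rendered):
        cfg, cm, img, mask = rendered
        seg = extract_descriptors(img, mask)
        truth = cm.cells.set_index("cell_id")["class"]
        labeled = seg.cells[seg.cells.cell_id.isin(truth.index)].reset_index(drop=True)
        y = (truth.loc[labeled.cell_id].to_numpy() == "TIL").astype(int)
        n = len(labeled)
        tr = np.arange(n) % 2 == 0
        clf = train_til_classifier(labeled[tr], y[tr], seed=0)
        train_cm = classify_tils(CellMap(labeled[tr]), model=clf, mode="model")
        test_cm = classify_tils(CellMap(labeled[~tr]), model=clf, mode="model")
        acc_tr = ((train_cm.cells["class"] == "TIL").to_numpy() == y[tr].astype(bool)).mean()
        acc_te = ((test_cm.cells["class"] == "TIL").to_numpy() == y[~tr].astype(bool)).mean()
        assert acc_tr >= acc_te - 0.02  # sanity ordering, small slack for ties
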