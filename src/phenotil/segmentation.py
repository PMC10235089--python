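"""Nuclei segmentation, per-nucleus descriptors, and TIL classification.

The segmentation stage is a classical marker-controlled watershed:
hematoxylin-channel deconvolution, Gaussian smoothing, foreground
thresholding, distance transform, peak markers, watershed.  Externally
produced label masks (e.g. from a deep-learning segmenter) can be
ingested directly and sent through the same descriptor/classification
path.

TIL / non-TIL classification runs either in rule mode (thresholds on
area, solidity and hematoxylin darkness — dependency-free and
deterministic) or as a maximum-margin linear classifier trained on
labeled nucleus records.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.color import rgb2gray, rgb2hed
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import watershed
from sklearn.svm import LinearSVC

from ._haralick import haralick_features
from .cellmap import HARALICK_COLS, NONTIL, TIL, CellMap, empty_cell_table

MIN_NUCLEUS_AREA = 16  # px^2 at 20x; sub-lymphocyte debris threshold


def segment_nuclei(
    image: np.ndarray,
    min_area: int = MIN_NUCLEUS_AREA,
    smoothing_sigma: float = 1.5,
    marker_min_distance: int = 5,
) -> np.ndarray:
    """Marker-controlled watershed nuclei segmentation.

    Pipeline: hematoxylin channel (color deconvolution) -> Gaussian
    smoothing -> Otsu foreground threshold -> Euclidean distance
    transform -> local-maximum markers -> watershed.  Objects below
    ``min_area`` are removed.  A blank tile yields an empty mask.

    Returns an int32 label mask (0 = background).
    """
    hed = rgb2hed(image)
    hema = gaussian(hed[..., 0], sigma=smoothing_sigma)
    if hema.max() - hema.min() < 1e-6:
        return np.zeros(image.shape[:2], np.int32)
    thr = threshold_otsu(hema)
    fg = hema > thr
    # guard: Otsu on a background-only tile can split noise; require
    # foreground to be darker-stained than background by a margin
    if fg.mean() < 1e-4 or (hema[fg].mean() - hema[~fg].mean()) < 0.02:
        return np.zeros(image.shape[:2], np.int32)
    lab, _ = ndi.label(fg)
    sizes = np.bincount(lab.ravel())
    fg &= ~np.isin(lab, np.where(sizes < min_area)[0])
    if not fg.any():
        return np.zeros(image.shape[:2], np.int32)
    dist = ndi.distance_transform_edt(fg)
    peaks = peak_local_max(
        dist, min_distance=marker_min_distance, labels=fg, exclude_border=False
    )
    markers = np.zeros(fg.shape, np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-dist, markers, mask=fg)
    # re-apply the area floor to post-watershed fragments
    sizes = np.bincount(labels.ravel())
    small = np.where(sizes < min_area)[0]
    if len(small):
        labels[np.isin(labels, small)] = 0
    # relabel consecutively
    out, _, _ = _relabel(labels)
    return out


def _relabel(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    ids = np.unique(labels)
    ids = ids[ids > 0]
    out = np.zeros_like(labels, np.int32)
    for new, old in enumerate(ids, start=1):
        out[labels == old] = new
    return out, ids, len(ids)


def extract_descriptors(image: np.ndarray, mask: np.ndarray,
                        microns_per_pixel: float = 0.5,
                        tile_id: str = "tile") -> CellMap:
    """Per-nucleus shape, color and texture descriptors.

    One record per label: centroid (x right, y down, 0-based), area,
    perimeter, eccentricity, equivalent diameter, solidity,
    orientation, per-channel mean/std/min/max, and the 12 co-occurrence
    texture statistics of the grayscale bounding-box patch.  Class is
    ``unassigned`` until :func:`classify_tils` runs.
    """
    gray = (rgb2gray(image) * 255).astype(np.uint8)
    rows = []
    for rp in regionprops(mask.astype(np.int32)):
        cy, cx = rp.centroid
        minr, minc, maxr, maxc = rp.bbox
        region = rp.image  # boolean within bbox
        rec = {
            "cell_id": int(rp.label),
            "x": float(cx),
            "y": float(cy),
            "class": "unassigned",
            "area": float(rp.area),
            "perimeter": float(rp.perimeter),
            "eccentricity": float(rp.eccentricity),
            "equiv_diameter": float(rp.equivalent_diameter_area),
            "solidity": float(rp.solidity),
            "orientation": float(rp.orientation),
        }
        for k, ch in enumerate("RGB"):
            vals = image[minr:maxr, minc:maxc, k][region].astype(float)
            rec[f"mean_{ch}"] = float(vals.mean())
            rec[f"std_{ch}"] = float(vals.std())
            rec[f"min_{ch}"] = float(vals.min())
            rec[f"max_{ch}"] = float(vals.max())
        har = haralick_features(gray[minr:maxr, minc:maxc])
        rec.update(dict(zip(HARALICK_COLS, har)))
        rows.append(rec)
    if not rows:
        return CellMap(empty_cell_table(), tile_id=tile_id,
                       microns_per_pixel=microns_per_pixel, shape=mask.shape)
    return CellMap(pd.DataFrame(rows), tile_id=tile_id,
                   microns_per_pixel=microns_per_pixel, shape=mask.shape)


# rule-mode thresholds: lymphocyte nuclei are small, compact and dark
RULE_MAX_AREA = 280.0        # px^2 at 20x
RULE_MIN_SOLIDITY = 0.85
RULE_MAX_BRIGHTNESS = 135.0  # mean of mean_R/G/B


def classify_tils(
    cell_map: CellMap,
    model: LinearSVC | None = None,
    mode: str = "rule",
    max_area: float = RULE_MAX_AREA,
    min_solidity: float = RULE_MIN_SOLIDITY,
    max_brightness: float = RULE_MAX_BRIGHTNESS,
) -> CellMap:
    """Assign every nucleus a TIL / non-TIL class.

    Rule mode thresholds area, solidity and mean brightness (small,
    compact, darkly stained nuclei are TILs); model mode scores the
    descriptor vector with a fitted linear maximum-margin classifier
    (see :func:`train_til_classifier`).  No cell is left unassigned.
    """
    cells = cell_map.cells.copy()
    if len(cells) == 0:
        return cell_map
    if mode == "rule":
        bright = cells[["mean_R", "mean_G", "mean_B"]].mean(axis=1)
        is_til = (
            (cells["area"] <= max_area)
            & (cells["solidity"] >= min_solidity)
            & (bright <= max_brightness)
        )
    elif mode == "model":
        if model is None:
            raise ValueError("model mode requires a fitted classifier")
        X = _classifier_matrix(cells)
        is_til = pd.Series(model.predict(X) == 1, index=cells.index)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    cells["class"] = np.where(is_til, TIL, NONTIL)
    return CellMap(cells, tile_id=cell_map.tile_id,
                   microns_per_pixel=cell_map.microns_per_pixel,
                   shape=cell_map.shape)


_CLF_COLS = ["area", "perimeter", "eccentricity", "equiv_diameter", "solidity",
             "mean_R", "mean_G", "mean_B"]


def _classifier_matrix(cells: pd.DataFrame) -> np.ndarray:
    return cells[_CLF_COLS].to_numpy(float)


def train_til_classifier(cells: pd.DataFrame, labels: np.ndarray,
                         seed: int = 0) -> LinearSVC:
    """Fit the linear maximum-margin TIL classifier (1 = TIL)."""
    clf = LinearSVC(C=1.0, random_state=seed, max_iter=20000, dual="auto")
    clf.fit(_classifier_matrix(cells), np.asarray(labels).astype(int))
    return clf


def ingest_mask(image: np.ndarray, mask_path: str | Path | np.ndarray,
                microns_per_pixel: float = 0.5, tile_id: str = "tile") -> CellMap:
    """Load an externally produced label mask and extract descriptors.

    Bypass path for masks produced by external segmenters (e.g. deep
    models); classes can be assigned afterwards by :func:`classify_tils`
    or merged from an external cell table.
    """
    if isinstance(mask_path, (str, Path)):
        import tifffile

        mask = tifffile.imread(str(mask_path))
    else:
        mask = np.asarray(mask_path)
    return extract_descriptors(image, mask.astype(np.int32),
                               microns_per_pixel=microns_per_pixel, tile_id=tile_id)


def match_objects(pred_mask: np.ndarray, true_mask: np.ndarray,
                  iou_threshold: float = 0.5) -> dict:
    """Object-level detection metrics at an IoU threshold.

    Greedy one-to-one matching of predicted to ground-truth objects by
    IoU; returns precision, recall and F1.
    """
    pred_ids = np.unique(pred_mask)
    pred_ids = pred_ids[pred_ids > 0]
    true_ids = np.unique(true_mask)
    true_ids = true_ids[true_ids > 0]
    if len(pred_ids) == 0 or len(true_ids) == 0:
        f1 = 1.0 if len(pred_ids) == len(true_ids) else 0.0
        return {"tp": 0, "fp": len(pred_ids), "fn": len(true_ids),
                "precision": f1, "recall": f1, "f1": f1}
    # IoU via joint histogram of the two label images
    joint = pd.crosstab(pred_mask.ravel(), true_mask.ravel())
    pred_area = {i: (pred_mask == i).sum() for i in pred_ids}
    true_area = {i: (true_mask == i).sum() for i in true_ids}
    pairs = []
    for p in pred_ids:
        if p not in joint.index:
            continue
        for t in true_ids:
            inter = joint.at[p, t] if t in joint.columns else 0
            if inter == 0:
                continue
            iou = inter / (pred_area[p] + true_area[t] - inter)
            if iou >= iou_threshold:
                pairs.append((iou, p, t))
    pairs.sort(reverse=True)
    used_p: set = set()
    used_t: set = set()
    tp = 0
    for _, p, t in pairs:
        if p in used_p or t in used_t:
            continue
        used_p.add(p)
        used_t.add(t)
        tp += 1
    fp = len(pred_ids) - tp
    fn = len(true_ids) - tp
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {"tp": tp, "fp": fp, "fn": fn,
            "precision": precision, "recall": recall, "f1": f1}
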