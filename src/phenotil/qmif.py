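"""H&E / immunofluorescence co-registration and single-cell subtype pairing.

Consecutive tissue sections imaged by H&E and multiplexed IF are
misaligned by smooth, locally varying deformations.  The registration
model is piecewise linear: control-point pairs are triangulated
(Delaunay, on the source points) and each triangle carries its own
affine map, so the transform is exact at every control point and
continuous across triangle edges.  Points outside the convex hull of
the control points are mapped by the affine of the nearest triangle
and flagged.

Subtype pairing quantifies each TIL's membrane-ring intensity in the
CD4 / CD8 / CD20 channels, normalizes by per-core AQUA scalars, and
assigns the argmax marker as the cell's subtype label.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import Delaunay, QhullError

MARKERS = ("CD4", "CD8", "CD20")


class DegenerateGeometryError(ValueError):
    """Control points do not define a valid triangulation."""


class PiecewiseLinearTransform:
    """Control-point piecewise-linear (per-triangle affine) mapping.

    Parameters
    ----------
    src, dst
        Matched control points, shape (M, 2), M >= 4, not all collinear.

    Notes
    -----
    The transform is exact at control points.  Evaluation returns the
    mapped coordinates together with a boolean flag per point marking
    locations outside the convex hull of the source points (these are
    extrapolated with the nearest triangle's affine).
    """

    def __init__(self, src: np.ndarray, dst: np.ndarray):
        src = np.asarray(src, float)
        dst = np.asarray(dst, float)
        if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
            raise ValueError("src and dst must both be (M, 2)")
        if len(src) < 4:
            raise DegenerateGeometryError("at least 4 control-point pairs required")
        if len(np.unique(src, axis=0)) < len(src):
            raise DegenerateGeometryError("duplicate source control points")
        try:
            self.tri = Delaunay(src)
        except QhullError as e:  # collinear input
            raise DegenerateGeometryError(f"degenerate control-point geometry: {e}") from e
        if self.tri.simplices.size == 0:
            raise DegenerateGeometryError("control points are collinear")
        self.src = src
        self.dst = dst
        # per-triangle affine A (2x2) and offset t: dst = A @ src + t
        self._affines = []
        for simplex in self.tri.simplices:
            s = src[simplex]  # 3x2
            d = dst[simplex]
            M = np.column_stack([s, np.ones(3)])  # 3x3
            coef = np.linalg.solve(M, d)  # 3x2: rows for x, y, 1
            self._affines.append(coef)
        self._affines = np.asarray(self._affines)  # (T, 3, 2)
        self._centroids = src[self.tri.simplices].mean(axis=1)

    def __call__(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map ``points`` (N, 2); returns (mapped, out_of_hull flags)."""
        pts = np.atleast_2d(np.asarray(points, float))
        simplex = self._locate(pts)
        outside = simplex < 0
        if outside.any():
            # nearest-triangle extension by centroid distance
            d2 = ((pts[outside, None, :] - self._centroids[None, :, :]) ** 2).sum(-1)
            simplex = simplex.copy()
            simplex[outside] = d2.argmin(axis=1)
        P = np.column_stack([pts, np.ones(len(pts))])  # (N, 3)
        coefs = self._affines[simplex]  # (N, 3, 2)
        mapped = np.einsum("ni,nij->nj", P, coefs)
        return mapped, outside

    def inverse(self) -> "PiecewiseLinearTransform":
        """Exact inverse sharing this transform's triangle topology.

        Per-triangle affines are inverted and located by barycentric
        search over the *mapped* triangles.  Note: re-fitting with
        swapped point roles instead re-triangulates the destination
        points, which agrees with this inverse only when both Delaunay
        triangulations share the same simplices.
        """
        inv = PiecewiseLinearTransform.__new__(PiecewiseLinearTransform)
        inv.src = self.dst
        inv.dst = self.src
        inv.tri = None
        affines = []
        for coef in self._affines:  # dst = [src 1] @ coef
            A = coef[:2]
            t = coef[2]
            Ainv = np.linalg.inv(A)
            affines.append(np.vstack([Ainv, -t @ Ainv]))
        inv._affines = np.asarray(affines)
        inv._triangles = self.dst[self.tri.simplices]  # (T, 3, 2)
        inv._centroids = inv._triangles.mean(axis=1)
        return inv

    def _locate(self, pts: np.ndarray) -> np.ndarray:
        """Simplex index per point; -1 outside all triangles."""
        if self.tri is not None:
            return self.tri.find_simplex(pts)
        # barycentric containment over explicit triangles
        out = np.full(len(pts), -1, int)
        a = self._triangles[:, 0]
        e1 = self._triangles[:, 1] - a
        e2 = self._triangles[:, 2] - a
        det = e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0]
        for k in range(len(self._triangles)):
            if abs(det[k]) < 1e-15:
                continue
            need = out == -1
            if not need.any():
                break
            d = pts[need] - a[k]
            u = (d[:, 0] * e2[k, 1] - d[:, 1] * e2[k, 0]) / det[k]
            v = (e1[k, 0] * d[:, 1] - e1[k, 1] * d[:, 0]) / det[k]
            hit = (u >= -1e-12) & (v >= -1e-12) & (u + v <= 1 + 1e-12)
            idx = np.nonzero(need)[0][hit]
            out[idx] = k
        return out

    def max_control_residual(self) -> float:
        mapped, _ = self(self.src)
        return float(np.abs(mapped - self.dst).max())


def fit_registration(src_points: np.ndarray, dst_points: np.ndarray) -> PiecewiseLinearTransform:
    """Fit the piecewise-linear registration from matched control points.

    Requires at least 4 non-collinear pairs; the returned transform is
    exact at every control point.
    """
    return PiecewiseLinearTransform(src_points, dst_points)


def quantify_subtype(
    if_stack: np.ndarray,
    nucleus_mask: np.ndarray,
    transform: PiecewiseLinearTransform | None,
    aqua: dict[str, float],
    ring_width: int = 2,
    cell_ids: np.ndarray | None = None,
) -> pd.DataFrame:
    """Membrane-ring marker quantification and argmax subtype calling.

    For each nucleus the membrane ring is the morphological dilation of
    the (transformed) nucleus by ``ring_width`` pixels minus the
    nucleus itself.  Mean intensity per marker over the ring is divided
    by the marker's AQUA scalar; the highest normalized marker becomes
    the label; an exact tie yields ``unassigned``.

    Parameters
    ----------
    if_stack
        (3, H, W) array ordered (CD4, CD8, CD20).
    nucleus_mask
        Label mask in the H&E frame; 0 is background.
    transform
        H&E -> IF mapping, or ``None`` for identity (already registered).
    aqua
        Positive per-marker normalization scalars, keys CD4/CD8/CD20.
    cell_ids
        Labels to quantify (default: all nonzero labels).

    Returns
    -------
    pandas.DataFrame
        One row per cell: til_id, raw_/norm_ intensity per marker,
        label, confidence (top/second ratio), out_of_hull flag.
    """
    for m in MARKERS:
        if aqua[m] <= 0:
            raise ValueError("AQUA scalars must be positive")
    _, H, W = if_stack.shape
    if cell_ids is None:
        cell_ids = np.unique(nucleus_mask)
        cell_ids = cell_ids[cell_ids > 0]
    rows = []
    objects = ndi.find_objects(nucleus_mask)
    for cid in cell_ids:
        cid = int(cid)
        sl = objects[cid - 1] if cid - 1 < len(objects) else None
        if sl is None:
            continue
        local = nucleus_mask[sl] == cid
        ys, xs = np.nonzero(local)
        ys = ys + sl[0].start
        xs = xs + sl[1].start
        out_flag = False
        if transform is not None:
            mapped, out = transform(np.column_stack([xs, ys]).astype(float))
            out_flag = bool(out.any())
            xs = np.round(mapped[:, 0]).astype(int)
            ys = np.round(mapped[:, 1]).astype(int)
            keep = (xs >= 0) & (xs < W) & (ys >= 0) & (ys < H)
            xs, ys = xs[keep], ys[keep]
        nucleus = np.zeros((H, W), bool)
        nucleus[ys, xs] = True
        ring = ndi.binary_dilation(nucleus, iterations=ring_width) & ~nucleus
        if not ring.any():
            ring = nucleus  # degenerate tiny object: fall back to the nucleus
        raw = np.array([float(if_stack[k][ring].mean()) for k in range(3)])
        norm = raw / np.array([aqua[m] for m in MARKERS])
        order = np.argsort(norm)[::-1]
        top, second = norm[order[0]], norm[order[1]]
        if np.isclose(top, second, rtol=0.0, atol=1e-12):
            label = "unassigned"
            conf = 1.0
        else:
            label = MARKERS[order[0]]
            conf = float(top / second) if second > 0 else np.inf
        rows.append(
            {
                "til_id": cid,
                **{f"raw_{m}": raw[k] for k, m in enumerate(MARKERS)},
                **{f"norm_{m}": norm[k] for k, m in enumerate(MARKERS)},
                "label": label,
                "confidence": conf,
                "out_of_hull": out_flag,
            }
        )
    return pd.DataFrame(rows)


def cluster_subtype_composition(
    cluster_labels: pd.Series, subtype_calls: pd.DataFrame, n_clusters: int = 8
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cluster x subtype composition table.

    Parameters
    ----------
    cluster_labels
        Series mapping til_id -> cluster label in 1..n_clusters.
    subtype_calls
        Output of :func:`quantify_subtype` (til_id, label).

    Returns
    -------
    (percentages, counts)
        ``percentages``: rows are clusters, columns CD4/CD8/CD20 summing
        to 100 over assigned cells (plus an ``n_unassigned`` column and a
        ``flagged_empty`` marker for clusters without assigned cells).
        ``counts``: raw contingency matrix suitable for chord-diagram
        export.
    """
    calls = subtype_calls.set_index("til_id")["label"]
    counts = pd.DataFrame(
        0, index=[f"C{j}" for j in range(1, n_clusters + 1)], columns=list(MARKERS)
    )
    unassigned = pd.Series(0, index=counts.index)
    for til_id, cl in cluster_labels.items():
        lab = calls.get(til_id)
        if lab is None:
            continue
        row = f"C{int(cl)}"
        if lab == "unassigned":
            unassigned[row] += 1
        else:
            counts.loc[row, lab] += 1
    totals = counts.sum(axis=1)
    pct = counts.div(totals.replace(0, np.nan), axis=0) * 100.0
    pct = pct.fillna(0.0)
    pct["n_unassigned"] = unassigned
    pct["flagged_empty"] = totals == 0
    return pct, counts
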