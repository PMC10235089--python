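"""Macenko stain normalization for H&E tiles.

Scanner- and lab-dependent color variation is removed by estimating
each tile's hematoxylin/eosin stain vectors in optical-density space
(SVD plane of tissue pixels, extreme-angle heuristic), then remapping
the tile's stain concentrations onto a reference stain profile.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from skimage.color import rgb_from_hed

_IO = 255.0
_OD_BACKGROUND = 0.15  # pixels below this OD magnitude are background
_ALPHA = 1.0           # percentile for extreme stain angles
_CONC_PCT = 99.0


class InsufficientTissueError(ValueError):
    """Tile contains too few tissue pixels for stain estimation."""


def _standard_he_profile() -> "StainProfile":
    # standard H&E optical-density vectors (fixed-matrix deconvolution
    # convention), used as the fallback reference
    m = rgb_from_hed[:2]  # rows: H, E in OD space
    m = m / np.linalg.norm(m, axis=1, keepdims=True)
    return StainProfile(stain_vectors=m, max_concentrations=np.array([1.0, 1.0]))


@dataclasses.dataclass
class StainProfile:
    """Reference stain basis: 2x3 unit OD vectors (H, E) + scaling."""

    stain_vectors: np.ndarray       # (2, 3), rows unit-norm
    max_concentrations: np.ndarray  # (2,), 99th-percentile concentrations


def _to_od(image: np.ndarray) -> np.ndarray:
    return -np.log((image.astype(float) + 1.0) / (_IO + 1.0))


def estimate_stain_profile(image: np.ndarray, min_tissue_frac: float = 0.01) -> StainProfile:
    """Estimate the two dominant stain vectors of an RGB tile.

    Tissue pixels (optical density above threshold) are projected on
    the plane of the top-2 right singular vectors of the OD cloud; the
    stain vectors are the directions at the extreme (1st / 99th
    percentile) angles within that plane, ordered so the first row is
    the more hematoxylin-like (blue-heavy) stain.
    """
    od = _to_od(image.reshape(-1, 3))
    tissue = od[np.linalg.norm(od, axis=1) > _OD_BACKGROUND]
    if len(tissue) < min_tissue_frac * image.shape[0] * image.shape[1]:
        raise InsufficientTissueError(
            f"only {len(tissue)} tissue pixels; below {min_tissue_frac:.0%} of tile"
        )
    _, _, vt = np.linalg.svd(tissue - tissue.mean(axis=0), full_matrices=False)
    plane = vt[:2].copy()  # (2, 3)
    # orient the first plane axis into the OD cone so angles stay within
    # (-pi/2, pi/2) and the percentile extremes cannot wrap around +-pi
    if (tissue @ plane[0]).mean() < 0:
        plane[0] = -plane[0]
    proj = tissue @ plane.T
    angles = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(angles, [_ALPHA, 100 - _ALPHA])
    v1 = np.cos(lo) * plane[0] + np.sin(lo) * plane[1]
    v2 = np.cos(hi) * plane[0] + np.sin(hi) * plane[1]
    # OD vectors must point into absorption (positive octant dominant)
    if v1.sum() < 0:
        v1 = -v1
    if v2.sum() < 0:
        v2 = -v2
    # hematoxylin absorbs more red/green relative to blue
    stains = np.vstack([v1, v2])
    if stains[0, 2] / (np.abs(stains[0]).sum()) < stains[1, 2] / (np.abs(stains[1]).sum()):
        stains = stains[::-1]
    stains = stains / np.linalg.norm(stains, axis=1, keepdims=True)
    conc = np.linalg.lstsq(stains.T, od.T, rcond=None)[0]
    maxc = np.percentile(np.maximum(conc, 0), _CONC_PCT, axis=1)
    maxc = np.maximum(maxc, 1e-6)
    return StainProfile(stain_vectors=stains, max_concentrations=maxc)


def macenko_normalize(
    image: np.ndarray,
    reference: StainProfile | None = None,
    min_tissue_frac: float = 0.01,
) -> np.ndarray:
    """Remap an 8-bit RGB tile onto a reference stain profile.

    The tile's own stain vectors and concentration scale are estimated
    (:func:`estimate_stain_profile`), concentrations are rescaled to
    the reference's concentration range, and the image is rebuilt from
    the reference stain vectors.  With ``reference=None`` the standard
    H&E optical-density basis is used.

    Raises
    ------
    InsufficientTissueError
        If fewer than ``min_tissue_frac`` of pixels carry tissue.
    """
    if image.dtype != np.uint8:
        raise ValueError("expected an 8-bit RGB tile")
    ref = reference if reference is not None else _standard_he_profile()
    own = estimate_stain_profile(image, min_tissue_frac=min_tissue_frac)
    h, w, _ = image.shape
    od = _to_od(image.reshape(-1, 3))
    # concentrations are not clipped: pixels slightly outside the estimated
    # stain cone keep their (small) negative coefficients, so remapping onto
    # the tile's own profile is lossless
    conc = np.linalg.lstsq(own.stain_vectors.T, od.T, rcond=None)[0]  # (2, N)
    scale = ref.max_concentrations / own.max_concentrations
    conc = conc * scale[:, None]
    od_new = (ref.stain_vectors.T @ conc).T  # (N, 3)
    out = (_IO + 1.0) * np.exp(-od_new) - 1.0
    return np.clip(out, 0, 255).astype(np.uint8).reshape(h, w, 3)
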