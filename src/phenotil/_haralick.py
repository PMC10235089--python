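"""Gray-level co-occurrence (Haralick) texture statistics.

Twelve statistics are computed from the normalized co-occurrence matrix
of an 8-bit grayscale patch, quantized to a small number of gray levels,
at pixel distance 1, averaged over the four principal directions.  The
names follow the classical texture-feature catalog: angular second
moment, contrast, correlation, sum-of-squares variance, inverse
difference moment, sum average, sum variance, sum entropy, entropy,
difference variance, difference entropy and the first information
measure of correlation.
"""

from __future__ import annotations

import numpy as np
from skimage.feature import graycomatrix

from .cellmap import HARALICK_STATS

_EPS = 1e-12
_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)


def _stats_from_glcm(p: np.ndarray) -> np.ndarray:
    """Compute the 12 statistics from one normalized GLCM ``p`` (L x L)."""
    L = p.shape[0]
    i = np.arange(L, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")

    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = (i * px).sum()
    mu_y = (i * py).sum()
    sd_x = np.sqrt(((i - mu_x) ** 2 * px).sum())
    sd_y = np.sqrt(((i - mu_y) ** 2 * py).sum())

    # distributions of i+j (range 0..2L-2) and |i-j| (range 0..L-1)
    p_sum = np.zeros(2 * L - 1)
    np.add.at(p_sum, (ii + jj).astype(int).ravel(), p.ravel())
    p_diff = np.zeros(L)
    np.add.at(p_diff, np.abs(ii - jj).astype(int).ravel(), p.ravel())

    asm = (p**2).sum()
    contrast = ((ii - jj) ** 2 * p).sum()
    if sd_x * sd_y > _EPS:
        correlation = (((ii - mu_x) * (jj - mu_y) * p).sum()) / (sd_x * sd_y)
    else:
        correlation = 1.0  # constant patch: perfectly correlated by convention
    variance = ((ii - mu_x) ** 2 * p).sum()
    idm = (p / (1.0 + (ii - jj) ** 2)).sum()

    k_sum = np.arange(2 * L - 1, dtype=float)
    sum_average = (k_sum * p_sum).sum()
    sum_variance = ((k_sum - sum_average) ** 2 * p_sum).sum()
    sum_entropy = -(p_sum * np.log2(p_sum + _EPS))[p_sum > 0].sum()

    entropy = -(p * np.log2(p + _EPS))[p > 0].sum()

    k_diff = np.arange(L, dtype=float)
    diff_mean = (k_diff * p_diff).sum()
    difference_variance = ((k_diff - diff_mean) ** 2 * p_diff).sum()
    difference_entropy = -(p_diff * np.log2(p_diff + _EPS))[p_diff > 0].sum()

    hx = -(px * np.log2(px + _EPS))[px > 0].sum()
    hy = -(py * np.log2(py + _EPS))[py > 0].sum()
    pxpy = np.outer(px, py)
    hxy1 = -(p * np.log2(pxpy + _EPS)).sum()
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > _EPS else 0.0

    return np.array(
        [
            asm,
            contrast,
            correlation,
            variance,
            idm,
            sum_average,
            sum_variance,
            sum_entropy,
            entropy,
            difference_variance,
            difference_entropy,
            imc1,
        ]
    )


def haralick_features(patch: np.ndarray, levels: int = 32) -> np.ndarray:
    """12 co-occurrence statistics of an 8-bit grayscale patch.

    The patch is quantized to ``levels`` gray bins; co-occurrence is
    taken at distance 1 over the four principal directions and the
    statistics are averaged across directions.  Patches too small to
    form any pixel pair return the constant-patch convention (ASM 1,
    correlation 1, entropies and contrasts 0).

    Parameters
    ----------
    patch
        2-D uint8 (or castable) array; typically a nucleus bounding box.
    levels
        Number of quantization bins.

    Returns
    -------
    numpy.ndarray
        Length-12 vector ordered as :data:`phenotil.cellmap.HARALICK_STATS`.
    """
    patch = np.asarray(patch)
    if patch.ndim != 2:
        raise ValueError("patch must be 2-D grayscale")
    if patch.size == 0 or min(patch.shape) < 1 or patch.size < 2:
        return _stats_from_glcm(np.array([[1.0]]))
    q = (patch.astype(np.uint16) * levels // 256).astype(np.uint8)
    glcm = graycomatrix(
        q, distances=[1], angles=list(_ANGLES), levels=levels, symmetric=True, normed=False
    ).astype(float)
    out = np.zeros(len(HARALICK_STATS))
    n_used = 0
    for a in range(glcm.shape[3]):
        g = glcm[:, :, 0, a]
        tot = g.sum()
        if tot == 0:  # degenerate direction (e.g. 1-pixel-wide patch)
            continue
        out += _stats_from_glcm(g / tot)
        n_used += 1
    if n_used == 0:
        return _stats_from_glcm(np.array([[1.0]]))
    return out / n_used
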