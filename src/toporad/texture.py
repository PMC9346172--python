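"""The fixed 54-feature histogram + texture catalogue.

Each derived image (original slice/volume, wavelet subband, or Betti-number
map) contributes exactly 54 features: 10 first-order histogram statistics,
22 gray-level co-occurrence (GLCM), 11 gray-level run-length (GLRLM) and 11
gray-level size-zone (GLSZM) features.  Texture features are computed after
in-ROI min-max quantization to a fixed number of gray levels (default 32);
the same machinery handles 2D slices/maps and 3D volumes (4 vs 13 unique
co-occurrence/run directions, 8- vs 26-connected zones).

Conventions (documented because competing ones exist in the literature):

* GLCM: symmetric, distance 1; the co-occurrence matrices of all directions
  are summed before normalization ("merged" aggregation).
* GLRLM: runs from all directions accumulate into one matrix; the run
  percentage divides by (ROI voxels x number of directions).
* Histogram entropy is the Shannon entropy (base 2) of the empirical
  distribution of distinct values.
* Degenerate 0/0 cases (constant ROI) define Skewness, Kurtosis and
  Correlation as 0.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from scipy import ndimage

__all__ = [
    "HISTOGRAM_NAMES",
    "GLCM_NAMES",
    "GLRLM_NAMES",
    "GLSZM_NAMES",
    "CATALOGUE_SIZE",
    "histogram_features",
    "texture_features",
    "quantize",
    "glcm_matrix",
    "glrlm_matrix",
    "glszm_matrix",
]

HISTOGRAM_NAMES = (
    "Mean",
    "Variance",
    "Skewness",
    "Kurtosis",
    "Energy",
    "Entropy",
    "MeanAbsoluteDeviation",
    "Median",
    "Min",
    "Max",
)

GLCM_NAMES = (
    "Autocorrelation",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "Dissimilarity",
    "JointEnergy",
    "JointEntropy",
    "MaximumProbability",
    "InverseDifference",
    "InverseDifferenceMoment",
    "InverseVariance",
    "IMC1",
    "IMC2",
    "SumAverage",
    "SumEntropy",
    "SumVariance",
    "SumSquares",
)

GLRLM_NAMES = (
    "ShortRunEmphasis",
    "LongRunEmphasis",
    "GrayLevelNonUniformity",
    "RunLengthNonUniformity",
    "RunPercentage",
    "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis",
    "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)

GLSZM_NAMES = (
    "SmallAreaEmphasis",
    "LargeAreaEmphasis",
    "GrayLevelNonUniformity",
    "ZoneSizeNonUniformity",
    "ZonePercentage",
    "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
)

CATALOGUE_SIZE = len(HISTOGRAM_NAMES) + len(GLCM_NAMES) + len(GLRLM_NAMES) + len(GLSZM_NAMES)
assert CATALOGUE_SIZE == 54


# ---------------------------------------------------------------------------
# first-order statistics


def histogram_features(values: np.ndarray) -> dict[str, float]:
    """The 10 first-order statistics of the in-ROI value list.

    Energy is the raw sum of squares; MeanAbsoluteDeviation the mean
    absolute deviation from the mean; Entropy the base-2 Shannon entropy of
    the empirical value distribution.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty ROI")
    mean = float(v.mean())
    var = float(v.var())
    sd = np.sqrt(var)
    if sd > 0:
        skew = float(((v - mean) ** 3).mean() / sd**3)
        kurt = float(((v - mean) ** 4).mean() / sd**4 - 3.0)
    else:
        skew = kurt = 0.0
    _, counts = np.unique(v, return_counts=True)
    p = counts / v.size
    entropy = float(-(p * np.log2(p)).sum())
    return {
        "Mean": mean,
        "Variance": var,
        "Skewness": skew,
        "Kurtosis": kurt,
        "Energy": float((v**2).sum()),
        "Entropy": entropy,
        "MeanAbsoluteDeviation": float(np.abs(v - mean).mean()),
        "Median": float(np.median(v)),
        "Min": float(v.min()),
        "Max": float(v.max()),
    }


# ---------------------------------------------------------------------------
# quantization and direction sets


def quantize(image: np.ndarray, roi: np.ndarray, levels: int) -> np.ndarray:
    """In-ROI min-max quantization to integer levels 1..levels (0 outside)."""
    if levels < 2:
        raise ValueError("levels must be >= 2")
    image = np.asarray(image, dtype=float)
    roi = np.asarray(roi).astype(bool)
    vals = image[roi]
    if vals.size == 0:
        raise ValueError("empty ROI")
    lo, hi = float(vals.min()), float(vals.max())
    q = np.zeros(image.shape, dtype=np.int32)
    if hi == lo:
        q[roi] = 1
    else:
        bins = np.minimum(((image - lo) / (hi - lo) * levels).astype(np.int32), levels - 1)
        q[roi] = bins[roi] + 1
    return q


def directions(ndim: int) -> list[tuple[int, ...]]:
    """Unique unit-step offsets up to sign: 4 in 2D, 13 in 3D."""
    out = []
    for d in product((-1, 0, 1), repeat=ndim):
        if d > (0,) * ndim:  # lexicographically positive half
            out.append(d)
    return out


def _shift_slices(d):
    src = tuple(slice(None, -1) if s == 1 else slice(1, None) if s == -1 else slice(None) for s in d)
    dst = tuple(slice(1, None) if s == 1 else slice(None, -1) if s == -1 else slice(None) for s in d)
    return src, dst


# ---------------------------------------------------------------------------
# GLCM


def glcm_matrix(q: np.ndarray, roi: np.ndarray, levels: int) -> np.ndarray:
    """Symmetric distance-1 co-occurrence matrix summed over all directions,
    normalized to a probability matrix (all-zero if no valid pairs)."""
    roi = np.asarray(roi).astype(bool)
    P = np.zeros((levels, levels), dtype=float)
    for d in directions(q.ndim):
        src, dst = _shift_slices(d)
        a, b = q[src], q[dst]
        m = roi[src] & roi[dst]
        np.add.at(P, (a[m] - 1, b[m] - 1), 1.0)
    P = P + P.T
    total = P.sum()
    return P / total if total > 0 else P


def _glcm_features(P: np.ndarray) -> dict[str, float]:
    Ng = P.shape[0]
    i = np.arange(1, Ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mux = float((i * px).sum())
    muy = float((i * py).sum())
    sx = float(np.sqrt(((i - mux) ** 2 * px).sum()))
    sy = float(np.sqrt(((i - muy) ** 2 * py).sum()))

    k_diff = np.arange(Ng)
    p_diff = np.zeros(Ng)
    np.add.at(p_diff, np.abs(ii - jj).ravel(), P.ravel())
    k_sum = np.arange(2, 2 * Ng + 1)
    p_sum = np.zeros(2 * Ng - 1)
    np.add.at(p_sum, (ii + jj - 2).ravel(), P.ravel())

    def _ent(p):
        p = p[p > 0]
        return float(-(p * np.log2(p)).sum()) if p.size else 0.0

    diff_avg = float((k_diff * p_diff).sum())
    sum_avg = float((k_sum * p_sum).sum())
    hxy = _ent(P.ravel())
    hx, hy = _ent(px), _ent(py)
    outer = np.outer(px, py)
    with np.errstate(divide="ignore"):
        log_outer = np.where(outer > 0, np.log2(np.where(outer > 0, outer, 1.0)), 0.0)
    hxy1 = float(-(P * log_outer).sum())
    hxy2 = _ent(outer.ravel())
    denom = max(hx, hy)
    imc1 = (hxy - hxy1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
    corr = ((ii * jj * P).sum() - mux * muy) / (sx * sy) if sx > 0 and sy > 0 else 0.0
    off = ii != jj
    inv_var = float((P[off] / (ii[off] - jj[off]) ** 2).sum())

    return {
        "Autocorrelation": float((ii * jj * P).sum()),
        "ClusterProminence": float(((ii + jj - mux - muy) ** 4 * P).sum()),
        "ClusterShade": float(((ii + jj - mux - muy) ** 3 * P).sum()),
        "ClusterTendency": float(((ii + jj - mux - muy) ** 2 * P).sum()),
        "Contrast": float(((ii - jj) ** 2 * P).sum()),
        "Correlation": float(corr),
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": _ent(p_diff),
        "DifferenceVariance": float(((k_diff - diff_avg) ** 2 * p_diff).sum()),
        "Dissimilarity": float((np.abs(ii - jj) * P).sum()),
        "JointEnergy": float((P**2).sum()),
        "JointEntropy": hxy,
        "MaximumProbability": float(P.max()),
        "InverseDifference": float((P / (1.0 + np.abs(ii - jj))).sum()),
        "InverseDifferenceMoment": float((P / (1.0 + (ii - jj) ** 2)).sum()),
        "InverseVariance": inv_var,
        "IMC1": float(imc1),
        "IMC2": imc2,
        "SumAverage": sum_avg,
        "SumEntropy": _ent(p_sum),
        "SumVariance": float(((k_sum - sum_avg) ** 2 * p_sum).sum()),
        "SumSquares": float(((ii - mux) ** 2 * P).sum()),
    }


# ---------------------------------------------------------------------------
# GLRLM


def glrlm_matrix(q: np.ndarray, roi: np.ndarray, levels: int) -> np.ndarray:
    """Run-length matrix R[g, l-1] merged over all directions.

    A run is a maximal straight sequence of in-ROI voxels sharing one gray
    level; out-of-ROI voxels break runs.
    """
    roi = np.asarray(roi).astype(bool)
    idx = np.argwhere(roi)
    if idx.size == 0:
        raise ValueError("empty ROI")
    lev = q[roi]
    max_run = int(max(q.shape))
    R = np.zeros((levels, max_run), dtype=float)
    for d in directions(q.ndim):
        dv = np.array(d)
        ax = int(np.nonzero(dv)[0][0])  # first nonzero axis; dv[ax] == 1
        t = idx[:, ax]
        base = idx - np.outer(t, dv)
        order = np.lexsort((t, *base.T[::-1]))
        t_o = t[order]
        base_o = base[order]
        lev_o = lev[order]
        new_run = np.ones(len(t_o), dtype=bool)
        if len(t_o) > 1:
            same_line = (base_o[1:] == base_o[:-1]).all(axis=1) & (t_o[1:] == t_o[:-1] + 1)
            new_run[1:] = ~(same_line & (lev_o[1:] == lev_o[:-1]))
        starts = np.flatnonzero(new_run)
        lengths = np.diff(np.append(starts, len(t_o)))
        np.add.at(R, (lev_o[starts] - 1, lengths - 1), 1.0)
    return R


def _rl_features(R: np.ndarray, n_voxels: int, n_dirs: int, names, pct_name: str) -> dict:
    """Shared run-length / size-zone feature formulas."""
    Nr = R.sum()
    g = np.arange(1, R.shape[0] + 1)[:, None]
    l = np.arange(1, R.shape[1] + 1)[None, :]
    if Nr == 0:
        return {name: 0.0 for name in names}
    rg = R.sum(axis=1)
    rl = R.sum(axis=0)
    feats = {
        names[0]: float((R / l**2).sum() / Nr),
        names[1]: float((R * l**2).sum() / Nr),
        names[2]: float((rg**2).sum() / Nr),
        names[3]: float((rl**2).sum() / Nr),
        pct_name: float(Nr / (n_voxels * n_dirs)),
        names[5]: float((R / g**2).sum() / Nr),
        names[6]: float((R * g**2).sum() / Nr),
        names[7]: float((R / (g**2 * l**2)).sum() / Nr),
        names[8]: float((R * g**2 / l**2).sum() / Nr),
        names[9]: float((R * l**2 / g**2).sum() / Nr),
        names[10]: float((R * g**2 * l**2).sum() / Nr),
    }
    return feats


# ---------------------------------------------------------------------------
# GLSZM


def glszm_matrix(q: np.ndarray, roi: np.ndarray, levels: int) -> np.ndarray:
    """Size-zone matrix Z[g, s-1]: zones are fully-connected (8/26) regions
    of equal gray level inside the ROI."""
    roi = np.asarray(roi).astype(bool)
    structure = np.ones((3,) * q.ndim, dtype=int)
    max_size = int(roi.sum())
    Z = np.zeros((levels, max_size), dtype=float)
    for lvl in np.unique(q[roi]):
        lab, n = ndimage.label((q == lvl) & roi, structure=structure)
        if n == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        np.add.at(Z, (int(lvl) - 1, sizes - 1), 1.0)
    return Z


# ---------------------------------------------------------------------------
# public entry point


def texture_features(image: np.ndarray, roi: np.ndarray, levels: int = 32) -> dict[str, float]:
    """All 44 texture features of one image restricted to a ROI.

    Works for 2D and 3D arrays; the ROI must contain at least 2 voxels.
    Feature names are prefixed GLCM_/GLRLM_/GLSZM_.
    """
    image = np.asarray(image, dtype=float)
    roi = np.asarray(roi).astype(bool)
    if image.shape != roi.shape:
        raise ValueError("image and ROI shapes differ")
    n_vox = int(roi.sum())
    if n_vox < 2:
        raise ValueError("ROI must contain at least 2 voxels")
    q = quantize(image, roi, levels)
    n_dirs = len(directions(image.ndim))

    out: dict[str, float] = {}
    P = glcm_matrix(q, roi, levels)
    for name, val in _glcm_features(P).items():
        out[f"GLCM_{name}"] = val
    R = glrlm_matrix(q, roi, levels)
    rl = _rl_features(R, n_vox, n_dirs, GLRLM_NAMES, "RunPercentage")
    for name in GLRLM_NAMES:
        out[f"GLRLM_{name}"] = rl[name]
    Z = glszm_matrix(q, roi, levels)
    sz = _rl_features(Z, n_vox, 1, GLSZM_NAMES, "ZonePercentage")
    for name in GLSZM_NAMES:
        out[f"GLSZM_{name}"] = sz[name]
    return out
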