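"""Feature-vector assembly: wavelet features (WF), Betti-map features
(BF/iBF) and their combinations (BWF/iBWF).

Column names encode provenance as ``Family_Name_Source[_thT]`` where Family
is Histogram/GLCM/GLRLM/GLSZM, Source identifies the derived image (CT,
LLL..HHH wavelet subbands, CTslice for the requantized max-GTV slice, or a
Betti map B0/B1/B1B0 with an i prefix for inverted polarity) and T is the
binarization threshold for map-derived features, e.g.
``Histogram_Energy_iB0_th235``.

Bookkeeping under the default catalogue (54 features per image):

* WF: 9 images (original + 8 subbands) x 54 = 486 columns.
* BF: 3 map types x 256 thresholds x 54 + 54 slice features = 41 526.
* iBF: BF plus the inverted-polarity 3 x 256 x 54 = 82 998 columns.
"""

from __future__ import annotations

import re
from typing import Sequence

import numpy as np
import pandas as pd
import pywt
from sklearn.base import BaseEstimator, TransformerMixin

from .betti import BettiMapConfig, build_map_stack, map_roi_from_mask, MAP_TYPES
from .texture import histogram_features, texture_features, CATALOGUE_SIZE

__all__ = [
    "WAVELET_SUBBANDS",
    "wavelet_decompose",
    "image_features",
    "extract_wf",
    "extract_bf",
    "extract_ibf",
    "combine_features",
    "parse_feature_name",
    "WaveletFeatureExtractor",
    "BettiFeatureExtractor",
]

#: subband order: L/H per spatial axis (x, y, z)
WAVELET_SUBBANDS = ("LLL", "HLL", "LHL", "LLH", "HHL", "HLH", "LHH", "HHH")

_NAME_RE = re.compile(
    r"^(?P<family>Histogram|GLCM|GLRLM|GLSZM)_(?P<name>[A-Za-z0-9]+)_(?P<source>i?[A-Za-z0-9]+?)(?:_th(?P<threshold>\d{1,3}))?$"
)


def parse_feature_name(column: str) -> dict:
    """Split a column name back into (family, name, source, threshold)."""
    m = _NAME_RE.match(column)
    if m is None:
        raise ValueError(f"unparseable feature name: {column!r}")
    d = m.groupdict()
    d["threshold"] = int(d["threshold"]) if d["threshold"] is not None else None
    return d


def wavelet_decompose(
    volume: np.ndarray, wavelet: str = "coif1", *, upsample: bool = True
) -> dict[str, np.ndarray]:
    """One-level 3D separable wavelet decomposition into 8 subbands.

    Uses periodization boundary handling (the filter bank is then
    orthogonal, so subband energies sum to the input energy).  With
    ``upsample=True`` each half-size subband is nearest-neighbor upsampled
    and cropped back to the input shape so the GTV mask applies directly.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 3:
        raise ValueError("expected a 3D volume")
    filt_len = pywt.Wavelet(wavelet).dec_len
    if min(volume.shape) < filt_len:
        raise ValueError(f"volume sides must be >= filter length ({filt_len})")
    coeffs = pywt.dwtn(volume, wavelet, mode="periodization")
    out = {}
    for label in WAVELET_SUBBANDS:
        key = "".join("a" if c == "L" else "d" for c in label)
        band = coeffs[key]
        if upsample:
            for ax in range(3):
                band = np.repeat(band, 2, axis=ax)
            band = band[tuple(slice(0, n) for n in volume.shape)]
        out[label] = band
    return out


def image_features(
    image: np.ndarray, roi: np.ndarray, source: str, *, levels: int = 32, threshold: int | None = None
) -> dict[str, float]:
    """The full 54-feature catalogue of one image, named with provenance."""
    suffix = f"_{source}" + (f"_th{threshold}" if threshold is not None else "")
    roi = np.asarray(roi).astype(bool)
    out = {}
    for name, val in histogram_features(np.asarray(image, dtype=float)[roi]).items():
        out[f"Histogram_{name}{suffix}"] = val
    for name, val in texture_features(image, roi, levels).items():
        out[f"{name}{suffix}"] = val
    assert len(out) == CATALOGUE_SIZE
    return out


def extract_wf(volume: np.ndarray, mask: np.ndarray, *, levels: int = 32) -> pd.Series:
    """Wavelet feature vector: original volume plus 8 coif1 subbands.

    486 columns under the default catalogue (9 images x 54).
    """
    feats: dict[str, float] = {}
    feats.update(image_features(volume, mask, "CT", levels=levels))
    for label, band in wavelet_decompose(volume).items():
        feats.update(image_features(band, mask, label, levels=levels))
    return pd.Series(feats)


def _map_stack_features(
    slice8: np.ndarray,
    mask2d: np.ndarray,
    cfg: BettiMapConfig,
    prefix: str,
    *,
    levels: int = 32,
) -> dict[str, float]:
    """54 features per (threshold, map type); map ROI = windows whose kernel
    center lies inside the GTV."""
    roi = map_roi_from_mask(mask2d, cfg)
    if roi.sum() < 2:
        raise ValueError("GTV too small relative to the kernel: map ROI < 2 pixels")
    stack = build_map_stack(slice8, cfg)
    feats: dict[str, float] = {}
    for t in cfg.thresholds:
        for map_type in MAP_TYPES:
            src = prefix + map_type.replace("B1B0", "B1B0")
            feats.update(
                image_features(stack.maps[t][map_type], roi, src, levels=levels, threshold=t)
            )
    return feats


def extract_bf(
    slice8: np.ndarray, mask2d: np.ndarray, cfg: BettiMapConfig | None = None, *, levels: int = 32
) -> pd.Series:
    """Original-polarity Betti-map feature vector plus requantized-slice
    features (41 526 columns at the full 256 thresholds)."""
    cfg = cfg or BettiMapConfig()
    if cfg.polarity != "original":
        raise ValueError("extract_bf uses original polarity")
    if np.asarray(mask2d).sum() < 2:
        raise ValueError("empty or degenerate GTV slice mask")
    feats = image_features(slice8, np.asarray(mask2d).astype(bool), "CTslice", levels=levels)
    feats.update(_map_stack_features(slice8, mask2d, cfg, "", levels=levels))
    return pd.Series(feats)


def extract_ibf(
    slice8: np.ndarray, mask2d: np.ndarray, cfg: BettiMapConfig | None = None, *, levels: int = 32
) -> pd.Series:
    """BF columns plus inverted-polarity map features (82 998 at full scale)."""
    cfg = cfg or BettiMapConfig()
    bf = extract_bf(slice8, mask2d, cfg, levels=levels)
    inv_cfg = BettiMapConfig(cfg.kernel_px, cfg.shift_px, cfg.thresholds, "inverted")
    inv = _map_stack_features(slice8, mask2d, inv_cfg, "i", levels=levels)
    return pd.concat([bf, pd.Series(inv)])


def combine_features(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Column-wise concatenation of two feature tables over the same patients."""
    if len(b.columns) == 0:
        return a.copy()
    if not a.index.equals(b.index):
        raise ValueError("patient rows differ between tables")
    clash = a.columns.intersection(b.columns)
    if len(clash) > 0:
        raise ValueError(f"column name collision: {list(clash[:5])}")
    return pd.concat([a, b], axis=1)


# ---------------------------------------------------------------------------
# sklearn-style transformers: X is a sequence of patient inputs, output a
# patients x features DataFrame


class WaveletFeatureExtractor(BaseEstimator, TransformerMixin):
    """Transformer computing WF vectors from (volume, mask) pairs.

    ``transform(X)`` expects a sequence of ``(values3d, mask3d)`` arrays
    (preprocessed, requantized volumes) and returns a DataFrame with 486
    columns under the default catalogue.
    """

    def __init__(self, levels: int = 32):
        self.levels = levels

    def fit(self, X, y=None):
        return self

    def transform(self, X, ids: Sequence[str] | None = None) -> pd.DataFrame:
        rows = [extract_wf(vol, mask, levels=self.levels) for vol, mask in X]
        index = list(ids) if ids is not None else list(range(len(rows)))
        return pd.DataFrame(rows, index=index)


class BettiFeatureExtractor(BaseEstimator, TransformerMixin):
    """Transformer computing BF or iBF vectors from (slice8, mask2d) pairs."""

    def __init__(
        self,
        family: str = "ibf",
        kernel_px: int = 9,
        shift_px: int = 3,
        thresholds: Sequence[int] | None = None,
        levels: int = 32,
    ):
        self.family = family
        self.kernel_px = kernel_px
        self.shift_px = shift_px
        self.thresholds = thresholds
        self.levels = levels

    def _config(self) -> BettiMapConfig:
        ts = tuple(self.thresholds) if self.thresholds is not None else tuple(range(256))
        return BettiMapConfig(self.kernel_px, self.shift_px, ts, "original")

    def fit(self, X, y=None):
        return self

    def transform(self, X, ids: Sequence[str] | None = None) -> pd.DataFrame:
        if self.family not in ("bf", "ibf"):
            raise ValueError("family must be 'bf' or 'ibf'")
        extractor = extract_bf if self.family == "bf" else extract_ibf
        cfg = self._config()
        rows = [extractor(sl, mask, cfg, levels=self.levels) for sl, mask in X]
        index = list(ids) if ids is not None else list(range(len(rows)))
        return pd.DataFrame(rows, index=index)
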