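"""Betti-number maps of thresholded 8-bit axial slices.

A slice is binarized at every gray-level threshold t (pixel >= t -> 1);
a K x K kernel steps across the slice with stride S and, per window, the
number of 8-connected foreground components (B0) and of 4-connected
enclosed background components, i.e. holes (B1), is recorded.  Doing this
for the binary image gives the original map; doing it for the complemented
image gives the inverted map (iB0/iB1), which responds to cavities even
when they are larger than the kernel.  A third map holds the B1/B0 ratio
(0 where B0 = 0).

Implementation note: windows are counted in a single pass per threshold by
tiling all windows onto one canvas with a one-pixel separator and labelling
the canvas once; the separator (background for B0, foreground for B1)
prevents components from bridging windows, so per-window counts equal the
brute-force per-window labelling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

__all__ = [
    "BettiMapConfig",
    "BettiMapStack",
    "binarize",
    "invert_binary",
    "count_b0",
    "count_b1",
    "betti_map",
    "build_map_stack",
    "map_roi_from_mask",
]

_EIGHT = np.ones((3, 3), dtype=int)
_FOUR = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=int)

MAP_TYPES = ("B0", "B1", "B1B0")


@dataclass(frozen=True)
class BettiMapConfig:
    """Kernel size K (odd), stride S, thresholds and map polarity."""

    kernel_px: int = 9
    shift_px: int = 3
    thresholds: tuple[int, ...] = tuple(range(256))
    polarity: str = "original"

    def __post_init__(self) -> None:
        if self.kernel_px < 1 or self.kernel_px % 2 == 0:
            raise ValueError("kernel_px must be a positive odd integer")
        if self.shift_px < 1:
            raise ValueError("shift_px must be >= 1")
        ts = tuple(int(t) for t in self.thresholds)
        if any(t < 0 or t > 255 for t in ts):
            raise ValueError("thresholds must lie in [0, 255]")
        object.__setattr__(self, "thresholds", ts)
        if self.polarity not in ("original", "inverted"):
            raise ValueError("polarity must be 'original' or 'inverted'")


@dataclass(frozen=True)
class BettiMapStack:
    """Per-threshold B0/B1/ratio maps for one polarity plus metadata."""

    maps: dict[int, dict[str, np.ndarray]]
    config: BettiMapConfig
    source: str = ""

    @property
    def n_maps(self) -> int:
        return sum(len(v) for v in self.maps.values())

    def save(self, path: str | Path) -> None:
        """Persist as a compressed array archive with a JSON sidecar."""
        path = Path(path)
        arrays = {
            f"t{t:03d}_{k}": arr for t, grids in self.maps.items() for k, arr in grids.items()
        }
        np.savez_compressed(path.with_suffix(".npz"), **arrays)
        meta = {
            "kernel_px": self.config.kernel_px,
            "shift_px": self.config.shift_px,
            "thresholds": list(self.config.thresholds),
            "polarity": self.config.polarity,
            "source": self.source,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def binarize(slice8: np.ndarray, t: int) -> np.ndarray:
    """Threshold inclusively: pixel >= t -> 1 else 0."""
    if not 0 <= t <= 255:
        raise ValueError("threshold must be in [0, 255]")
    return (np.asarray(slice8) >= t).astype(np.uint8)


def invert_binary(b: np.ndarray) -> np.ndarray:
    """Exact logical complement, conserving total pixel count."""
    b = np.asarray(b)
    if not np.all((b == 0) | (b == 1)):
        raise ValueError("input must be binary")
    return (1 - b).astype(np.uint8)


def count_b0(b: np.ndarray) -> int:
    """Number of 8-connected components of ones."""
    return int(ndimage.label(np.asarray(b), structure=_EIGHT)[1])


def count_b1(b: np.ndarray) -> int:
    """Number of holes: 4-connected zero components not touching the border."""
    b = np.asarray(b)
    lbl, n = ndimage.label(b == 0, structure=_FOUR)
    if n == 0:
        return 0
    border = np.concatenate([lbl[0, :], lbl[-1, :], lbl[:, 0], lbl[:, -1]])
    touching = np.unique(border[border > 0])
    return n - len(touching)


def _tile_windows(binar: np.ndarray, K: int, S: int, sep: int):
    """Arrange all fully-inside K x K windows on a canvas with a one-pixel
    separator of value ``sep``; returns (canvas, nI, nJ, pitch)."""
    H, W = binar.shape
    if K > min(H, W):
        raise ValueError(f"kernel ({K}) larger than slice side ({min(H, W)})")
    nI = (H - K) // S + 1
    nJ = (W - K) // S + 1
    win = sliding_window_view(binar, (K, K))[::S, ::S]  # (nI, nJ, K, K)
    P = K + 1
    big = np.full((nI, P, nJ, P), sep, dtype=np.uint8)
    big[:, :K, :, :K] = win.transpose(0, 2, 1, 3)
    return big.reshape(nI * P, nJ * P), nI, nJ, P


def _per_tile_label_counts(lbl: np.ndarray, n: int, nI: int, nJ: int, P: int,
                           keep: np.ndarray | None = None) -> np.ndarray:
    """Count distinct labels per tile; each label lives in exactly one tile."""
    counts = np.zeros((nI, nJ), dtype=int)
    if n == 0:
        return counts
    flat = lbl.ravel()
    _, first = np.unique(flat, return_index=True)
    labels = flat[first]
    sel = labels > 0
    if keep is not None:
        sel &= keep[labels]
    first = first[sel]
    rows, cols = np.divmod(first, lbl.shape[1])
    np.add.at(counts, (rows // P, cols // P), 1)
    return counts


def _window_counts(binar: np.ndarray, K: int, S: int) -> tuple[np.ndarray, np.ndarray]:
    """(B0 map, B1 map) over all fully-inside windows of a binary slice."""
    # B0: zero separator keeps 8-connected components inside their window
    canvas0, nI, nJ, P = _tile_windows(binar, K, S, sep=0)
    lbl0, n0 = ndimage.label(canvas0, structure=_EIGHT)
    b0 = _per_tile_label_counts(lbl0, n0, nI, nJ, P)

    # B1: ones separator keeps 4-connected zero regions inside their window;
    # zero regions touching the window's own border are background, not holes
    canvas1, _, _, _ = _tile_windows(binar, K, S, sep=1)
    lblz, nz = ndimage.label(canvas1 == 0, structure=_FOUR)
    if nz == 0:
        return b0, np.zeros((nI, nJ), dtype=int)
    border = np.zeros((nI, P, nJ, P), dtype=bool)
    border[:, 0, :, :K] = border[:, K - 1, :, :K] = True
    border[:, :K, :, 0] = border[:, :K, :, K - 1] = True
    border = border.reshape(nI * P, nJ * P)
    touching = np.unique(lblz[border & (lblz > 0)])
    keep = np.ones(nz + 1, dtype=bool)
    keep[0] = False
    keep[touching] = False
    b1 = _per_tile_label_counts(lblz, nz, nI, nJ, P, keep=keep)
    return b0, b1


def betti_map(
    slice8: np.ndarray, t: int, cfg: BettiMapConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """B0, B1 and B1/B0 maps of one slice at one threshold.

    Windows are anchored at (i*S, j*S) and must lie fully inside the slice,
    so the map shape is floor((H-K)/S)+1 x floor((W-K)/S)+1.
    """
    binar = binarize(slice8, t)
    if cfg.polarity == "inverted":
        binar = invert_binary(binar)
    b0, b1 = _window_counts(binar, cfg.kernel_px, cfg.shift_px)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(b0 > 0, b1 / np.maximum(b0, 1), 0.0)
    return b0, b1, ratio


def build_map_stack(slice8: np.ndarray, cfg: BettiMapConfig, source: str = "") -> BettiMapStack:
    """All three map types at every configured threshold for one polarity."""
    maps: dict[int, dict[str, np.ndarray]] = {}
    for t in cfg.thresholds:
        b0, b1, ratio = betti_map(slice8, t, cfg)
        maps[t] = {"B0": b0, "B1": b1, "B1B0": ratio}
    return BettiMapStack(maps, cfg, source)


def map_roi_from_mask(mask2d: np.ndarray, cfg: BettiMapConfig) -> np.ndarray:
    """Boolean map-grid ROI: True where the window's center pixel is in the GTV."""
    mask2d = np.asarray(mask2d).astype(bool)
    H, W = mask2d.shape
    K, S = cfg.kernel_px, cfg.shift_px
    if K > min(H, W):
        raise ValueError("kernel larger than slice")
    nI = (H - K) // S + 1
    nJ = (W - K) // S + 1
    ci = np.arange(nI) * S + K // 2
    cj = np.arange(nJ) * S + K // 2
    return mask2d[np.ix_(ci, cj)]
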