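"""Unfold scans into training units and fold predictions back into maps.

The 1D route unfolds a cube into independent pixel spectra. The 3D route
extracts one w×w×B patch per pixel (default 3×3), labeled by its central
pixel, so that a pixel is classified from its spatial neighbourhood. Border
pixels are handled by a configurable halo policy; the default zero-pads,
consistent with the zero padding already present in the scans, and keeps one
patch per pixel so folded segmentation maps stay complete.

Unfolding is exposed both as a lazy row-major iterator and as materialized
arrays; ``fold_predictions`` inverts it, keyed by pixel provenance so patch
order is irrelevant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .cube_io import HyperCube, LabelMap, ShapeMismatchError, SpectroCubeError


class PatchError(SpectroCubeError):
    pass


BORDER_POLICIES = ("zero", "reflect", "drop")


@dataclass
class PatchSet:
    """Materialized patches with provenance.

    patches : (n, w, w, B); labels : (n,) class codes; pixel_index : (n, 3)
    object array of (scan_id, row, col) triples. With window 1 the patches are
    single spectra and ``spectra`` gives them as (n, B).
    """

    patches: np.ndarray
    labels: np.ndarray
    pixel_index: np.ndarray
    window: int

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise PatchError("window must be odd and ≥ 1")
        n = self.patches.shape[0]
        if not (len(self.labels) == n and len(self.pixel_index) == n):
            raise PatchError("patches, labels, pixel_index lengths differ")

    def __len__(self) -> int:
        return self.patches.shape[0]

    @property
    def spectra(self) -> np.ndarray:
        return self.patches.reshape(len(self), -1) if self.window == 1 else \
            self.patches[:, self.window // 2, self.window // 2, :]


def _check_aligned(cube: HyperCube, labels: LabelMap) -> None:
    if cube.intensities.shape[:2] != labels.shape:
        raise ShapeMismatchError(
            f"cube grid {cube.intensities.shape[:2]} != labels {labels.shape}"
        )


def _padded(cube: HyperCube, half: int, border: str) -> np.ndarray:
    pad = ((half, half), (half, half), (0, 0))
    if border == "zero":
        return np.pad(cube.intensities, pad, mode="constant")
    if border == "reflect":
        return np.pad(cube.intensities, pad, mode="reflect")
    raise PatchError(f"unknown border policy {border!r}")


def iter_patches(
    cube: HyperCube,
    labels: LabelMap,
    window: int = 3,
    border: str = "zero",
) -> Iterator[tuple[np.ndarray, int, tuple[str, int, int]]]:
    """Lazy row-major patch stream: yields (patch, label, (scan_id, row, col))."""
    _check_aligned(cube, labels)
    h, w_, _ = cube.shape
    if window % 2 == 0:
        raise PatchError("window must be odd")
    if window > min(h, w_):
        raise PatchError(f"window {window} larger than grid {h}×{w_}")
    if border not in BORDER_POLICIES:
        raise PatchError(f"border must be one of {BORDER_POLICIES}")
    half = window // 2
    if border == "drop":
        rows = range(half, h - half)
        cols = range(half, w_ - half)
        arr = cube.intensities
        for r in rows:
            for c in cols:
                yield (
                    arr[r - half : r + half + 1, c - half : c + half + 1, :],
                    int(labels.labels[r, c]),
                    (cube.scan_id, r, c),
                )
        return
    padded = _padded(cube, half, border)
    for r in range(h):
        for c in range(w_):
            yield (
                padded[r : r + window, c : c + window, :],
                int(labels.labels[r, c]),
                (cube.scan_id, r, c),
            )


def extract_patches(
    cube: HyperCube,
    labels: LabelMap,
    window: int = 3,
    border: str = "zero",
) -> PatchSet:
    """One w×w×B patch per pixel, labeled by its central pixel.

    With border = zero|reflect, n = H×W; with drop, only interior pixels are
    kept.
    """
    _check_aligned(cube, labels)
    h, w_, b = cube.shape
    if window % 2 == 0:
        raise PatchError("window must be odd")
    if window > min(h, w_):
        raise PatchError(f"window {window} larger than grid {h}×{w_}")
    if border not in BORDER_POLICIES:
        raise PatchError(f"border must be one of {BORDER_POLICIES}")
    half = window // 2
    if border == "drop":
        src = cube.intensities
        view = np.lib.stride_tricks.sliding_window_view(src, (window, window), (0, 1))
        # view: (H-2h, W-2h, B, w, w) -> (n, w, w, B)
        patches = np.ascontiguousarray(view.transpose(0, 1, 3, 4, 2))
        rows, cols = np.mgrid[half : h - half, half : w_ - half]
    else:
        padded = _padded(cube, half, border)
        view = np.lib.stride_tricks.sliding_window_view(
            padded, (window, window), (0, 1)
        )
        patches = np.ascontiguousarray(view.transpose(0, 1, 3, 4, 2))
        rows, cols = np.mgrid[0:h, 0:w_]
    rows = rows.ravel()
    cols = cols.ravel()
    n = rows.size
    patches = patches.reshape(n, window, window, b)
    lab = labels.labels[rows, cols].astype(np.int64)
    idx = np.empty((n, 3), dtype=object)
    idx[:, 0] = cube.scan_id
    idx[:, 1] = rows
    idx[:, 2] = cols
    return PatchSet(patches, lab, idx, window)


def unfold_1d(cube: HyperCube, labels: LabelMap) -> PatchSet:
    """Unfold a scan into independent 1D spectra (window-1 patch extraction)."""
    return extract_patches(cube, labels, window=1, border="zero")


def fold_predictions(
    pixel_index: Sequence[Sequence] | np.ndarray,
    predicted: Sequence[int] | np.ndarray,
    grid: tuple[int, int],
) -> np.ndarray:
    """Reassemble per-pixel predictions into a 2D map.

    Every grid pixel must appear exactly once in ``pixel_index``; patch order
    is irrelevant. Inverse of unfolding.
    """
    h, w = grid
    predicted = np.asarray(predicted)
    idx = np.asarray(pixel_index, dtype=object)
    if len(idx) != len(predicted):
        raise PatchError("pixel_index and predictions differ in length")
    if len(idx) != h * w:
        raise PatchError(
            f"expected {h * w} pixels for grid {grid}, got {len(idx)}"
        )
    out = np.full((h, w), -1, dtype=np.int64)
    for (scan_id, r, c), p in zip(idx, predicted):
        r, c = int(r), int(c)
        if not (0 <= r < h and 0 <= c < w):
            raise PatchError(f"pixel ({r}, {c}) outside grid {grid}")
        if out[r, c] != -1:
            raise PatchError(f"duplicate pixel ({r}, {c})")
        out[r, c] = int(p)
    if np.any(out == -1):
        missing = np.argwhere(out == -1)[0]
        raise PatchError(f"missing pixel {tuple(missing)}")
    return out
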