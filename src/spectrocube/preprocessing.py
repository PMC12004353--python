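"""Per-spectrum preprocessing: despiking, SNIP background removal, normalization.

Every pixel spectrum is treated independently, in the fixed order
despike → background subtraction → normalization (spikes corrupt baseline
estimates if removed later). Pixels whose spectra are all zero — the masked
rest/others pixels — pass through untouched.

SNIP (statistics-sensitive nonlinear iterative peak clipping) estimates a
smooth fluorescence background by repeatedly clipping each point to the mean
of its symmetric neighbours at growing half-widths m = 1..M:

    v[i] ← min(v[i], (v[i−m] + v[i+m]) / 2)

optionally inside the log-log-square-root (LLS) compression
y = log(log(√(v+1)+1)+1), which tames high-dynamic-range fluorescence.
Despiking removes cosmic-ray artifacts — isolated sharp spikes — by replacing
points whose robust z-score against a running median exceeds a cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter

from .cube_io import HyperCube, LabelMap, SpectroCubeError


class PreprocessError(SpectroCubeError):
    pass


class ZeroSpectrumError(PreprocessError):
    """Normalization requested for an all-zero spectrum."""


NORM_METHODS = ("l2", "area", "max", "none")


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the three-step chain.

    snip_iterations : max clipping half-width M (bins); larger follows broader
        backgrounds. Default 40, common SNIP practice for Raman.
    snip_use_lls : apply the LLS compression before clipping (default on).
    despike_window : odd running-median window in bins (default 7).
    despike_threshold : robust z-score cutoff for spike replacement (default 8).
    norm_method : one of l2 | area | max | none (default l2 — unit-norm
        spectra are scale-free inputs for the networks).
    """

    snip_iterations: int = 40
    snip_use_lls: bool = True
    despike_window: int = 7
    despike_threshold: float = 8.0
    norm_method: str = "l2"

    def __post_init__(self) -> None:
        if self.snip_iterations < 1:
            raise PreprocessError("snip_iterations must be ≥ 1")
        if self.despike_window < 3 or self.despike_window % 2 == 0:
            raise PreprocessError("despike_window must be odd and ≥ 3")
        if self.despike_threshold <= 0:
            raise PreprocessError("despike_threshold must be positive")
        if self.norm_method not in NORM_METHODS:
            raise PreprocessError(f"norm_method must be one of {NORM_METHODS}")


def _lls(y: np.ndarray) -> np.ndarray:
    return np.log(np.log(np.sqrt(y + 1.0) + 1.0) + 1.0)


def _inv_lls(y: np.ndarray) -> np.ndarray:
    return np.square(np.exp(np.exp(y) - 1.0) - 1.0) - 1.0


def snip_baseline(spectrum: np.ndarray, config: PreprocessConfig) -> np.ndarray:
    """SNIP background estimate of one spectrum (or a batch, last axis = bins).

    Clipping passes are synchronous: each pass m reads the previous pass's
    values. The baseline never exceeds the working spectrum at any step, so
    more iterations can only lower it.
    """
    v = np.asarray(spectrum, dtype=np.float64)
    b = v.shape[-1]
    if not np.all(np.isfinite(v)):
        raise PreprocessError("non-finite values in spectrum")
    if b < 3:
        raise PreprocessError(f"spectrum too short ({b} bins) for SNIP")
    offset = 0.0
    if config.snip_use_lls:
        offset = min(0.0, float(v.min()))  # LLS needs v+1 > 0
        v = _lls(v - offset)
    v = v.copy()
    m_max = min(config.snip_iterations, (b - 1) // 2)
    for m in range(1, m_max + 1):
        avg = 0.5 * (v[..., : b - 2 * m] + v[..., 2 * m :])
        v[..., m : b - m] = np.minimum(v[..., m : b - m], avg)
    if config.snip_use_lls:
        v = _inv_lls(v) + offset
    return v


def _running_median(x: np.ndarray, window: int) -> np.ndarray:
    # edge-replicated centered window along the last axis
    size = (1,) * (x.ndim - 1) + (window,)
    return median_filter(x, size=size, mode="nearest")


def _despike_pass(x: np.ndarray, config: PreprocessConfig) -> np.ndarray:
    med = _running_median(x, config.despike_window)
    resid = x - med
    # per-spectrum global MAD of residuals, scaled to σ-equivalents, floored
    # at 1% of the overall signal scale so smooth curvature is never flagged
    mad = np.median(np.abs(resid), axis=-1, keepdims=True)
    signal_scale = np.median(
        np.abs(x - np.median(x, axis=-1, keepdims=True)), axis=-1, keepdims=True
    )
    scale = 1.4826 * mad + 0.01 * signal_scale + 1e-12
    z = np.abs(resid) / scale
    return np.where(z > config.despike_threshold, med, x)


def despike(spectrum: np.ndarray, config: PreprocessConfig) -> np.ndarray:
    """Replace cosmic-ray spikes by the local running median.

    A point is a spike when |x − median_w(x)| exceeds ``despike_threshold``
    robust standard deviations (1.4826·MAD of the residuals). The pass is
    repeated until no point is flagged (bounded), which makes the operation
    exactly idempotent.
    """
    x = np.asarray(spectrum, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise PreprocessError("non-finite values in spectrum")
    if config.despike_window >= x.shape[-1]:
        raise PreprocessError("despike_window must be smaller than the spectrum")
    for _ in range(10):
        nxt = _despike_pass(x, config)
        if np.array_equal(nxt, x):
            break
        x = nxt
    return x


def normalize(spectrum: np.ndarray, method: str = "l2") -> np.ndarray:
    """Scale one spectrum: unit L2 norm, unit absolute area, unit max, or none."""
    if method not in NORM_METHODS:
        raise PreprocessError(f"unknown norm method {method!r}")
    x = np.asarray(spectrum, dtype=np.float64)
    if method == "none":
        return x.copy()
    if not np.any(x):
        raise ZeroSpectrumError("cannot normalize an all-zero spectrum")
    if method == "l2":
        return x / np.linalg.norm(x)
    if method == "area":
        return x / np.sum(np.abs(x))
    return x / x.max()


def preprocess_spectrum(spectrum: np.ndarray, config: PreprocessConfig) -> np.ndarray:
    """despike → SNIP subtraction → normalize, for a single spectrum."""
    x = despike(spectrum, config)
    x = x - snip_baseline(x, config)
    return normalize(x, config.norm_method)


def preprocess_cube(
    cube: HyperCube, labels: LabelMap, config: PreprocessConfig
) -> HyperCube:
    """Apply the chain to every pixel spectrum of a scan.

    All-zero spectra (masked rest/others pixels, zero padding) are passed
    through bit-identically.
    """
    h, w, b = cube.shape
    flat = cube.intensities.reshape(h * w, b).astype(np.float64)
    live = np.any(flat != 0, axis=1)
    out = flat.copy()
    if np.any(live):
        x = flat[live]
        x = despike(x, config)
        x = x - snip_baseline(x, config)
        if config.norm_method != "none":
            if not np.all(np.any(x, axis=1)):
                raise ZeroSpectrumError(
                    "background subtraction produced an all-zero spectrum"
                )
            if config.norm_method == "l2":
                x = x / np.linalg.norm(x, axis=1, keepdims=True)
            elif config.norm_method == "area":
                x = x / np.sum(np.abs(x), axis=1, keepdims=True)
            else:
                x = x / x.max(axis=1, keepdims=True)
        out[live] = x
    from dataclasses import replace

    return replace(cube, intensities=out.reshape(h, w, b))
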