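"""Synthetic annotated hyperspectral phantoms.

The generator emulates the statistical structure the pipeline assumes in real
tissue scans: contiguous blob-shaped class regions on a small spatial grid,
one class-specific Raman-like signature (a sum of Gaussian peaks) per class,
a smooth subject-specific polynomial fluorescence baseline, white spectral
noise, sparse cosmic-ray spikes — and, crucially, a fraction of isolated
pixels whose *spectrum* is drawn from a wrong class while their annotation
stays correct. These spatially uncorrelated corruptions are exactly the
structure that rewards spatially aware models over per-spectrum ones: a 3×3
majority vote over spectral evidence beats per-pixel evidence.

Everything is deterministic in the config seed; subjects differ only through
their baseline coefficients.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .cube_io import HyperCube, LabelMap, SpectroCubeError, write_scan


class PhantomError(SpectroCubeError):
    pass


@dataclass(frozen=True)
class PhantomConfig:
    """Phantom generation parameters (desk-scale defaults).

    Defaults produce 16 scans of 24×24 pixels × 64 bands from 8 subjects with
    3 classes — small enough to train all three networks on one CPU while
    keeping the blob/signature/noise structure of the real scans.
    """

    grid: tuple[int, int] = (24, 24)
    bands: int = 64
    n_classes: int = 3
    n_scans: int = 16
    n_subjects: int = 8
    peaks_per_class: int = 5
    peak_width_bins: float = 3.0
    baseline_degree: int = 2
    baseline_amplitude: float = 0.5
    noise_sd: float = 0.05
    spike_rate: float = 0.02
    spike_amplitude: float = 20.0
    pixel_label_noise: float = 0.08
    blob_smoothness: float = 3.0
    min_class_separation: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise PhantomError("n_classes must be ≥ 2")
        if self.n_subjects > self.n_scans:
            raise PhantomError("n_subjects must be ≤ n_scans")
        if min(self.grid) < 1 or self.bands < 2:
            raise PhantomError("degenerate grid or band count")
        for name in ("noise_sd", "spike_rate", "peak_width_bins",
                     "blob_smoothness", "baseline_amplitude"):
            if getattr(self, name) < 0:
                raise PhantomError(f"{name} must be ≥ 0")
        if not (0 <= self.pixel_label_noise < 1):
            raise PhantomError("pixel_label_noise must be in [0, 1)")


def _rng(*entropy: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(list(entropy)))


def separation_floor(cfg: PhantomConfig) -> float:
    """Required min pairwise L2 distance between normalized signatures.

    Scales down with √(bands/64): fewer spectral bands leave less room for
    distinct smooth signatures.
    """
    return cfg.min_class_separation * min(1.0, np.sqrt(cfg.bands / 64.0))


def make_signatures(cfg: PhantomConfig) -> np.ndarray:
    """n_classes × bands matrix of class signatures (sums of Gaussian peaks).

    Regenerates (deterministically in the seed) until every pair of
    L2-normalized signatures is at least :func:`separation_floor` apart.
    """
    b = cfg.bands
    grid = np.arange(b, dtype=np.float64)
    for attempt in range(64):
        rng = _rng(cfg.seed, 101, attempt)
        sig = np.zeros((cfg.n_classes, b))
        for c in range(cfg.n_classes):
            pos = rng.uniform(0.08 * b, 0.92 * b, size=cfg.peaks_per_class)
            height = rng.uniform(0.5, 1.5, size=cfg.peaks_per_class)
            width = cfg.peak_width_bins * rng.uniform(0.7, 1.3, cfg.peaks_per_class)
            for p, h, s in zip(pos, height, width):
                sig[c] += h * np.exp(-0.5 * ((grid - p) / s) ** 2)
        unit = sig / np.linalg.norm(sig, axis=1, keepdims=True)
        d = np.linalg.norm(unit[:, None, :] - unit[None, :, :], axis=2)
        np.fill_diagonal(d, np.inf)
        if d.min() >= separation_floor(cfg):
            return sig
    raise PhantomError(
        "could not satisfy the class-separation floor; lower "
        "min_class_separation or raise peaks_per_class/bands"
    )


def _blob_labels(cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Contiguous class regions: threshold a smoothed random field at
    quantiles giving roughly equal class areas."""
    h, w = cfg.grid
    f = gaussian_filter(rng.standard_normal((h, w)), cfg.blob_smoothness)
    qs = np.quantile(f, np.linspace(0, 1, cfg.n_classes + 1)[1:-1])
    return np.searchsorted(qs, f, side="right").astype(np.int16)


def _subject_baseline(cfg: PhantomConfig, subject_id: str) -> np.ndarray:
    """Smooth polynomial baseline shared by all scans of one subject."""
    crc = zlib.crc32(str(subject_id).encode())
    rng = _rng(cfg.seed, 202, crc & 0x7FFFFFFF)
    coeffs = rng.uniform(-1, 1, size=cfg.baseline_degree + 1)
    t = np.linspace(-1, 1, cfg.bands)
    base = np.polynomial.polynomial.polyval(t, coeffs)
    base -= base.min()
    return cfg.baseline_amplitude * base


def make_scan(
    cfg: PhantomConfig,
    subject_id: str,
    scan_seed: int,
    return_truth: bool = False,
):
    """Generate one annotated scan.

    Each pixel's spectrum is its class signature plus the subject baseline,
    Gaussian noise and Poisson-count spikes; a ``pixel_label_noise`` fraction
    of pixels get the spectrum of a *wrong* class while keeping the true
    annotation. With ``return_truth`` the per-pixel spectrum-generating class
    map is also returned (for oracle checks).
    """
    h, w = cfg.grid
    b = cfg.bands
    rng = _rng(cfg.seed, 303, int(scan_seed))
    signatures = make_signatures(cfg)
    labels = _blob_labels(cfg, rng)
    spectrum_classes = labels.copy()
    n_noise = int(round(cfg.pixel_label_noise * h * w))
    if n_noise:
        flat = rng.choice(h * w, size=n_noise, replace=False)
        shift = rng.integers(1, cfg.n_classes, size=n_noise)
        sc = spectrum_classes.ravel()
        sc[flat] = (sc[flat] + shift) % cfg.n_classes
        spectrum_classes = sc.reshape(h, w)
    baseline = _subject_baseline(cfg, subject_id)
    cube = signatures[spectrum_classes] + baseline
    if cfg.noise_sd > 0:
        cube = cube + rng.normal(0.0, cfg.noise_sd, size=(h, w, b))
    n_spikes = rng.poisson(cfg.spike_rate, size=(h, w))
    for r, c in zip(*np.nonzero(n_spikes)):
        for _ in range(n_spikes[r, c]):
            pos = rng.integers(0, b)
            cube[r, c, pos] += cfg.spike_amplitude * rng.uniform(0.5, 1.5)
    axis = np.linspace(400.0, 1800.0, b)
    hc = HyperCube(
        cube.astype(np.float32),
        axis,
        scan_id=f"scan{scan_seed:04d}",
        subject_id=str(subject_id),
    )
    class_names = tuple(f"class{i}" for i in range(cfg.n_classes))
    lm = LabelMap(labels, class_names)
    if return_truth:
        return hc, lm, {"spectrum_classes": spectrum_classes,
                        "baseline": baseline, "signatures": signatures}
    return hc, lm


def make_dataset(
    cfg: PhantomConfig, path=None
) -> list[tuple[HyperCube, LabelMap]]:
    """Generate ``n_scans`` scans assigned round-robin to ``n_subjects``
    subjects; optionally write them into an HDF5 container at ``path``."""
    scans = []
    for i in range(cfg.n_scans):
        subject = f"subject{i % cfg.n_subjects:03d}"
        scans.append(make_scan(cfg, subject, scan_seed=i))
    if path is not None:
        mode = "w"
        for cube, labels in scans:
            write_scan(path, cube, labels, mode=mode)
            mode = "a"
    return scans


def majority_vote_smooth(class_map: np.ndarray, n_classes: int) -> np.ndarray:
    """3×3 majority vote over a class map (edge windows truncated); an
    oracle for how much isolated-pixel corruption spatial context removes.
    Ties go to the smallest class code among the tied."""
    h, w = class_map.shape
    votes = np.zeros((n_classes, h, w), dtype=np.int32)
    padded = np.pad(class_map, 1, mode="constant", constant_values=-1)
    for dr in range(3):
        for dc in range(3):
            block = padded[dr : dr + h, dc : dc + w]
            for k in range(n_classes):
                votes[k] += block == k
    return votes.argmax(axis=0).astype(class_map.dtype)
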