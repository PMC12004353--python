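"""SNIP baseline estimation, despiking, normalization, and the cube chain."""

import numpy as np
import pytest

from spectrocube import (
    PhantomConfig,
    PreprocessConfig,
    despike,
    make_scan,
    normalize,
    preprocess_cube,
    preprocess_spectrum,
    snip_baseline,
)
from spectrocube.cube_io import HyperCube, LabelMap
from spectrocube.preprocessing import PreprocessError, ZeroSpectrumError, _lls, _inv_lls


# --- independent oracles ----------------------------------------------------

def snip_oracle(spectrum, iterations, use_lls):
    """Direct, loop-based transcription of the clipping recursion."""
    v = np.asarray(spectrum, dtype=float).copy()
    offset = 0.0
    if use_lls:
        offset = min(0.0, v.min())
        v = np.log(np.log(np.sqrt(v - offset + 1) + 1) + 1)
    b = len(v)
    for m in range(1, min(iterations, (b - 1) // 2) + 1):
        prev = v.copy()
        for i in range(m, b - m):
            v[i] = min(prev[i], 0.5 * (prev[i - m] + prev[i + m]))
    if use_lls:
        v = (np.exp(np.exp(v) - 1) - 1) ** 2 - 1 + offset
    return v


def despike_oracle_pass(x, window, threshold):
    """Explicit running median (edge-replicated) + floored MAD z-score."""
    b = len(x)
    half = window // 2
    padded = np.concatenate([[x[0]] * half, x, [x[-1]] * half])
    med = np.array([np.median(padded[i : i + window]) for i in range(b)])
    resid = x - med
    mad = np.median(np.abs(resid))
    signal_scale = np.median(np.abs(x - np.median(x)))
    z = np.abs(resid) / (1.4826 * mad + 0.01 * signal_scale + 1e-12)
    return np.where(z > threshold, med, x)


# --- SNIP -------------------------------------------------------------------

class TestSnip:
    def test_constant_spectrum_is_fixed_point(self):
        cfg = PreprocessConfig(snip_iterations=10)
        x = np.full(50, 3.7)
        assert np.allclose(snip_baseline(x, cfg), x, atol=1e-9)

    def test_linear_ramp_fully_removed(self):
        cfg = PreprocessConfig(snip_iterations=30, snip_use_lls=False)
        x = np.linspace(2.0, 9.0, 120)
        corrected = x - snip_baseline(x, cfg)
        assert np.max(np.abs(corrected)) < 1e-6 * (x.max() - x.min())

    @pytest.mark.parametrize("use_lls", [False, True])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_loop_oracle(self, seed, use_lls):
        rng = np.random.default_rng(seed)
        x = np.abs(rng.normal(1.0, 0.5, size=80)) + 0.1
        cfg = PreprocessConfig(snip_iterations=12, snip_use_lls=use_lls)
        assert np.allclose(
            snip_baseline(x, cfg), snip_oracle(x, 12, use_lls), atol=1e-9
        )

    def test_recovers_quadratic_background_under_peak(self):
        # single Gaussian peak (sigma = 5 bins) on a convex quadratic background
        b = 300
        t = np.arange(b, dtype=float)
        background = 2.0 + 0.5 * ((t - 150) / 100) ** 2
        peak = 3.0 * np.exp(-0.5 * ((t - 150) / 5.0) ** 2)
        cfg = PreprocessConfig(snip_iterations=40, snip_use_lls=False)
        baseline = snip_baseline(background + peak, cfg)
        off_peak = np.abs(t - 150) > 4 * 5
        rms = np.sqrt(np.mean((baseline[off_peak] - background[off_peak]) ** 2))
        assert rms < 0.02 * np.sqrt(np.mean(background[off_peak] ** 2))

    def test_more_iterations_never_raise_baseline(self):
        rng = np.random.default_rng(3)
        x = np.abs(rng.normal(1.0, 0.5, size=90)) + 0.1
        prev = None
        for m in (1, 5, 10, 20, 40):
            cur = snip_baseline(x, PreprocessConfig(snip_iterations=m))
            if prev is not None:
                assert np.all(cur <= prev + 1e-9)
            prev = cur

    def test_lls_inverts(self):
        y = np.linspace(0.0, 50.0, 31)
        assert np.allclose(_inv_lls(_lls(y)), y, atol=1e-8)

    def test_non_finite_rejected(self):
        cfg = PreprocessConfig()
        with pytest.raises(PreprocessError):
            snip_baseline(np.array([1.0, np.nan, 2.0, 1.0]), cfg)


# --- despiking --------------------------------------------------------------

class TestDespike:
    def smooth(self, b=400):
        t = np.linspace(0, 4 * np.pi, b)
        return 1.0 + 0.3 * np.sin(t) + 0.1 * np.cos(3 * t)

    def test_identity_on_smooth_spectrum(self):
        x = self.smooth()
        assert np.array_equal(despike(x, PreprocessConfig()), x)

    def test_single_spike_replaced_others_untouched(self):
        cfg = PreprocessConfig()
        x = self.smooth()
        x[300] *= 100
        y = despike(x, cfg)
        assert y[300] != x[300]
        assert np.abs(y[300] - np.median(x[297:304])) < 0.5
        mask = np.ones(len(x), bool)
        mask[300] = False
        assert np.array_equal(y[mask], x[mask])

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(9)
        x = self.smooth() + rng.normal(0, 0.01, 400)
        for pos in (40, 200, 333):
            x[pos] += 30
        cfg = PreprocessConfig(despike_window=7, despike_threshold=8.0)
        expected = x.copy()
        for _ in range(10):
            nxt = despike_oracle_pass(expected, 7, 8.0)
            if np.array_equal(nxt, expected):
                break
            expected = nxt
        assert np.allclose(despike(x, cfg), expected, atol=1e-12)

    def test_two_adjacent_spikes_both_flagged(self):
        cfg = PreprocessConfig(despike_window=7, despike_threshold=5.0)
        x = self.smooth()
        x[200] += 50
        x[201] += 45
        y = despike(x, cfg)
        assert y[200] < 10 and y[201] < 10

    @pytest.mark.parametrize("seed", range(10))
    def test_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        x = self.smooth() + rng.normal(0, 0.05, 400)
        spikes = rng.choice(400, size=5, replace=False)
        x[spikes] += rng.uniform(5, 80, size=5)
        cfg = PreprocessConfig()
        once = despike(x, cfg)
        assert np.array_equal(despike(once, cfg), once)

    def test_window_too_large_rejected(self):
        with pytest.raises(PreprocessError):
            despike(np.ones(5), PreprocessConfig(despike_window=7))


# --- normalization ----------------------------------------------------------

class TestNormalize:
    def test_l2_example(self):
        assert np.allclose(normalize(np.array([3.0, 4.0]), "l2"), [0.6, 0.8])

    @pytest.mark.parametrize("seed", range(5))
    def test_l2_unit_norm(self, seed):
        v = np.random.default_rng(seed).normal(size=64)
        assert abs(np.linalg.norm(normalize(v, "l2")) - 1.0) < 1e-12

    def test_area_and_max(self):
        v = np.array([1.0, -3.0])
        assert np.sum(np.abs(normalize(v, "area"))) == pytest.approx(1.0)
        assert normalize(np.array([2.0, 8.0]), "max").max() == pytest.approx(1.0)

    def test_zero_spectrum_rejected(self):
        with pytest.raises(ZeroSpectrumError):
            normalize(np.zeros(10), "l2")
        assert np.array_equal(normalize(np.zeros(10), "none"), np.zeros(10))


# --- whole-cube chain -------------------------------------------------------

class TestPreprocessCube:
    def test_all_masked_cube_untouched(self):
        cube = HyperCube(
            np.zeros((3, 4, 20), np.float32), np.arange(20.0), "s", "m"
        )
        labels = LabelMap(np.zeros((3, 4), np.int16), ("others",), (0,))
        out = preprocess_cube(cube, labels, PreprocessConfig())
        assert np.array_equal(out.intensities, cube.intensities)

    def test_single_pixel_equals_composition(self):
        rng = np.random.default_rng(5)
        spec = np.abs(rng.normal(2.0, 0.5, size=60)) + 0.5
        cube = HyperCube(spec[None, None, :], np.arange(60.0), "s", "m")
        labels = LabelMap(np.zeros((1, 1), np.int16), ("a",))
        cfg = PreprocessConfig(snip_iterations=10)
        out = preprocess_cube(cube, labels, cfg)
        assert np.allclose(
            out.intensities[0, 0], preprocess_spectrum(spec, cfg), atol=1e-10
        )

    def test_masked_pixels_pass_through_inside_mixed_cube(self, tiny_cfg):
        cube, labels = make_scan(tiny_cfg, "s0", scan_seed=1)
        arr = cube.intensities.copy()
        arr[0, 0] = 0  # a masked pixel among live ones
        cube = HyperCube(arr, cube.axis, cube.scan_id, cube.subject_id)
        out = preprocess_cube(cube, labels, PreprocessConfig(snip_iterations=8))
        assert np.all(out.intensities[0, 0] == 0)
        assert not np.allclose(out.intensities[1, 1], arr[1, 1])

    def test_background_removed_on_synthetic_scan(self):
        # known generating background: after subtraction, off-peak level is
        # small relative to peak height
        cfg = PhantomConfig(
            grid=(6, 6), bands=128, peaks_per_class=2, peak_width_bins=2.0,
            noise_sd=0.0, spike_rate=0.0, pixel_label_noise=0.0,
            baseline_amplitude=1.0, seed=11,
        )
        cube, labels, truth = make_scan(cfg, "s", 0, return_truth=True)
        pc = PreprocessConfig(snip_iterations=40, norm_method="none")
        out = preprocess_cube(cube, labels, pc)
        sig = truth["signatures"]
        for r, c in [(0, 0), (3, 4)]:
            k = truth["spectrum_classes"][r, c]
            corrected = out.intensities[r, c]
            off_peak = sig[k] < 0.02 * sig[k].max()
            assert np.abs(corrected[off_peak]).mean() < 0.02 * sig[k].max()
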