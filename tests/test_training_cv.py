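"""Grouped fold assignment, the training loop, and cross-validation plumbing."""

import numpy as np
import pytest

from spectrocube import (
    PhantomConfig,
    TrainConfig,
    build_cnn1d,
    grouped_kfold,
    instantiate,
    make_dataset,
    run_cv,
    train,
)
from spectrocube.training_cv import CVError


def subject_counts(scans):
    counts: dict[str, int] = {}
    for cube, labels in scans:
        counts[cube.subject_id] = counts.get(cube.subject_id, 0) + labels.labels.size
    return counts


# well-separated, low-noise phantom: easy for any of the models
EASY = PhantomConfig(
    grid=(10, 10), bands=16, n_classes=3, n_scans=6, n_subjects=3,
    noise_sd=0.02, spike_rate=0.0, pixel_label_noise=0.0,
    baseline_amplitude=0.1, seed=21,
)


class TestGroupedKFold:
    def test_equal_subjects_split_evenly(self):
        folds = grouped_kfold({f"s{i}": 100 for i in range(10)}, K=5, seed=0)
        sizes = np.bincount(list(folds.subject_to_fold.values()), minlength=5)
        assert np.all(sizes == 2)

    def test_deterministic_in_seed(self):
        subjects = {f"s{i}": 100 + i for i in range(9)}
        a = grouped_kfold(subjects, K=3, seed=4)
        b = grouped_kfold(subjects, K=3, seed=4)
        assert a.subject_to_fold == b.subject_to_fold

    def test_balance_bound_at_scale(self):
        # subject sizes shaped like scans-per-subject × pixels-per-scan
        rng = np.random.default_rng(0)
        sizes = 1360 * (1 + rng.poisson(3.8, size=156))
        folds = grouped_kfold(
            {f"mouse{i}": int(s) for i, s in enumerate(sizes)}, K=5, seed=1
        )
        loads = np.zeros(5)
        for i, s in enumerate(sizes):
            loads[folds.subject_to_fold[f"mouse{i}"]] += s
        assert loads.max() / loads.min() <= 1.10

    def test_greedy_matches_reference_loop(self):
        # independent re-run of the same greedy rule
        subjects = {"a": 50, "b": 40, "c": 30, "d": 20, "e": 10}
        folds = grouped_kfold(subjects, K=2, seed=0)
        loads = {0: 0, 1: 0}
        expect = {}
        for sid in sorted(subjects, key=lambda s: -subjects[s]):
            f = min(loads, key=lambda k: (loads[k], k))
            expect[sid] = f
            loads[f] += subjects[sid]
        assert folds.subject_to_fold == expect

    def test_k_bounds_rejected(self):
        with pytest.raises(CVError):
            grouped_kfold({"a": 1, "b": 1}, K=3)
        with pytest.raises(CVError):
            grouped_kfold({"a": 1, "b": 1, "c": 1}, K=1)


class TestTrain:
    def _data(self, n=48):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(n, 16, 1)).astype(np.float32)
        y = rng.integers(0, 2, size=n)
        return x, y

    def test_history_recorded_and_finite(self):
        x, y = self._data()
        net = instantiate(build_cnn1d(16, 2), seed=0)
        hist = train(net, x, y, TrainConfig(epochs=2, batch_size=16, seed=0))
        assert len(hist["loss"]) == 2
        assert all(np.isfinite(v) for v in hist["loss"])
        assert all(0 <= v <= 1 for v in hist["accuracy"])

    def test_same_seed_same_trajectory(self):
        x, y = self._data()
        h1 = train(instantiate(build_cnn1d(16, 2), seed=5), x, y,
                   TrainConfig(epochs=3, batch_size=16, seed=9))
        h2 = train(instantiate(build_cnn1d(16, 2), seed=5), x, y,
                   TrainConfig(epochs=3, batch_size=16, seed=9))
        assert h1["loss"] == h2["loss"]

    def test_shape_mismatch_and_empty_rejected(self):
        x, y = self._data()
        net = instantiate(build_cnn1d(32, 2), seed=0)
        with pytest.raises(CVError):
            train(net, x, y, TrainConfig(epochs=1))
        with pytest.raises(CVError):
            train(net, x[:0], y[:0], TrainConfig(epochs=1))

    def test_max_units_subsamples(self):
        x, y = self._data()
        net = instantiate(build_cnn1d(16, 2), seed=0)
        hist = train(net, x, y, TrainConfig(epochs=1, batch_size=8, seed=0,
                                            max_units=10))
        assert len(hist["loss"]) == 1


class TestRunCV:
    def test_two_fold_record_count_and_leakage(self):
        cfg = PhantomConfig(
            grid=(8, 8), bands=16, n_scans=4, n_subjects=2, seed=13
        )
        scans = make_dataset(cfg)
        folds = grouped_kfold(subject_counts(scans), K=2, seed=0)
        recs = run_cv(scans, "cnn1d", folds,
                      TrainConfig(epochs=1, batch_size=64, seed=0))
        assert len(recs) == 2
        assert {r["fold"] for r in recs} == {0, 1}
        for r in recs:
            assert 0.0 <= r["val_accuracy"] <= 1.0
            assert 0.0 <= r["val_balanced_accuracy"] <= 1.0

    def test_validation_folds_cover_each_scan_once(self):
        scans = make_dataset(EASY)
        folds = grouped_kfold(subject_counts(scans), K=3, seed=0)
        seen = [folds.fold_of(c.subject_id) for c, _ in scans]
        assert sorted(set(seen)) == [0, 1, 2]
        assert len(seen) == len(scans)  # each scan validates in exactly one fold

    def test_missing_subject_rejected(self):
        scans = make_dataset(EASY)
        folds = grouped_kfold({"other": 10, "another": 10}, K=2, seed=0)
        with pytest.raises(CVError):
            run_cv(scans, "cnn1d", folds, TrainConfig(epochs=1))

    def test_easy_phantom_cnn1d_validation_accuracy(self):
        """On a well-separated phantom a few epochs of the 1D CNN reach
        > 0.9 validation accuracy (nearest-centroid is ~1.0 here)."""
        scans = make_dataset(EASY)
        folds = grouped_kfold(subject_counts(scans), K=3, seed=0)
        recs = run_cv(scans, "cnn1d", folds,
                      TrainConfig(epochs=5, batch_size=64, seed=1))
        accs = [r["val_accuracy"] for r in recs]
        assert np.mean(accs) > 0.9

    def test_easy_phantom_cnn3d_training_balanced_accuracy(self):
        """The 3D patch CNN fits the easy phantom's training set."""
        scans = make_dataset(EASY)
        folds = grouped_kfold(subject_counts(scans), K=3, seed=0)
        recs = run_cv(scans, "cnn3d", folds,
                      TrainConfig(epochs=12, batch_size=64, seed=1),
                      folds_to_run=[0])
        assert recs[0]["train_balanced_accuracy"] >= 0.95

    def test_unet_runs_and_predicts_full_maps(self):
        scans = make_dataset(EASY)
        folds = grouped_kfold(subject_counts(scans), K=3, seed=0)
        recs = run_cv(scans, "unet3d", folds,
                      TrainConfig(epochs=2, seed=1), base_kernels=8,
                      folds_to_run=[0])
        assert len(recs) == 1
        assert 0.0 <= recs[0]["val_balanced_accuracy"] <= 1.0
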