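"""Subject-level grouped cross-validation and the training loop.

Folds are assigned at the subject (mouse/patient) level, never at the scan or
pixel level, so no individual contributes data to both the training and
validation side of a fold. Subjects are packed greedily — largest spectra
count first into the currently lightest fold — which balances fold sizes as
far as the subject constraint allows; a seed breaks ties.

Training optimizes categorical cross-entropy with Adam at a fixed learning
rate (default 3e-4). For the patch/spectrum classifiers a unit is one pixel;
for the U-Net a unit is one whole scan and the loss is per-pixel
cross-entropy averaged over all pixels, masked ones included (they form a
predictable background class in the output maps); evaluation metrics still
exclude them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from . import nn
from .cube_io import HyperCube, LabelMap, SpectroCubeError, TaskScheme, relabel
from .metrics import balanced_accuracy, accuracy, confusion
from .models import BUILDERS, instantiate
from .patching import extract_patches, fold_predictions, unfold_1d

logger = logging.getLogger("spectrocube")


class CVError(SpectroCubeError):
    pass


@dataclass(frozen=True)
class FoldAssignment:
    """Mapping subject → fold index for grouped K-fold cross-validation."""

    subject_to_fold: Mapping[str, int]
    K: int
    seed: int = 0

    def __post_init__(self) -> None:
        folds = set(self.subject_to_fold.values())
        if self.K < 2:
            raise CVError("K must be ≥ 2")
        if folds != set(range(self.K)):
            raise CVError("every fold index in 0..K−1 must be non-empty")

    def fold_of(self, subject_id: str) -> int:
        try:
            return self.subject_to_fold[subject_id]
        except KeyError:
            raise CVError(f"subject {subject_id!r} has no fold") from None


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters (the optimizer is always Adam).

    ``max_units`` optionally subsamples the training units once (seeded)
    before training — a desk-scale control for quick experiments; ``None``
    uses everything.
    """

    epochs: int = 50
    learning_rate: float = 3e-4
    batch_size: int = 256
    seed: int = 0
    class_weighting: str = "none"  # none | balanced
    max_units: Optional[int] = None

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise CVError("epochs must be ≥ 1")
        if self.learning_rate <= 0:
            raise CVError("learning_rate must be positive")
        if self.class_weighting not in ("none", "balanced"):
            raise CVError("class_weighting must be 'none' or 'balanced'")


def grouped_kfold(
    subjects: Iterable[tuple[str, int]] | Mapping[str, int],
    K: int,
    seed: int = 0,
) -> FoldAssignment:
    """Partition subjects into K folds balancing total spectra counts.

    Greedy: subjects in decreasing count order (seeded tie-break) each go to
    the currently lightest fold. All scans of a subject share its fold.
    """
    if isinstance(subjects, Mapping):
        items = list(subjects.items())
    else:
        items = list(subjects)
    if K < 2:
        raise CVError("K must be ≥ 2")
    if len(items) < K:
        raise CVError(f"{len(items)} subjects cannot fill {K} folds")
    if len({s for s, _ in items}) != len(items):
        raise CVError("duplicate subject ids")
    rng = np.random.default_rng(seed)
    tie = rng.permutation(len(items))
    order = sorted(range(len(items)), key=lambda i: (-items[i][1], tie[i]))
    loads = np.zeros(K, dtype=np.int64)
    assignment: dict[str, int] = {}
    for i in order:
        f = int(np.argmin(loads))  # ties -> lowest fold index
        sid, count = items[i]
        assignment[sid] = f
        loads[f] += count
    return FoldAssignment(assignment, K, seed)


def _class_weights(y: np.ndarray, n_classes: int, mode: str) -> np.ndarray | None:
    if mode == "none":
        return None
    counts = np.bincount(y.ravel(), minlength=n_classes).astype(np.float64)
    weights = np.zeros(n_classes)
    present = counts > 0
    weights[present] = y.size / (present.sum() * counts[present])
    return weights


def train(
    network: nn.Network,
    units: np.ndarray,
    targets: np.ndarray,
    cfg: TrainConfig,
) -> dict:
    """Minibatch Adam training; returns the per-epoch history.

    Fully reproducible given ``cfg.seed`` (init is the network's concern;
    shuffling and subsampling are seeded here). History records per-epoch
    mean loss and training accuracy/balanced accuracy computed from the
    predictions made during the epoch's forward passes.
    """
    x = np.asarray(units, dtype=np.float32)
    y = np.asarray(targets)
    if x.shape[0] == 0:
        raise CVError("empty training set")
    if x.shape[0] != y.shape[0]:
        raise CVError("units and targets differ in length")
    expected = getattr(network, "input_shape", None)
    if expected is not None and tuple(x.shape[1:]) != tuple(expected):
        raise CVError(
            f"unit shape {x.shape[1:]} does not match network input {expected}"
        )
    rng = np.random.default_rng(cfg.seed)
    if cfg.max_units is not None and cfg.max_units < x.shape[0]:
        pick = rng.choice(x.shape[0], size=cfg.max_units, replace=False)
        x, y = x[pick], y[pick]
    n_classes = network.forward(x[:1], training=False).shape[-1]
    weights = _class_weights(y, n_classes, cfg.class_weighting)
    opt = nn.Adam(network, lr=cfg.learning_rate)
    history: dict[str, list[float]] = {
        "loss": [], "accuracy": [], "balanced_accuracy": []
    }
    n = x.shape[0]
    for _epoch in range(cfg.epochs):
        perm = rng.permutation(n)
        losses = []
        preds = np.empty(n, dtype=np.int64) if y.ndim == 1 else np.empty(
            y.shape, dtype=np.int64
        )
        for i in range(0, n, cfg.batch_size):
            sel = perm[i : i + cfg.batch_size]
            logits = network.forward(x[sel], training=True)
            loss, grad = nn.cross_entropy_loss_grad(logits, y[sel], weights)
            network.backward(grad)
            opt.step()
            losses.append(loss * len(sel))
            preds[sel] = np.argmax(logits, axis=-1)
        cm = confusion(y.reshape(-1, 1), preds.reshape(-1, 1))
        history["loss"].append(float(np.sum(losses) / n))
        history["accuracy"].append(accuracy(cm))
        history["balanced_accuracy"].append(balanced_accuracy(cm))
        logger.debug(
            "epoch %d loss %.4f acc %.3f", _epoch, history["loss"][-1],
            history["accuracy"][-1],
        )
    return history


def _training_units(
    model: str,
    scans: Sequence[tuple[HyperCube, LabelMap]],
    window: int,
    border: str,
) -> tuple[np.ndarray, np.ndarray]:
    if model == "cnn1d":
        xs, ys = [], []
        for cube, labels in scans:
            ps = unfold_1d(cube, labels)
            xs.append(ps.spectra[:, :, None])
            ys.append(ps.labels)
        return np.concatenate(xs).astype(np.float32), np.concatenate(ys)
    if model == "cnn3d":
        xs, ys = [], []
        for cube, labels in scans:
            ps = extract_patches(cube, labels, window=window, border=border)
            xs.append(ps.patches[..., None])
            ys.append(ps.labels)
        return np.concatenate(xs).astype(np.float32), np.concatenate(ys)
    if model == "unet3d":
        x = np.stack([c.intensities for c, _ in scans])[..., None]
        y = np.stack([l.labels for _, l in scans]).astype(np.int64)
        return x.astype(np.float32), y
    raise CVError(f"unknown model {model!r}")


def predict_map(
    network: nn.Network,
    model: str,
    cube: HyperCube,
    labels: LabelMap,
    window: int = 3,
    border: str = "zero",
    batch_size: int = 1024,
) -> np.ndarray:
    """Predicted 2D segmentation map of one scan."""
    if model == "cnn1d":
        ps = unfold_1d(cube, labels)
        preds = network.predict(
            ps.spectra[:, :, None].astype(np.float32), batch_size
        )
        return fold_predictions(ps.pixel_index, preds, labels.shape)
    if model == "cnn3d":
        ps = extract_patches(cube, labels, window=window, border=border)
        preds = network.predict(ps.patches[..., None].astype(np.float32),
                                batch_size)
        return fold_predictions(ps.pixel_index, preds, labels.shape)
    if model == "unet3d":
        x = cube.intensities[None, ..., None].astype(np.float32)
        return network.predict(x, batch_size=1)[0]
    raise CVError(f"unknown model {model!r}")


def run_cv(
    dataset: Sequence[tuple[HyperCube, LabelMap]],
    model: str,
    folds: FoldAssignment,
    train_cfg: TrainConfig,
    task: Optional[TaskScheme] = None,
    window: int = 3,
    border: str = "zero",
    base_kernels: int = 128,
    folds_to_run: Optional[Sequence[int]] = None,
    return_maps: bool = False,
) -> list[dict]:
    """External grouped cross-validation of one architecture.

    For each fold: train on the other K−1 folds' scans, predict full
    segmentation maps on the fold's scans, and record training (final-epoch)
    and validation accuracy/balanced accuracy, with masked classes excluded
    from evaluation. Returns one record per fold.
    """
    if model not in BUILDERS:
        raise CVError(f"unknown model {model!r}; choose from {list(BUILDERS)}")
    scans = list(dataset)
    if task is not None:
        scans = [relabel(labels, cube, task) for cube, labels in dataset]
    if not scans:
        raise CVError("empty dataset")
    for cube, _ in scans:
        folds.fold_of(cube.subject_id)  # raises if missing
    n_classes = len(scans[0][1].class_names)
    bands = scans[0][0].n_bands
    grid = scans[0][1].shape
    records: list[dict] = []
    run_folds = list(folds_to_run) if folds_to_run is not None else list(
        range(folds.K)
    )
    for f in run_folds:
        train_scans = [s for s in scans if folds.fold_of(s[0].subject_id) != f]
        val_scans = [s for s in scans if folds.fold_of(s[0].subject_id) == f]
        if not val_scans:
            raise CVError(f"fold {f} has no validation scans")
        if not train_scans:
            raise CVError(f"fold {f} has no training scans")
        train_subjects = {c.subject_id for c, _ in train_scans}
        val_subjects = {c.subject_id for c, _ in val_scans}
        if train_subjects & val_subjects:
            raise CVError(
                f"subject leakage in fold {f}: {train_subjects & val_subjects}"
            )
        if model == "cnn1d":
            spec = BUILDERS[model](bands, n_classes)
        elif model == "cnn3d":
            spec = BUILDERS[model](window, bands, n_classes)
        else:
            spec = BUILDERS[model](grid, bands, n_classes, base_kernels)
        network = instantiate(spec, seed=train_cfg.seed * 1000 + f)
        x, y = _training_units(model, train_scans, window, border)
        cfg = train_cfg
        if model == "unet3d":
            cfg = replace(train_cfg, batch_size=1, max_units=None)
        history = train(network, x, y, cfg)
        masked = scans[0][1].masked_classes
        true_all, pred_all = [], []
        maps: dict[str, np.ndarray] = {}
        for cube, labels in val_scans:
            pred = predict_map(
                network, model, cube, labels, window=window, border=border,
                batch_size=train_cfg.batch_size,
            )
            if return_maps:
                maps[cube.scan_id] = pred
            true_all.append(labels.labels.ravel())
            pred_all.append(pred.ravel())
        cm = confusion(
            np.concatenate(true_all)[None, :],
            np.concatenate(pred_all)[None, :],
            class_names=scans[0][1].class_names,
            exclude=masked,
        )
        rec = {
            "fold": f,
            "model": model,
            "n_train_units": int(x.shape[0]),
            "train_accuracy": history["accuracy"][-1],
            "train_balanced_accuracy": history["balanced_accuracy"][-1],
            "val_accuracy": accuracy(cm),
            "val_balanced_accuracy": balanced_accuracy(cm),
            "history": history,
        }
        if return_maps:
            rec["maps"] = maps
        logger.info(
            "fold %d %s: val acc %.3f bal-acc %.3f", f, model,
            rec["val_accuracy"], rec["val_balanced_accuracy"],
        )
        records.append(rec)
    return records
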