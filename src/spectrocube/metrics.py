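"""Segmentation evaluation: confusion matrix, accuracy, balanced accuracy,
Dice–Sørensen coefficient, with the masked-class exclusion rule.

Evaluation is pixel-wise on 2D maps. Pixels whose TRUE class is masked
(rest class / others — their spectra are all zero) are excluded entirely
before tallying. Accuracy is the fraction of evaluated pixels predicted
correctly (trace/total — the multiclass reading of the binary
(TP+TN)/(TP+TN+FP+FN) form); balanced accuracy is the mean of per-class
recalls TPᵢ/(TPᵢ+FNᵢ) over classes that actually occur; DSC is
2|A∩B|/(|A|+|B|) between the predicted and annotated positive sets of a
class, reported per class and as a macro mean on the ×100 scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cube_io import LabelMap, ShapeMismatchError, SpectroCubeError


class MetricError(SpectroCubeError):
    pass


@dataclass
class ConfusionMatrix:
    """K×K count table; rows are true classes, columns predicted."""

    counts: np.ndarray
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.class_names)
        if self.counts.shape != (k, k):
            raise MetricError(
                f"counts {self.counts.shape} vs {k} classes"
            )
        if np.any(self.counts < 0):
            raise MetricError("negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def tp(self, i: int) -> int:
        return int(self.counts[i, i])

    def fn(self, i: int) -> int:
        return int(self.counts[i].sum() - self.counts[i, i])

    def fp(self, i: int) -> int:
        return int(self.counts[:, i].sum() - self.counts[i, i])

    def tn(self, i: int) -> int:
        return self.total - self.tp(i) - self.fn(i) - self.fp(i)

    def recall(self, i: int) -> float:
        denom = self.tp(i) + self.fn(i)
        if denom == 0:
            raise MetricError(f"class {i} has no true pixels")
        return self.tp(i) / denom


def _as_array(m) -> np.ndarray:
    return m.labels if isinstance(m, LabelMap) else np.asarray(m)


def confusion(
    true_map,
    pred_map,
    class_names: Sequence[str] | None = None,
    exclude: Iterable[int] = (),
) -> ConfusionMatrix:
    """Tally a confusion matrix, omitting pixels whose true class is excluded."""
    t = _as_array(true_map)
    p = _as_array(pred_map)
    if t.shape != p.shape:
        raise ShapeMismatchError(f"true {t.shape} vs predicted {p.shape}")
    if class_names is None:
        if isinstance(true_map, LabelMap):
            class_names = true_map.class_names
        else:
            k = int(max(t.max(initial=0), p.max(initial=0))) + 1
            class_names = tuple(str(i) for i in range(k))
    if not exclude and isinstance(true_map, LabelMap):
        exclude = true_map.masked_classes
    k = len(class_names)
    t = t.ravel().astype(np.int64)
    p = p.ravel().astype(np.int64)
    exclude = tuple(exclude)
    if exclude:
        keep = ~np.isin(t, exclude)
        t, p = t[keep], p[keep]
    if t.size and (t.min() < 0 or t.max() >= k or p.min() < 0 or p.max() >= k):
        raise MetricError(f"class codes outside 0..{k - 1}")
    counts = np.bincount(t * k + p, minlength=k * k).reshape(k, k)
    return ConfusionMatrix(counts, tuple(class_names))


def accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of evaluated pixels on the diagonal."""
    if cm.total == 0:
        raise MetricError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def balanced_accuracy(cm: ConfusionMatrix) -> float:
    """Mean recall over classes with at least one true pixel."""
    if cm.total == 0:
        raise MetricError("empty confusion matrix")
    row = cm.counts.sum(axis=1)
    present = row > 0
    recalls = np.diag(cm.counts)[present] / row[present]
    return float(recalls.mean())


def dsc(true_set_size: int, pred_set_size: int, intersection: int) -> float:
    """Dice–Sørensen coefficient 2|A∩B|/(|A|+|B|) on the 0–1 scale."""
    if true_set_size < 0 or pred_set_size < 0:
        raise MetricError("set sizes must be ≥ 0")
    if intersection > min(true_set_size, pred_set_size):
        raise MetricError("intersection exceeds a set size")
    denom = true_set_size + pred_set_size
    if denom == 0:
        raise MetricError("both sets empty")
    return 2.0 * intersection / denom


def dsc_per_class(cm: ConfusionMatrix) -> dict[str, float]:
    """One-vs-rest DSC per class plus the macro mean, ×100.

    Classes absent from both annotation and prediction are skipped.
    """
    out: dict[str, float] = {}
    vals = []
    for i, name in enumerate(cm.class_names):
        a = cm.tp(i) + cm.fn(i)  # annotated positives
        b = cm.tp(i) + cm.fp(i)  # predicted positives
        if a + b == 0:
            continue
        v = 100.0 * dsc(a, b, cm.tp(i))
        out[name] = v
        vals.append(v)
    if not vals:
        raise MetricError("no class has any pixels")
    out["macro"] = float(np.mean(vals))
    return out


def metrics_frame(records: Iterable[dict]) -> pd.DataFrame:
    """Long-format (fold, phase, metric, value) table for CSV reports."""
    rows = []
    for rec in records:
        for phase in ("train", "val"):
            for metric in ("accuracy", "balanced_accuracy"):
                key = f"{phase}_{metric}"
                if key in rec:
                    rows.append(
                        {"fold": rec["fold"], "phase": phase,
                         "metric": metric, "value": rec[key]}
                    )
    return pd.DataFrame(rows, columns=["fold", "phase", "metric", "value"])
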