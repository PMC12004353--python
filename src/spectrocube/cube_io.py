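"""Annotated hyperspectral scans: in-memory model, HDF5 container, relabeling.

A scan is a hyperspectral cube — an H×W spatial grid with a full spectrum of B
bands per pixel — paired with a per-pixel integer label map and a subject
identifier (the mouse or patient the scan came from). Scans live in an HDF5
container with one group per scan under ``/scans/<scan_id>/``.

Two task relabelings of the original 8-class colorectal annotation are
provided: epithelial-tissue detection (4 classes) and colorectal-cancer
detection (5 classes). In both, the classes judged uninformative are merged
into a single rest/others class whose spectra are zeroed; those pixels are
excluded from evaluation metrics downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import h5py
import numpy as np
import pandas as pd


class SpectroCubeError(Exception):
    """Base class for all spectrocube data errors."""


class ContainerError(SpectroCubeError):
    """Missing or malformed dataset in an HDF5 container."""


class ShapeMismatchError(SpectroCubeError):
    """Cube and label map (or target grid) shapes are inconsistent."""


class UnknownClassError(SpectroCubeError):
    """A label or class name is outside the declared scheme."""


# Original annotation of the colorectal mouse dataset, in declared order;
# class codes are 0-based indices into this list.
ORIGINAL_CLASSES: tuple[str, ...] = (
    "carcinoma",
    "adenoma",
    "hyperplasia",
    "normal",
    "spectroscopic artifact",
    "other tissue",
    "question",
    "zero",
)


@dataclass
class HyperCube:
    """One scan's intensities (H×W×B) plus its spectral axis and identity.

    Parameters
    ----------
    intensities
        3D float array, two spatial axes then the spectral axis.
    axis
        Length-B strictly increasing spectral coordinate (wavenumber cm⁻¹ or
        wavelength nm).
    scan_id, subject_id
        Opaque identifiers; subject_id groups scans for leak-free
        cross-validation.
    """

    intensities: np.ndarray
    axis: np.ndarray
    scan_id: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        self.axis = np.asarray(self.axis, dtype=np.float64)
        if self.intensities.ndim != 3:
            raise ShapeMismatchError(
                f"intensities must be 3D (H, W, B), got {self.intensities.ndim}D"
            )
        h, w, b = self.intensities.shape
        if h < 1 or w < 1 or b < 2:
            raise ShapeMismatchError(f"degenerate cube shape {(h, w, b)}")
        if self.axis.shape != (b,):
            raise ShapeMismatchError(
                f"axis length {self.axis.shape} does not match B={b}"
            )
        if not np.all(np.diff(self.axis) > 0):
            raise ContainerError("spectral axis must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise ContainerError("intensities contain non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape  # type: ignore[return-value]

    @property
    def n_bands(self) -> int:
        return self.intensities.shape[2]


@dataclass
class LabelMap:
    """Per-pixel class codes aligned to a cube, with class names and masking.

    ``masked_classes`` are the codes whose spectra are zeroed (rest/others);
    they are excluded from evaluation metrics but still present in maps.
    """

    labels: np.ndarray
    class_names: tuple[str, ...]
    masked_classes: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.class_names = tuple(self.class_names)
        self.masked_classes = tuple(sorted(set(int(m) for m in self.masked_classes)))
        if self.labels.ndim != 2:
            raise ShapeMismatchError("labels must be a 2D map")
        if not np.issubdtype(self.labels.dtype, np.integer):
            self.labels = self.labels.astype(np.int16)
        n = len(self.class_names)
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= n):
            raise UnknownClassError(
                f"label codes outside 0..{n - 1} for classes {self.class_names}"
            )
        if any(m < 0 or m >= n for m in self.masked_classes):
            raise UnknownClassError("masked_classes outside declared class range")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def counts(self) -> dict[str, int]:
        """Pixel count per class name (zero for absent classes)."""
        c = np.bincount(self.labels.ravel(), minlength=len(self.class_names))
        return {name: int(c[i]) for i, name in enumerate(self.class_names)}


@dataclass(frozen=True)
class TaskScheme:
    """A relabeling of the original classes for one detection task.

    ``mapping`` must be total over the original class list; every class in
    ``zeroed`` maps to the task's single rest/others class, whose spectra are
    set to zero by :func:`relabel`.
    """

    name: str
    mapping: Mapping[str, str]
    zeroed: frozenset[str]
    task_classes: tuple[str, ...]

    def __post_init__(self) -> None:
        missing = [c for c in ORIGINAL_CLASSES if c not in self.mapping]
        if missing:
            raise UnknownClassError(f"scheme {self.name!r} misses classes {missing}")
        targets = {self.mapping[c] for c in self.zeroed}
        if self.zeroed and len(targets) != 1:
            raise UnknownClassError(
                "zeroed classes must merge into exactly one task class"
            )
        bad = [t for t in self.mapping.values() if t not in self.task_classes]
        if bad:
            raise UnknownClassError(f"mapping targets not in task_classes: {bad}")

    @property
    def masked_task_classes(self) -> tuple[int, ...]:
        zt = {self.mapping[c] for c in self.zeroed}
        return tuple(i for i, t in enumerate(self.task_classes) if t in zt)


EPITHELIAL_SCHEME = TaskScheme(
    name="epithelial",
    mapping={
        "carcinoma": "epithelial tissue",
        "adenoma": "epithelial tissue",
        "hyperplasia": "epithelial tissue",
        "normal": "epithelial tissue",
        "spectroscopic artifact": "spectroscopic artifact",
        "other tissue": "other tissue",
        "question": "rest class",
        "zero": "rest class",
    },
    zeroed=frozenset({"question", "zero"}),
    task_classes=(
        "epithelial tissue",
        "spectroscopic artifact",
        "other tissue",
        "rest class",
    ),
)

COLORECTAL_SCHEME = TaskScheme(
    name="colorectal",
    mapping={
        "carcinoma": "carcinoma",
        "adenoma": "adenoma",
        "hyperplasia": "hyperplasia",
        "normal": "normal",
        "spectroscopic artifact": "others",
        "other tissue": "others",
        "question": "others",
        "zero": "others",
    },
    zeroed=frozenset(
        {"spectroscopic artifact", "other tissue", "question", "zero"}
    ),
    task_classes=("carcinoma", "adenoma", "hyperplasia", "normal", "others"),
)

SCHEMES: dict[str, TaskScheme] = {
    "epithelial": EPITHELIAL_SCHEME,
    "colorectal": COLORECTAL_SCHEME,
}


# ---------------------------------------------------------------------------
# HDF5 container
# ---------------------------------------------------------------------------

def write_scan(path, cube: HyperCube, labels: LabelMap, mode: str = "a") -> None:
    """Write one scan into the container at ``path`` (group /scans/<scan_id>)."""
    if cube.intensities.shape[:2] != labels.shape:
        raise ShapeMismatchError(
            f"cube grid {cube.intensities.shape[:2]} != labels {labels.shape}"
        )
    with h5py.File(path, mode) as f:
        grp = f.require_group("scans")
        if cube.scan_id in grp:
            del grp[cube.scan_id]
        g = grp.create_group(cube.scan_id)
        g.create_dataset("intensities", data=cube.intensities.astype(np.float32))
        g.create_dataset("labels", data=labels.labels.astype(np.int16))
        g.create_dataset("axis", data=cube.axis.astype(np.float64))
        g.attrs["subject_id"] = cube.subject_id
        g.attrs["class_names"] = list(labels.class_names)
        g.attrs["masked_classes"] = list(labels.masked_classes)


def read_scan(path, scan_id: str) -> tuple[HyperCube, LabelMap]:
    """Read one scan back from a container written by :func:`write_scan`."""
    with h5py.File(path, "r") as f:
        key = f"scans/{scan_id}"
        if key not in f:
            raise ContainerError(f"scan {scan_id!r} not found in {path}")
        g = f[key]
        for ds in ("intensities", "labels", "axis"):
            if ds not in g:
                raise ContainerError(f"dataset {ds!r} missing for scan {scan_id!r}")
        intensities = g["intensities"][()]
        label_arr = g["labels"][()]
        axis = g["axis"][()]
        subject_id = str(g.attrs.get("subject_id", ""))
        class_names = [
            c.decode() if isinstance(c, bytes) else str(c)
            for c in g.attrs.get("class_names", [])
        ]
        masked = [int(m) for m in g.attrs.get("masked_classes", [])]
    if intensities.ndim != 3 or label_arr.shape != intensities.shape[:2]:
        raise ShapeMismatchError(
            f"scan {scan_id!r}: labels {label_arr.shape} vs cube "
            f"{intensities.shape}"
        )
    cube = HyperCube(intensities, axis, scan_id=scan_id, subject_id=subject_id)
    labels = LabelMap(label_arr, tuple(class_names), tuple(masked))
    return cube, labels


def list_scans(path) -> list[str]:
    """Scan ids present in a container, sorted."""
    with h5py.File(path, "r") as f:
        if "scans" not in f:
            return []
        return sorted(f["scans"].keys())


def read_dataset(path) -> list[tuple[HyperCube, LabelMap]]:
    """Read every scan in a container."""
    return [read_scan(path, sid) for sid in list_scans(path)]


# ---------------------------------------------------------------------------
# Zero padding and relabeling
# ---------------------------------------------------------------------------

def pad_to_grid(
    cube: HyperCube,
    labels: LabelMap,
    target: tuple[int, int],
    zero_class: int,
) -> tuple[HyperCube, LabelMap]:
    """Zero-pad a scan to a common grid size.

    The original data occupy the top-left block; padded pixels get all-zero
    spectra and label ``zero_class``.
    """
    h, w, b = cube.shape
    h0, w0 = target
    if h > h0 or w > w0:
        raise ShapeMismatchError(f"cube {h}×{w} larger than target {h0}×{w0}")
    if not (0 <= zero_class < len(labels.class_names)):
        raise UnknownClassError(f"zero_class {zero_class} not a valid class code")
    if (h, w) == (h0, w0):
        return cube, labels
    out = np.zeros((h0, w0, b), dtype=cube.intensities.dtype)
    out[:h, :w, :] = cube.intensities
    lab = np.full((h0, w0), zero_class, dtype=labels.labels.dtype)
    lab[:h, :w] = labels.labels
    return (
        replace(cube, intensities=out),
        replace(labels, labels=lab),
    )


def relabel(
    labels: LabelMap, cube: HyperCube, scheme: TaskScheme
) -> tuple[HyperCube, LabelMap]:
    """Apply a task scheme: remap classes and zero the spectra of merged-away
    pixels.

    Class counts are conserved under the mapping; pixels whose task class is
    masked get all-zero spectra, all other spectra are returned bit-exactly.
    """
    for name in labels.class_names:
        if name not in scheme.mapping:
            raise UnknownClassError(
                f"class {name!r} not covered by scheme {scheme.name!r}"
            )
    lut = np.array(
        [scheme.task_classes.index(scheme.mapping[c]) for c in labels.class_names],
        dtype=np.int16,
    )
    new_labels = lut[labels.labels]
    masked = scheme.masked_task_classes
    new_int = cube.intensities.copy()
    if masked:
        zero_mask = np.isin(new_labels, masked)
        new_int[zero_mask] = 0
    return (
        replace(cube, intensities=new_int),
        LabelMap(new_labels, scheme.task_classes, masked),
    )


def map_counts(counts: Mapping[str, int], scheme: TaskScheme) -> dict[str, int]:
    """Aggregate per-class pixel counts under a task scheme (audit arithmetic)."""
    out = {t: 0 for t in scheme.task_classes}
    for name, n in counts.items():
        if name not in scheme.mapping:
            raise UnknownClassError(f"class {name!r} unknown to scheme {scheme.name!r}")
        out[scheme.mapping[name]] += int(n)
    return {t: n for t, n in out.items() if n > 0}


def counts_table(
    scans: Iterable[tuple[HyperCube, LabelMap]]
) -> pd.DataFrame:
    """Long-format per-scan class counts, for CSV audit export."""
    rows = []
    for cube, labels in scans:
        for name, n in labels.counts().items():
            rows.append(
                {"scan_id": cube.scan_id, "subject_id": cube.subject_id,
                 "class": name, "count": n}
            )
    return pd.DataFrame(rows, columns=["scan_id", "subject_id", "class", "count"])
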