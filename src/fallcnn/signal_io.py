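"""Accelerometer trace I/O, windowing, normalization and train/test splitting.

The unit of classifier input is a fixed-length ``Window`` — an L×3 matrix of
triaxial acceleration samples cut from a longer ``AccelTrace``.  Datasets are
flat collections of labeled windows; on disk they are a directory of
per-window CSV files plus a JSON manifest (see :func:`write_dataset`).

Conventions
-----------
* Labels: ``"fall"`` (positive class, encoded 1), ``"adl"`` (negative class,
  encoded 0), or ``"unlabeled"``.
* Acceleration units are whatever the sensor reported (g or m/s²); nothing
  here converts units, since values are min–max normalized before training.
* Windowing discards any trailing partial slice; nothing is padded.
* Min–max normalization is fitted per channel (x, y, z separately) on the
  training split only and applied unclipped to both splits, so held-out
  values may fall outside [0, 1].
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

LABEL_FALL = "fall"
LABEL_ADL = "adl"
LABEL_UNLABELED = "unlabeled"
_VALID_LABELS = (LABEL_FALL, LABEL_ADL, LABEL_UNLABELED)

# on-disk label encoding: fall = 1, adl = 0
_LABEL_TO_CODE = {LABEL_ADL: 0, LABEL_FALL: 1}
_CODE_TO_LABEL = {0: LABEL_ADL, 1: LABEL_FALL}


class SignalIOError(Exception):
    """Base class for trace/dataset I/O failures."""


class MissingFileError(SignalIOError):
    """Input file or directory does not exist."""


class MissingColumnError(SignalIOError):
    """A configured column is absent from the CSV header."""


class NonNumericValueError(SignalIOError):
    """An acceleration cell could not be parsed as a number."""


class EmptyTraceError(SignalIOError):
    """The input file contains no samples."""


@dataclass(frozen=True)
class CsvDialect:
    """Column mapping for accelerometer CSV files.

    Defaults match the package's own output: columns ``t,x,y,z`` plus an
    optional ``label`` column with fall=1, adl=0.
    """

    time: str = "t"
    x: str = "x"
    y: str = "y"
    z: str = "z"
    label: str | None = "label"


@dataclass
class AccelTrace:
    """A variable-length stream of timestamped triaxial acceleration samples.

    ``t`` is a non-decreasing 1-D array of time indices; ``xyz`` is the
    (n, 3) array of acceleration components, all finite.
    """

    t: np.ndarray
    xyz: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise SignalIOError(
                f"trace must have shape (n, 3), got {self.xyz.shape}"
            )
        if self.t.shape[0] != self.xyz.shape[0]:
            raise SignalIOError("time and acceleration arrays differ in length")
        if not np.all(np.isfinite(self.xyz)):
            raise SignalIOError("trace contains non-finite acceleration values")
        if self.t.size > 1 and np.any(np.diff(self.t) < 0):
            raise SignalIOError("sample times must be non-decreasing")

    def __len__(self) -> int:
        return self.xyz.shape[0]


@dataclass
class Window:
    """One fixed-length L×3 slice of acceleration values, optionally labeled.

    ``origin`` records provenance: ``"<trace id>@<offset>"`` for segmented
    windows, ``"synthetic"`` for simulated ones, ``"augmented:<parent>"`` for
    rotated copies.
    """

    values: np.ndarray
    label: str = LABEL_UNLABELED
    origin: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 3:
            raise SignalIOError(
                f"window must have shape (L, 3), got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise SignalIOError("window contains non-finite values")
        if self.label not in _VALID_LABELS:
            raise SignalIOError(f"unknown label {self.label!r}")

    @property
    def length(self) -> int:
        return self.values.shape[0]


@dataclass
class LabeledDataset:
    """A collection of equal-length windows with class bookkeeping."""

    windows: list[Window] = field(default_factory=list)

    def __post_init__(self) -> None:
        lengths = {w.length for w in self.windows}
        if len(lengths) > 1:
            raise SignalIOError(
                f"windows have inconsistent lengths: {sorted(lengths)}"
            )

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    @property
    def window_length(self) -> int | None:
        return self.windows[0].length if self.windows else None

    @property
    def class_counts(self) -> tuple[int, int]:
        """(n_fall, n_adl) tally of window labels."""
        n_fall = sum(1 for w in self.windows if w.label == LABEL_FALL)
        n_adl = sum(1 for w in self.windows if w.label == LABEL_ADL)
        return n_fall, n_adl

    def stacked(self) -> np.ndarray:
        """All windows as one (N, L, 3) array."""
        if not self.windows:
            raise SignalIOError("dataset is empty")
        return np.stack([w.values for w in self.windows])

    def labels(self) -> list[str]:
        return [w.label for w in self.windows]


def read_accel_csv(path: str | Path, dialect: CsvDialect | None = None) -> AccelTrace:
    """Read a triaxial accelerometer trace from a delimited text file.

    Row order is preserved.  Raises :class:`MissingFileError`,
    :class:`MissingColumnError`, :class:`NonNumericValueError` or
    :class:`EmptyTraceError` as distinct failures.
    """
    dialect = dialect or CsvDialect()
    path = Path(path)
    if not path.exists():
        raise MissingFileError(f"no such file: {path}")
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise EmptyTraceError(f"no samples in {path}") from None
    if frame.empty:
        raise EmptyTraceError(f"no samples in {path}")
    needed = [dialect.time, dialect.x, dialect.y, dialect.z]
    for col in needed:
        if col not in frame.columns:
            raise MissingColumnError(f"column {col!r} missing from {path}")
    cols = frame[[dialect.x, dialect.y, dialect.z]]
    numeric = cols.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~cols.isna()
    if bad.any().any() or numeric.isna().any().any():
        row = int(numeric.isna().any(axis=1).idxmax())
        raise NonNumericValueError(
            f"non-numeric acceleration value near row {row} of {path}"
        )
    t = pd.to_numeric(frame[dialect.time], errors="coerce")
    if t.isna().any():
        raise NonNumericValueError(f"non-numeric time value in {path}")
    return AccelTrace(t.to_numpy(), numeric.to_numpy(), source_id=path.stem)


def write_accel_csv(trace: AccelTrace, path: str | Path,
                    dialect: CsvDialect | None = None) -> None:
    """Write a trace as CSV with the dialect's column names."""
    dialect = dialect or CsvDialect()
    frame = pd.DataFrame({
        dialect.time: trace.t,
        dialect.x: trace.xyz[:, 0],
        dialect.y: trace.xyz[:, 1],
        dialect.z: trace.xyz[:, 2],
    })
    frame.to_csv(path, index=False)


def segment_windows(trace: AccelTrace, length: int,
                    stride: int | None = None) -> list[Window]:
    """Cut a trace into fixed-length windows at offsets 0, stride, 2·stride, …

    The default stride equals ``length`` (non-overlapping windows).  A
    trailing slice shorter than ``length`` is discarded; a trace shorter than
    one window yields an empty list.
    """
    if length < 1:
        raise ValueError("window length must be >= 1")
    stride = length if stride is None else stride
    if stride < 1:
        raise ValueError("stride must be >= 1")
    out: list[Window] = []
    for start in range(0, len(trace) - length + 1, stride):
        out.append(Window(
            trace.xyz[start:start + length].copy(),
            origin=f"{trace.source_id}@{start}",
        ))
    return out


@dataclass
class NormalizerParams:
    """Per-channel min and max fitted on a training set.

    A channel with ``min == max`` is degenerate: normalization maps it to 0.
    """

    minimum: np.ndarray  # shape (3,)
    maximum: np.ndarray  # shape (3,)

    def __post_init__(self) -> None:
        self.minimum = np.asarray(self.minimum, dtype=float).reshape(3)
        self.maximum = np.asarray(self.maximum, dtype=float).reshape(3)
        if np.any(self.maximum < self.minimum):
            raise SignalIOError("normalizer has max < min")

    @property
    def degenerate(self) -> np.ndarray:
        """Boolean mask of constant channels."""
        return self.maximum == self.minimum

    def to_dict(self) -> dict:
        return {"min": self.minimum.tolist(), "max": self.maximum.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizerParams":
        return cls(np.asarray(d["min"]), np.asarray(d["max"]))


def fit_min_max(train: LabeledDataset) -> NormalizerParams:
    """Per-channel extrema over every sample of every training window."""
    if len(train) == 0:
        raise SignalIOError("cannot fit normalizer on an empty dataset")
    stacked = train.stacked()  # (N, L, 3)
    return NormalizerParams(
        stacked.min(axis=(0, 1)),
        stacked.max(axis=(0, 1)),
    )


def apply_min_max(dataset: LabeledDataset,
                  params: NormalizerParams) -> LabeledDataset:
    """Map each value to (v − min)/(max − min), channel-wise.

    Values from the fitting set land in [0, 1]; values outside the fitted
    range (e.g. a held-out split) are NOT clipped.  Degenerate channels map
    to 0.
    """
    span = params.maximum - params.minimum
    safe = np.where(span == 0, 1.0, span)
    out = []
    for w in dataset:
        v = (w.values - params.minimum) / safe
        v[:, params.degenerate] = 0.0
        out.append(Window(v, label=w.label, origin=w.origin))
    return LabeledDataset(out)


def invert_min_max(dataset: LabeledDataset,
                   params: NormalizerParams) -> LabeledDataset:
    """Inverse of :func:`apply_min_max` for non-degenerate channels."""
    span = params.maximum - params.minimum
    out = []
    for w in dataset:
        v = w.values * span + params.minimum
        out.append(Window(v, label=w.label, origin=w.origin))
    return LabeledDataset(out)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def split_dataset(dataset: LabeledDataset, train_fraction: float,
                  seed: int) -> tuple[LabeledDataset, LabeledDataset]:
    """Shuffle with a seeded generator and partition into train/test.

    Train size is ``round(train_fraction · N)`` (half away from zero); the
    test split takes the remainder.  The two splits are disjoint and their
    union is the input.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    if len(dataset) == 0:
        raise SignalIOError("cannot split an empty dataset")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(dataset))
    n_train = _round_half_away(train_fraction * len(dataset))
    train = LabeledDataset([dataset.windows[i] for i in order[:n_train]])
    test = LabeledDataset([dataset.windows[i] for i in order[n_train:]])
    return train, test


# ---------------------------------------------------------------------------
# dataset persistence: directory of per-window CSVs + JSON manifest

MANIFEST_NAME = "manifest.json"


def write_dataset(dataset: LabeledDataset, directory: str | Path) -> Path:
    """Persist a dataset as ``<dir>/window_00000.csv`` … plus a manifest.

    The manifest records window_length, class_counts and per-window label,
    origin and filename; the per-window CSVs hold t,x,y,z rows.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, w in enumerate(dataset):
        name = f"window_{i:05d}.csv"
        trace = AccelTrace(np.arange(w.length), w.values, source_id=name)
        write_accel_csv(trace, directory / name)
        entries.append({
            "file": name,
            "label": _LABEL_TO_CODE.get(w.label, -1),
            "origin": w.origin,
        })
    n_fall, n_adl = dataset.class_counts
    manifest = {
        "format": "fallcnn-dataset-v1",
        "window_length": dataset.window_length,
        "class_counts": {"fall": n_fall, "adl": n_adl},
        "windows": entries,
    }
    path = directory / MANIFEST_NAME
    path.write_text(json.dumps(manifest, indent=1))
    return path


def read_dataset(manifest_path: str | Path) -> LabeledDataset:
    """Load a dataset written by :func:`write_dataset`.

    ``manifest_path`` may be the manifest file or its directory.
    """
    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / MANIFEST_NAME
    if not manifest_path.exists():
        raise MissingFileError(f"no such manifest: {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    directory = manifest_path.parent
    windows = []
    for entry in manifest["windows"]:
        trace = read_accel_csv(directory / entry["file"])
        windows.append(Window(
            trace.xyz,
            label=_CODE_TO_LABEL.get(entry["label"], LABEL_UNLABELED),
            origin=entry.get("origin", ""),
        ))
    ds = LabeledDataset(windows)
    expected = manifest.get("window_length")
    if expected is not None and ds.window_length != expected:
        raise SignalIOError(
            f"manifest window_length {expected} does not match data"
        )
    return ds
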