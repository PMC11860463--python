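"""Data model and file I/O for incomplete two-view datasets.

A dataset is two per-view feature matrices over the same N samples, an
N x 2 binary availability mask (1 = the view was observed for that
sample) and an optional integer label vector. Masked-out rows are stored
as zeros on disk but are semantically undefined: consumers must select
rows by mask, never by sentinel value, and every computation in this
package does so.

On-disk layouts
---------------
Directory: ``view1.csv``, ``view2.csv``, ``mask.csv``, optional
``labels.csv`` — comma-delimited, no header, '.' decimal, samples as
rows. Single file: an HDF5 container with datasets of the same names.
Floats are written with 17 significant digits so a save/load round trip
is bit-exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

from .errors import ParameterError, StructuralError, ValidationError

_CSV_FMT = "%.17g"


@dataclass
class MissingSpec:
    """How to knock views out of a complete dataset.

    The only scheme is the two-view clinical one: an affected sample
    loses exactly ONE of its two views, chosen uniformly; at
    ``missing_rate`` 1.0 every sample keeps exactly one view, at 0.0 the
    data stay complete.
    """

    missing_rate: float
    seed: int
    scheme: str = "one-view-per-missing-sample"

    def __post_init__(self):
        if not 0.0 <= float(self.missing_rate) <= 1.0:
            raise ParameterError(
                f"missing_rate must be in [0, 1], got {self.missing_rate}"
            )
        if self.scheme != "one-view-per-missing-sample":
            raise ParameterError(f"unknown missing scheme {self.scheme!r}")


@dataclass
class IncompleteMultiviewDataset:
    """Two view matrices (N x D1, N x D2), an N x 2 mask, optional labels."""

    views: list
    mask: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.views = [np.asarray(v, dtype=np.float64) for v in self.views]
        if len(self.views) != 2:
            raise StructuralError(
                f"exactly two views are supported, got {len(self.views)}"
            )
        self.mask = np.asarray(self.mask)
        n = self.views[0].shape[0]
        for v, mat in enumerate(self.views, start=1):
            if mat.ndim != 2:
                raise StructuralError(f"view{v} must be 2-D, got {mat.ndim}-D")
            if mat.shape[0] != n:
                raise StructuralError(
                    f"row-count mismatch: view1 has {n} rows, "
                    f"view{v} has {mat.shape[0]}"
                )
            if not np.all(np.isfinite(mat)):
                raise ValidationError(f"view{v} contains NaN or Inf entries")
        if self.mask.shape != (n, 2):
            raise StructuralError(
                f"mask must be {(n, 2)}, got {self.mask.shape}"
            )
        if not np.isin(self.mask, (0, 1)).all():
            raise ValidationError("mask entries must be 0 or 1")
        self.mask = self.mask.astype(np.int8)
        empty = np.flatnonzero(self.mask.sum(axis=1) == 0)
        if empty.size:
            raise ValidationError(
                f"sample {int(empty[0])} has no available view "
                f"(mask row is all zeros)"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (n,):
                raise StructuralError(
                    f"labels must have length {n}, got {self.labels.shape}"
                )
            self.labels = self.labels.astype(np.int64)

    # ---- basic facts ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.views[0].shape[0]

    @property
    def n_views(self) -> int:
        return 2

    @property
    def is_complete(self) -> bool:
        return bool(self.mask.all())

    @property
    def n_paired(self) -> int:
        """Samples with both views available."""
        return int((self.mask.sum(axis=1) == 2).sum())

    def available_rows(self, view: int) -> np.ndarray:
        """Indices of samples for which ``view`` (0 or 1) is observed."""
        return np.flatnonzero(self.mask[:, view] == 1)

    def view_rows(self, view: int) -> np.ndarray:
        """The observed rows of a view — the only sanctioned access path."""
        return self.views[view][self.available_rows(view)]


def apply_missing(dataset: IncompleteMultiviewDataset,
                  spec: MissingSpec) -> IncompleteMultiviewDataset:
    """Mask exactly ``round(rate * N)`` samples, each losing one view.

    Deterministic given ``spec.seed``; the input must be complete. The
    features are shared with the input (only the mask is new) — masked
    entries are never rewritten because consumers never read them.
    """
    if not dataset.is_complete:
        raise ValidationError("apply_missing requires a complete dataset")
    n = dataset.n_samples
    n_missing = int(np.rint(spec.missing_rate * n))
    rng = np.random.default_rng(spec.seed)
    rows = rng.choice(n, size=n_missing, replace=False)
    dropped_view = rng.integers(0, 2, size=n_missing)
    mask = np.ones((n, 2), dtype=np.int8)
    mask[rows, dropped_view] = 0
    return IncompleteMultiviewDataset(
        views=[v.copy() for v in dataset.views],
        mask=mask,
        labels=None if dataset.labels is None else dataset.labels.copy(),
    )


# ---- persistence -------------------------------------------------------

def save_dataset(dataset: IncompleteMultiviewDataset, path) -> Path:
    """Write to a directory of CSVs, or to one HDF5 file if ``path`` ends
    in ``.h5``/``.hdf5``. Masked rows are written as zeros."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            for v, mat in enumerate(dataset.views, start=1):
                f.create_dataset(f"view{v}", data=_zero_masked(dataset, v - 1))
            f.create_dataset("mask", data=dataset.mask.astype(np.int64))
            if dataset.labels is not None:
                f.create_dataset("labels", data=dataset.labels)
        return path
    path.mkdir(parents=True, exist_ok=True)
    for v in (1, 2):
        np.savetxt(path / f"view{v}.csv", _zero_masked(dataset, v - 1),
                   fmt=_CSV_FMT, delimiter=",")
    np.savetxt(path / "mask.csv", dataset.mask, fmt="%d", delimiter=",")
    if dataset.labels is not None:
        np.savetxt(path / "labels.csv", dataset.labels, fmt="%d",
                   delimiter=",")
    return path


def _zero_masked(dataset, view):
    out = dataset.views[view].copy()
    out[dataset.mask[:, view] == 0] = 0.0
    return out


def load_dataset(path) -> IncompleteMultiviewDataset:
    """Load from the directory or HDF5 layout written by `save_dataset`."""
    path = Path(path)
    if path.is_file() and path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            views = [np.asarray(f["view1"]), np.asarray(f["view2"])]
            mask = np.asarray(f["mask"])
            labels = np.asarray(f["labels"]) if "labels" in f else None
        return IncompleteMultiviewDataset(views, mask, labels)
    if not path.is_dir():
        raise StructuralError(f"{path} is neither a directory nor an HDF5 file")
    views = [_load_matrix(path / f"view{v}.csv") for v in (1, 2)]
    mask = _load_matrix(path / "mask.csv")
    labels_path = path / "labels.csv"
    labels = None
    if labels_path.exists():
        labels = _load_matrix(labels_path).ravel()
    return IncompleteMultiviewDataset(views, mask, labels)


def _load_matrix(path: Path) -> np.ndarray:
    if not path.exists():
        raise StructuralError(f"missing required file {path}")
    arr = np.loadtxt(path, delimiter=",", ndmin=2)
    return arr
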