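"""Shared data model, volume I/O, standardization, and the searchlight engine.

All analysis modules operate on the same in-memory currency: a
:class:`SubjectTimeSeries` holding one subject's (time x unit) response
matrix, and a :class:`MultiSubjectDataset` holding an aligned group of them.
``unit`` generalizes voxel: a column may be a voxel, a parcel, or any other
feature with a time course.  Volumes on disk are NIfTI-1; matrices may also
be read from plain TSV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Literal

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "DegenerateDataWarning",
    "SubjectTimeSeries",
    "MultiSubjectDataset",
    "VolumeGeometry",
    "SearchlightSpec",
    "zscore_time",
    "read_volume",
    "write_volume",
    "read_matrix",
    "save_dataset",
    "load_dataset",
    "searchlight",
    "n_unit_pairs",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


class DegenerateDataWarning(UserWarning):
    """Signals zero-variance units or other degenerate-but-tolerated input."""


@dataclass
class SubjectTimeSeries:
    """One subject's neural response matrix.

    Parameters
    ----------
    data : ndarray, shape (T, V)
        Response of V units over T timepoints (TRs). Must be finite,
        with T >= 2 and V >= 1.
    tr_seconds : float
        Sampling interval (repetition time) in seconds; must be positive.
    subject_id : str
        Identifier used in reports and error messages.
    unit_labels : list of str, optional
        Optional names for the V columns.
    """

    data: np.ndarray
    tr_seconds: float
    subject_id: str = "subject"
    unit_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError(
                f"data must be 2-D (time x unit), got ndim={self.data.ndim}"
            )
        t, v = self.data.shape
        if t < 2 or v < 1:
            raise ValidationError(f"need T >= 2 and V >= 1, got T={t}, V={v}")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError(f"non-finite values in data of {self.subject_id!r}")
        if not (np.isfinite(self.tr_seconds) and self.tr_seconds > 0):
            raise ValidationError(f"tr_seconds must be positive, got {self.tr_seconds}")
        if self.unit_labels is not None and len(self.unit_labels) != v:
            raise ValidationError("unit_labels length must equal V")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_units(self) -> int:
        return self.data.shape[1]


@dataclass
class MultiSubjectDataset:
    """Ordered collection of subjects recorded under a common time base.

    ``units_aligned`` requires every subject to have the same V (needed by
    ISC/ISFC, where column v must mean the same thing in every brain);
    ``time_aligned_only`` permits differing V (sufficient for the shared
    response model, which learns its own per-subject spatial basis).
    """

    subjects: list[SubjectTimeSeries]
    alignment_mode: Literal["units_aligned", "time_aligned_only"] = "units_aligned"

    def __post_init__(self) -> None:
        if len(self.subjects) < 2:
            raise ValidationError("need at least 2 subjects")
        t0 = self.subjects[0].n_timepoints
        if any(s.n_timepoints != t0 for s in self.subjects):
            raise ValidationError("all subjects must share the same T")
        if self.alignment_mode == "units_aligned":
            v0 = self.subjects[0].n_units
            if any(s.n_units != v0 for s in self.subjects):
                raise ValidationError(
                    "units_aligned dataset requires identical V across subjects"
                )
        elif self.alignment_mode != "time_aligned_only":
            raise ValidationError(f"unknown alignment_mode {self.alignment_mode!r}")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_timepoints(self) -> int:
        return self.subjects[0].n_timepoints

    @property
    def n_units(self) -> int:
        if self.alignment_mode != "units_aligned":
            raise ValidationError("n_units undefined unless units_aligned")
        return self.subjects[0].n_units

    def stack(self) -> np.ndarray:
        """Return an (N, T, V) array; requires units_aligned."""
        if self.alignment_mode != "units_aligned":
            raise ValidationError("stack() requires units_aligned")
        return np.stack([s.data for s in self.subjects])

    def restrict_units(self, columns: np.ndarray) -> "MultiSubjectDataset":
        """Sub-dataset keeping only the given unit columns (units_aligned)."""
        subs = [
            SubjectTimeSeries(
                s.data[:, columns], s.tr_seconds, s.subject_id,
                [s.unit_labels[c] for c in columns] if s.unit_labels else None,
            )
            for s in self.subjects
        ]
        return MultiSubjectDataset(subs, "units_aligned")


@dataclass
class VolumeGeometry:
    """Links matrix columns back to voxel coordinates.

    In-mask voxels are serialized in ascending linear index with x fastest
    (Fortran order); this fixed convention makes volume round trips exact
    and is shared by the searchlight and NIfTI I/O.
    """

    dims: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.dims = tuple(int(d) for d in self.dims)
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        self.mask = np.asarray(self.mask, dtype=bool)
        if len(self.dims) != 3 or any(d < 1 for d in self.dims):
            raise ValidationError("dims must be a positive integer triple")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValidationError("voxel sizes must be positive")
        if self.mask.shape != self.dims:
            raise ValidationError(
                f"mask shape {self.mask.shape} does not match dims {self.dims}"
            )
        if not self.mask.any():
            raise ValidationError("empty mask")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def mask_coordinates(self) -> np.ndarray:
        """(V, 3) integer voxel coordinates in serialization order."""
        flat = np.flatnonzero(self.mask.ravel(order="F"))
        return np.column_stack(np.unravel_index(flat, self.dims, order="F"))


@dataclass
class SearchlightSpec:
    """Neighborhood definition for the moving-window engine."""

    radius_voxels: int = 1
    shape: Literal["cube", "ball"] = "cube"
    min_units: int = 1

    def __post_init__(self) -> None:
        if self.radius_voxels < 0:
            raise ValidationError("radius must be non-negative")
        if self.min_units < 1:
            raise ValidationError("min_units must be positive")
        if self.shape not in ("cube", "ball"):
            raise ValidationError(f"unknown searchlight shape {self.shape!r}")


def zscore_time(ts: SubjectTimeSeries) -> SubjectTimeSeries:
    """Standardize each unit's time series to mean 0, population sd 1.

    Zero-variance units are returned as all-zeros and reported via a
    :class:`DegenerateDataWarning`. Population (1/T) variance is used so
    that Pearson-correlation identities on standardized data are exact.
    """
    x = ts.data
    mu = x.mean(axis=0)
    sd = x.std(axis=0)  # population
    dead = sd == 0
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} zero-variance unit(s) in {ts.subject_id!r} "
            "set to zero",
            DegenerateDataWarning,
            stacklevel=2,
        )
    safe = np.where(dead, 1.0, sd)
    z = (x - mu) / safe
    z[:, dead] = 0.0
    return SubjectTimeSeries(z, ts.tr_seconds, ts.subject_id, ts.unit_labels)


# ---------------------------------------------------------------------------
# Volume I/O


def _flat_mask(mask: np.ndarray) -> np.ndarray:
    return np.flatnonzero(np.asarray(mask, bool).ravel(order="F"))


def read_volume(
    path: str,
    mask_path: str,
    tr_seconds: float,
    subject_id: str = "subject",
) -> tuple[SubjectTimeSeries, VolumeGeometry]:
    """Load a 4-D NIfTI volume and 3-D mask into a (T, V) matrix.

    Columns are in-mask voxels in ascending Fortran linear index (x fastest).
    """
    img = nib.load(path)
    mimg = nib.load(mask_path)
    data = np.asanyarray(img.dataobj)
    mask = np.asanyarray(mimg.dataobj).astype(bool)
    if data.ndim != 4:
        raise ValidationError(f"expected a 4-D image, got ndim={data.ndim}")
    if mask.ndim != 3 or mask.shape != data.shape[:3]:
        raise ValidationError(
            f"grid mismatch: image {data.shape[:3]} vs mask {mask.shape}"
        )
    if not mask.any():
        raise ValidationError("empty mask")
    zooms = img.header.get_zooms()[:3]
    geom = VolumeGeometry(data.shape[:3], zooms, mask)
    flat = _flat_mask(mask)
    t = data.shape[3]
    matrix = data.reshape(-1, t, order="F")[flat].T.astype(float)
    return SubjectTimeSeries(matrix, tr_seconds, subject_id), geom


def write_volume(path: str, ts: SubjectTimeSeries, geometry: VolumeGeometry) -> None:
    """Write a (T, V) matrix back to a 4-D NIfTI volume (zeros off-mask)."""
    if ts.n_units != geometry.n_voxels:
        raise ValidationError(
            f"V={ts.n_units} does not match mask voxel count {geometry.n_voxels}"
        )
    t = ts.n_timepoints
    vol = np.zeros((int(np.prod(geometry.dims)), t))
    vol[_flat_mask(geometry.mask)] = ts.data.T
    vol = vol.reshape(*geometry.dims, t, order="F")
    affine = np.diag(list(geometry.voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(vol, affine)
    img.header.set_zooms(tuple(geometry.voxel_size_mm) + (ts.tr_seconds,))
    nib.save(img, path)


def read_matrix(path: str, tr_seconds: float, subject_id: str = "subject") -> SubjectTimeSeries:
    """Read a T x V TSV matrix (header optional) as a SubjectTimeSeries."""
    with open(path) as fh:
        first = fh.readline()
    has_header = any(
        not _is_number(tok) for tok in first.strip().split("\t") if tok
    )
    df = pd.read_csv(path, sep="\t", header=0 if has_header else None)
    labels = [str(c) for c in df.columns] if has_header else None
    return SubjectTimeSeries(df.to_numpy(float), tr_seconds, subject_id, labels)


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def save_dataset(path: str, dataset: MultiSubjectDataset) -> None:
    """Store a dataset as a compressed multi-array container (.npz)."""
    arrays = {
        f"subject_{i:04d}": s.data for i, s in enumerate(dataset.subjects)
    }
    arrays["tr_seconds"] = np.array([s.tr_seconds for s in dataset.subjects])
    arrays["subject_ids"] = np.array([s.subject_id for s in dataset.subjects])
    arrays["alignment_mode"] = np.array(dataset.alignment_mode)
    np.savez_compressed(path, **arrays)


def load_dataset(path: str) -> MultiSubjectDataset:
    with np.load(path, allow_pickle=False) as z:
        keys = sorted(
            k for k in z.files if k.startswith("subject_") and k[8:].isdigit()
        )
        trs = z["tr_seconds"]
        ids = z["subject_ids"]
        mode = str(z["alignment_mode"])
        subs = [
            SubjectTimeSeries(z[k], float(trs[i]), str(ids[i]))
            for i, k in enumerate(keys)
        ]
    return MultiSubjectDataset(subs, mode)  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# Searchlight


class SearchlightError(RuntimeError):
    """Wraps an exception raised by the neighborhood statistic, tagged with
    the center voxel coordinate."""

    def __init__(self, coordinate: tuple[int, int, int], cause: BaseException):
        self.coordinate = coordinate
        super().__init__(f"searchlight statistic failed at voxel {coordinate}: {cause}")


def _neighborhood_offsets(radius: int, shape: str) -> np.ndarray:
    r = np.arange(-radius, radius + 1)
    grid = np.stack(np.meshgrid(r, r, r, indexing="ij"), axis=-1).reshape(-1, 3)
    if shape == "ball":
        grid = grid[(grid**2).sum(axis=1) <= radius**2]
    return grid


def searchlight(
    dataset: MultiSubjectDataset,
    geometry: VolumeGeometry,
    spec: SearchlightSpec,
    fn: Callable[[MultiSubjectDataset], float],
) -> np.ndarray:
    """Apply ``fn`` to the local neighborhood of every in-mask voxel.

    Returns a 3-D map of ``fn`` values (NaN off-mask and wherever the
    neighborhood holds fewer than ``spec.min_units`` in-mask voxels).
    Neighborhoods are truncated at the volume edge, never wrapped: the
    window ends where the brain ends.
    """
    if dataset.alignment_mode != "units_aligned":
        raise ValidationError("searchlight requires a units_aligned dataset")
    if dataset.n_units != geometry.n_voxels:
        raise ValidationError("dataset V does not match geometry voxel count")
    dims = geometry.dims
    # map voxel coordinate -> column index in the data matrices
    col_of = np.full(dims, -1, dtype=int)
    coords = geometry.mask_coordinates()
    col_of[tuple(coords.T)] = np.arange(len(coords))

    offsets = _neighborhood_offsets(spec.radius_voxels, spec.shape)
    out = np.full(dims, np.nan)
    for cx, cy, cz in coords:
        pts = offsets + (cx, cy, cz)
        ok = np.all((pts >= 0) & (pts < dims), axis=1)  # truncate at edges
        pts = pts[ok]
        cols = col_of[tuple(pts.T)]
        cols = np.sort(cols[cols >= 0])
        if len(cols) < spec.min_units:
            continue
        sub = dataset.restrict_units(cols)
        try:
            out[cx, cy, cz] = fn(sub)
        except Exception as exc:  # noqa: BLE001 - re-raised with location
            raise SearchlightError((int(cx), int(cy), int(cz)), exc) from exc
    return out


def n_unit_pairs(n_units: int) -> int:
    """Number of unordered unit pairs C(V, 2).

    The size of a full unit-by-unit correlation analysis: e.g. a typical
    whole-brain voxel count of 30,000 yields ~4.5e8 pairs, which is why
    full-matrix approaches need dedicated engineering.
    """
    if n_units < 0:
        raise ValidationError("n_units must be non-negative")
    return n_units * (n_units - 1) // 2
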