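"""Impact of physiological signals on functional connectivity.

Functional connectivity (FC) is the Pearson correlation between regional
BOLD time series.  To quantify how much of it is carried by slow physiology,
ROI (or voxel) time series are compared before and after projecting out a
nuisance subspace — the convolved RV/HR regressor basis, optionally together
with the six rigid-body head-motion parameters and their backward first
differences — by per-row ordinary least squares.
"""

from __future__ import annotations

import warnings

import numpy as np
import nibabel as nib

from .response import RegressorSet

__all__ = [
    "NuisanceSet",
    "build_motion_nuisance",
    "project_out_nuisance",
    "fc_matrix",
    "seed_correlation_map",
]


class NuisanceSet:
    """T x K matrix of mean-centred nuisance columns with labels."""

    def __init__(self, columns: np.ndarray, labels: list[str] | None = None):
        columns = np.asarray(columns, dtype=float)
        if columns.ndim == 1:
            columns = columns[:, None]
        if columns.size:
            columns = columns - columns.mean(axis=0, keepdims=True)
        self.columns = columns
        self.labels = labels or [f"nuisance_{i}" for i in range(columns.shape[1])]
        if len(self.labels) != columns.shape[1]:
            raise ValueError("labels must match column count")

    @classmethod
    def empty(cls, n_frames: int) -> "NuisanceSet":
        return cls(np.empty((n_frames, 0)), labels=[])

    @classmethod
    def from_regressors(cls, *sets: RegressorSet) -> "NuisanceSet":
        cols = np.hstack([s.columns for s in sets])
        labels = [lab for s in sets for lab in s.labels]
        return cls(cols, labels)

    def combined_with(self, other: "NuisanceSet") -> "NuisanceSet":
        return NuisanceSet(
            np.hstack([self.columns, other.columns]), self.labels + other.labels
        )

    @property
    def n_frames(self) -> int:
        return self.columns.shape[0]

    @property
    def n_columns(self) -> int:
        return self.columns.shape[1]


def build_motion_nuisance(motion: np.ndarray) -> NuisanceSet:
    """Six rigid-body parameters plus backward first differences (leading 0)."""
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion must be T x 6")
    deriv = np.vstack([np.zeros((1, 6)), np.diff(motion, axis=0)])
    labels = [f"motion_{i}" for i in range(6)] + [f"motion_deriv_{i}" for i in range(6)]
    return NuisanceSet(np.hstack([motion, deriv]), labels)


def project_out_nuisance(ts: np.ndarray, nuisance: NuisanceSet) -> np.ndarray:
    """Per-row OLS residual of an R x T matrix against [1, nuisance].

    An empty nuisance set reduces to row-demeaning.  Residuals are orthogonal
    to every retained column.  Dependent columns are harmless (the
    least-squares solve projects onto the column space).
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim == 1:
        ts = ts[None, :]
    T = ts.shape[1]
    if nuisance.n_frames != T:
        raise ValueError("nuisance and data must share the time axis")
    if nuisance.n_columns >= T:
        raise ValueError("more nuisance columns than frames")
    design = np.column_stack([np.ones(T), nuisance.columns])
    beta, *_ = np.linalg.lstsq(design, ts.T, rcond=None)
    return ts - (design @ beta).T


def fc_matrix(ts: np.ndarray) -> np.ndarray:
    """R x R Pearson functional-connectivity matrix.

    Symmetric with unit diagonal; raises if any row is constant (correlation
    undefined).
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError("ts must be R x T")
    sds = ts.std(axis=1)
    bad = np.flatnonzero(sds == 0)
    if bad.size:
        raise ValueError(f"constant ROI time series at rows {bad.tolist()}")
    fc = np.corrcoef(ts)
    fc = (fc + fc.T) / 2.0
    np.fill_diagonal(fc, 1.0)
    return np.clip(fc, -1.0, 1.0)


def seed_correlation_map(
    seed_xyz: tuple[float, float, float],
    fmri: nib.Nifti1Image,
    nuisance: NuisanceSet | None = None,
    radius_mm: float = 0.0,
) -> np.ndarray:
    """Voxel-wise Pearson correlation with a seed time course.

    ``seed_xyz`` are world (MNI mm) coordinates; the seed series is the voxel
    nearest the coordinate, or the mean over a sphere of ``radius_mm`` when
    positive.  When a nuisance set is given it is projected out of the seed
    and every voxel before correlating.  Constant voxels map to 0.
    """
    data = np.asarray(fmri.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError("fmri must be 4-D")
    inv = np.linalg.inv(fmri.affine)
    ijk = inv @ np.array([*seed_xyz, 1.0])
    center = np.rint(ijk[:3]).astype(int)
    if np.any(center < 0) or np.any(center >= data.shape[:3]):
        raise ValueError(f"seed coordinate {seed_xyz} outside the volume")

    if radius_mm > 0:
        grid = np.stack(
            np.meshgrid(*[np.arange(s) for s in data.shape[:3]], indexing="ij"), axis=-1
        )
        world = nib.affines.apply_affine(fmri.affine, grid.reshape(-1, 3))
        dist = np.linalg.norm(world - np.asarray(seed_xyz), axis=1)
        mask = (dist <= radius_mm).reshape(data.shape[:3])
        seed_series = data[mask].mean(axis=0)
    else:
        seed_series = data[tuple(center)]

    T = data.shape[3]
    flat = data.reshape(-1, T)
    raw_seed_sd = float(np.std(seed_series))
    if nuisance is not None:
        seed_series = project_out_nuisance(seed_series, nuisance)[0]
        flat = project_out_nuisance(flat, nuisance)

    seed_c = seed_series - seed_series.mean()
    seed_sd = seed_c.std()
    if seed_sd <= 1e-10 * max(raw_seed_sd, 1.0):
        warnings.warn(
            "seed series is (near-)constant after nuisance projection; "
            "correlation map is degenerate",
            RuntimeWarning,
        )
        return np.zeros(data.shape[:3])
    flat_c = flat - flat.mean(axis=1, keepdims=True)
    sds = flat_c.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (flat_c @ seed_c) / (T * sds * seed_sd)
    corr[~np.isfinite(corr)] = 0.0
    return np.clip(corr, -1.0, 1.0).reshape(data.shape[:3])
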