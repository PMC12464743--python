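"""Multi-atlas parcellation and ROI time-series extraction.

Whole-brain fMRI is reduced to a channels-by-time matrix by averaging voxels
within regions of interest drawn from four published atlases composed on a
shared MNI152 grid: 400 cortical parcels, 72 white-matter bundle regions
(from a probabilistic tract atlas thresholded at 95% confidence), 16
subcortical regions and 9 brainstem arousal-network nuclei — 497 ROIs in
total.  ROI ids are global and contiguous from 1, ordered by atlas part and
within-part label.

Preprocessing of the extracted matrix follows the standard low-frequency
pipeline: per-row linear+quadratic detrend, zero-phase 0.01-0.15 Hz band-pass,
temporal downsampling by an integer factor, and z-normalisation.  Head-motion
regression is deliberately not part of this stage (apparent motion carries
respiratory information the downstream model can use).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .physio import bandpass_filter, znormalize

__all__ = [
    "AtlasPart",
    "AtlasBundle",
    "ROITimeseries",
    "compose_atlas",
    "extract_roi_timeseries",
    "preprocess_timeseries",
    "load_atlas_manifest",
    "write_roi_timeseries",
    "read_roi_timeseries",
]


@dataclass
class AtlasPart:
    """One constituent atlas volume.

    kind "labels": integer 3-D label map (0 = background).
    kind "probability": 4-D probability maps, one volume per region; a voxel
    belongs to the argmax region if that probability meets ``threshold``.
    """

    name: str
    image: nib.Nifti1Image
    kind: str = "labels"
    threshold: float = 0.95

    def __post_init__(self) -> None:
        if self.kind not in ("labels", "probability"):
            raise ValueError(f"unknown atlas part kind {self.kind!r}")


@dataclass
class AtlasBundle:
    """Composed multi-atlas parcellation on a single grid."""

    label_volume: np.ndarray           # int array, 0 = unlabeled
    affine: np.ndarray
    roi_index: pd.DataFrame            # roi_id, part, local_label, name
    voxel_counts: dict[int, int]
    overlap_voxels: int                # voxels claimed by >1 part

    @property
    def n_rois(self) -> int:
        return len(self.roi_index)

    @property
    def roi_ids(self) -> np.ndarray:
        return self.roi_index["roi_id"].to_numpy()


@dataclass
class ROITimeseries:
    """R x T matrix of parcel-mean BOLD signals."""

    data: np.ndarray
    dt: float
    roi_ids: np.ndarray
    preprocessed: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.roi_ids = np.asarray(self.roi_ids)
        if self.data.ndim != 2:
            raise ValueError("data must be R x T")
        if self.data.shape[0] != len(self.roi_ids):
            raise ValueError("row count must match roi_ids")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_rois(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]


def _part_assignments(part: AtlasPart) -> tuple[np.ndarray, list[int]]:
    """Voxel-wise local labels (0 = unassigned) and the sorted label list."""
    arr = np.asarray(part.image.dataobj)
    if part.kind == "labels":
        labels = np.rint(arr).astype(int)
        labels[labels < 0] = 0
        present = sorted(int(v) for v in np.unique(labels) if v != 0)
        return labels, present
    # probability: 4-D, one map per region
    if arr.ndim != 4:
        raise ValueError(f"probability atlas {part.name!r} must be 4-D")
    best = np.argmax(arr, axis=3)
    best_p = np.max(arr, axis=3)
    labels = np.where(best_p >= part.threshold, best + 1, 0)
    present = list(range(1, arr.shape[3] + 1))
    return labels, present


def compose_atlas(
    parts: list[AtlasPart],
    precedence: list[str] | None = None,
) -> AtlasBundle:
    """Compose atlas parts into one contiguous global labelling.

    All parts must share grid shape and affine (resample upstream otherwise).
    Voxels claimed by several parts go to the highest-precedence part
    (default precedence favours gray matter: any part named "cortical" then
    "subcortical" then "aan" then "white_matter", then listing order).
    Global ROI ids follow the listing order of ``parts`` and within-part
    label order.  Every composed ROI must retain at least one voxel.
    """
    if not parts:
        raise ValueError("no atlas parts given")
    shape3 = np.asarray(parts[0].image.dataobj).shape[:3]
    affine = parts[0].image.affine
    for p in parts:
        if np.asarray(p.image.dataobj).shape[:3] != shape3 or not np.allclose(
            p.image.affine, affine
        ):
            raise ValueError(f"atlas part {p.name!r} is on a different grid")

    default_order = ["cortical", "subcortical", "aan", "white_matter"]
    if precedence is None:
        precedence = sorted(
            (p.name for p in parts),
            key=lambda n: default_order.index(n)
            if n in default_order
            else len(default_order),
        )
    rank = {name: i for i, name in enumerate(precedence)}

    part_labels: dict[str, tuple[np.ndarray, list[int]]] = {
        p.name: _part_assignments(p) for p in parts
    }

    # assign global ids in listing order
    rows = []
    next_id = 1
    global_maps: dict[str, dict[int, int]] = {}
    for p in parts:
        labels, present = part_labels[p.name]
        mapping = {}
        for local in present:
            mapping[local] = next_id
            rows.append(
                {
                    "roi_id": next_id,
                    "part": p.name,
                    "local_label": local,
                    "name": f"{p.name}_{local}",
                }
            )
            next_id += 1
        global_maps[p.name] = mapping

    # compose with precedence: iterate from lowest to highest rank so the
    # highest-precedence part overwrites
    out = np.zeros(shape3, dtype=np.int32)
    claimed = np.zeros(shape3, dtype=np.int8)
    for p in sorted(parts, key=lambda q: rank.get(q.name, len(rank)), reverse=True):
        labels, _ = part_labels[p.name]
        mask = labels > 0
        claimed[mask] += 1
        lut = np.zeros(labels.max() + 1, dtype=np.int32)
        for local, gid in global_maps[p.name].items():
            lut[local] = gid
        out[mask] = lut[labels[mask]]

    overlap = int(np.sum(claimed > 1))
    index = pd.DataFrame(rows)
    counts = dict(zip(*np.unique(out[out > 0], return_counts=True)))
    counts = {int(k): int(v) for k, v in counts.items()}
    empty = [int(r) for r in index["roi_id"] if counts.get(int(r), 0) == 0]
    if empty:
        raise ValueError(f"ROIs empty after composition: {empty}")
    return AtlasBundle(
        label_volume=out,
        affine=affine,
        roi_index=index,
        voxel_counts=counts,
        overlap_voxels=overlap,
    )


def extract_roi_timeseries(
    fmri: nib.Nifti1Image, bundle: AtlasBundle, dt: float | None = None
) -> ROITimeseries:
    """Unweighted mean time series over the voxels of each composed ROI.

    ``dt`` defaults to the repetition time from the image header.  An ROI
    lying entirely outside the image field of view yields a NaN row and a
    warning.
    """
    data = np.asarray(fmri.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError("fmri must be a 4-D volume")
    if data.shape[:3] != bundle.label_volume.shape:
        raise ValueError(
            f"fMRI grid {data.shape[:3]} does not match atlas grid "
            f"{bundle.label_volume.shape}"
        )
    if dt is None:
        dt = float(fmri.header.get_zooms()[3])
    T = data.shape[3]
    flat_labels = bundle.label_volume.reshape(-1)
    flat = data.reshape(-1, T)
    out = np.full((bundle.n_rois, T), np.nan)
    for i, roi in enumerate(bundle.roi_ids):
        mask = flat_labels == roi
        if not np.any(mask):
            warnings.warn(f"ROI {roi} outside field of view", RuntimeWarning)
            continue
        out[i] = flat[mask].mean(axis=0)
    return ROITimeseries(data=out, dt=dt, roi_ids=bundle.roi_ids)


def detrend_quadratic(data: np.ndarray) -> np.ndarray:
    """Remove the per-row OLS fit of [1, t, t^2]."""
    data = np.asarray(data, dtype=float)
    T = data.shape[-1]
    t = np.arange(T, dtype=float)
    t = (t - t.mean()) / max(t.std(), 1.0)  # conditioning only
    basis = np.column_stack([np.ones(T), t, t**2])
    beta, *_ = np.linalg.lstsq(basis, data.T, rcond=None)
    return data - (basis @ beta).T


def preprocess_timeseries(
    ts: ROITimeseries,
    band: tuple[float, float] = (0.01, 0.15),
    downsample: int = 2,
) -> ROITimeseries:
    """Detrend (linear+quadratic), band-pass, decimate, z-normalise.

    Operations are applied in that order; decimation keeps frames
    ``0, f, 2f, ...`` so the output has ``ceil(T/f)`` frames and frame
    spacing ``dt * f``.
    """
    if ts.preprocessed:
        raise ValueError("time series already preprocessed")
    detrended = detrend_quadratic(ts.data)
    filtered = bandpass_filter(detrended, ts.dt, band=band, axis=-1)
    if downsample > 1:
        filtered = filtered[:, ::downsample]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        normalized = znormalize(filtered, axis=-1)
    return ROITimeseries(
        data=normalized,
        dt=ts.dt * downsample,
        roi_ids=ts.roi_ids,
        preprocessed=True,
    )


# ---------------------------------------------------------------------------
# Manifest and TSV I/O
# ---------------------------------------------------------------------------

def load_atlas_manifest(path: str | Path) -> tuple[list[AtlasPart], list[str] | None]:
    """Load atlas parts from a YAML manifest.

    Schema::

        precedence: [cortical, subcortical, aan, white_matter]   # optional
        parts:
          - name: cortical
            file: schaefer400.nii.gz
            kind: labels
          - name: white_matter
            file: pandora72.nii.gz
            kind: probability
            threshold: 0.95
    """
    path = Path(path)
    spec = yaml.safe_load(path.read_text())
    parts = []
    for entry in spec["parts"]:
        img = nib.load(str((path.parent / entry["file"]).resolve()))
        parts.append(
            AtlasPart(
                name=entry["name"],
                image=img,
                kind=entry.get("kind", "labels"),
                threshold=float(entry.get("threshold", 0.95)),
            )
        )
    return parts, spec.get("precedence")


def write_roi_timeseries(ts: ROITimeseries, path: str | Path,
                         provenance: dict | None = None) -> None:
    """ROIs-by-frames TSV plus JSON sidecar (dt, roi ids, provenance)."""
    path = Path(path)
    df = pd.DataFrame(ts.data, index=pd.Index(ts.roi_ids, name="roi_id"))
    df.to_csv(path, sep="\t")
    sidecar = {
        "dt": ts.dt,
        "roi_ids": [int(r) for r in ts.roi_ids],
        "preprocessed": ts.preprocessed,
        "provenance": provenance or {},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_roi_timeseries(path: str | Path) -> ROITimeseries:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return ROITimeseries(
        data=df.to_numpy(),
        dt=sidecar["dt"],
        roi_ids=np.asarray(sidecar["roi_ids"]),
        preprocessed=sidecar.get("preprocessed", False),
    )
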