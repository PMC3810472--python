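"""In-memory containers for 4D BOLD data and cohort manifests.

The pipeline operates on already-aligned data: a :class:`BoldDataset` holds a
masked 4D voxel time series together with its repetition time and group label.
Spatial preprocessing (realignment, normalisation, smoothing) is assumed to
have happened upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = ["BoldDataset", "load_bold", "save_bold", "read_manifest", "write_manifest"]


@dataclass
class BoldDataset:
    """Masked 4D BOLD-like volume.

    Parameters
    ----------
    data : (x, y, z, t) float array, arbitrary units.
    mask : (x, y, z) boolean volume of in-brain voxels.
    tr_seconds : repetition time in seconds.
    subject_id, group : cohort bookkeeping labels.
    """

    data: np.ndarray
    mask: np.ndarray
    tr_seconds: float
    subject_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 4:
            raise ValueError(f"data must be 4D (x,y,z,t), got shape {self.data.shape}")
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError(
                f"mask shape {self.mask.shape} incongruent with data {self.data.shape[:3]}"
            )
        if self.n_frames < 2:
            raise ValueError("a time series needs at least 2 frames")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        # fast path: all-finite volumes skip the expensive masked check
        if not np.all(np.isfinite(self.data)):
            if not np.isfinite(self.data).all(axis=3)[self.mask].all():
                raise ValueError("non-finite values inside the mask")

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def in_mask_series(self) -> np.ndarray:
        """Return the (n_voxels, n_frames) matrix of in-mask series.

        Voxels appear in C (row-major) flat order of the mask; the same order
        is used everywhere a flat voxel index is reported.
        """
        return self.data[self.mask]

    def with_data(self, data: np.ndarray) -> "BoldDataset":
        """Copy of this dataset with ``data`` replaced (same mask/metadata)."""
        return BoldDataset(
            data=data,
            mask=self.mask,
            tr_seconds=self.tr_seconds,
            subject_id=self.subject_id,
            group=self.group,
        )


def save_bold(dataset: BoldDataset, bold_path: str | Path, mask_path: str | Path | None = None) -> None:
    """Write a dataset (and optionally its mask) as NIfTI-1."""
    affine = np.eye(4)
    img = nib.Nifti1Image(dataset.data.astype(np.float32), affine)
    img.header.set_zooms((1.0, 1.0, 1.0, dataset.tr_seconds))
    nib.save(img, str(bold_path))
    if mask_path is not None:
        nib.save(nib.Nifti1Image(dataset.mask.astype(np.uint8), affine), str(mask_path))


def load_bold(
    bold_path: str | Path,
    mask_path: str | Path | None = None,
    tr_seconds: float | None = None,
    subject_id: str = "",
    group: str = "",
) -> BoldDataset:
    """Read a 4D NIfTI volume; the mask defaults to nonzero-variance voxels."""
    img = nib.load(str(bold_path))
    data = np.ascontiguousarray(np.asarray(img.dataobj, dtype=float))
    if tr_seconds is None:
        zooms = img.header.get_zooms()
        tr_seconds = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    else:
        mask = data.std(axis=3) > 0
    return BoldDataset(data=data, mask=mask, tr_seconds=tr_seconds,
                       subject_id=subject_id, group=group)


MANIFEST_COLUMNS = ["subject_id", "group", "bold_path", "motion_path"]


def write_manifest(rows: list[dict], path: str | Path) -> None:
    """Write a cohort manifest as TSV (subject_id, group, bold_path, motion_path)."""
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} lacks columns: {missing}")
    return df
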