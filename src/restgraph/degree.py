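"""Voxel-level degree centrality maps.

Every in-mask voxel is correlated with every other in-mask voxel; the degree
of a voxel is the count of correlations above an absolute threshold
(r > 0.25 by default — one-sided on signed r, so anti-correlations do not
count).  Degree maps are z-scored within the mask for averaging and
between-subject comparison, and a group hub map is obtained from a
voxelwise one-sample t-test of the z-degree maps.

The full voxel x voxel correlation matrix is never materialised: correlation
is computed in row blocks, so peak memory is O(block_size * n_voxels) while
the result is exactly independent of the block partition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .datasets import BoldDataset

__all__ = ["DegreeMap", "voxel_degree_map", "z_transform_map", "hub_map"]


@dataclass
class DegreeMap:
    """Voxel degree volume with optional z-scored companion."""

    degree: np.ndarray
    mask: np.ndarray
    r_threshold: float
    z_degree: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.degree.shape != self.mask.shape:
            raise ValueError("degree and mask volumes must be congruent")
        if not -1 < self.r_threshold < 1:
            raise ValueError("r_threshold must lie in (-1, 1)")


def voxel_degree_map(
    dataset: BoldDataset,
    r_threshold: float = 0.25,
    block_size: int = 1024,
    on_zero_variance: str = "error",
) -> DegreeMap:
    """Count, per voxel, the other in-mask voxels correlated above threshold.

    ``on_zero_variance`` controls what happens when an in-mask voxel has a
    constant series: ``"error"`` raises naming the voxel, ``"mask"`` drops
    such voxels from the mask before computing.
    """
    mask = dataset.mask.copy()
    X = dataset.data[mask].astype(float)
    sd = X.std(axis=1)
    if (sd == 0).any():
        bad = np.flatnonzero(sd == 0)
        if on_zero_variance == "mask":
            flat_idx = np.flatnonzero(mask.reshape(-1))
            mask.reshape(-1)[flat_idx[bad]] = False
            X = X[sd > 0]
            sd = sd[sd > 0]
        elif on_zero_variance == "error":
            raise ValueError(
                f"zero-variance series at in-mask voxel rows {bad.tolist()[:10]}"
            )
        else:
            raise ValueError(f"unknown on_zero_variance mode {on_zero_variance!r}")
    n_vox = X.shape[0]
    if n_vox < 2:
        raise ValueError("need at least 2 in-mask voxels")
    # unit-norm rows: correlation becomes a plain dot product; float32 is
    # ample for comparing r against a threshold and halves the gemm cost
    Xc = X - X.mean(axis=1, keepdims=True)
    Xc /= np.linalg.norm(Xc, axis=1, keepdims=True)
    Xc = Xc.astype(np.float32)
    counts = np.empty(n_vox, dtype=int)
    for start in range(0, n_vox, block_size):
        stop = min(start + block_size, n_vox)
        r_block = Xc[start:stop] @ Xc.T
        above = r_block > r_threshold
        # exclude self-pairs (self correlation is exactly 1 > threshold)
        above[np.arange(stop - start), np.arange(start, stop)] = False
        counts[start:stop] = above.sum(axis=1)
    degree = np.zeros(mask.shape, dtype=int)
    degree[mask] = counts
    return DegreeMap(degree=degree, mask=mask, r_threshold=r_threshold)


def z_transform_map(dmap: DegreeMap) -> DegreeMap:
    """Z-score the in-mask degrees (population SD); out-of-mask voxels stay 0."""
    vals = dmap.degree[dmap.mask].astype(float)
    sd = vals.std()  # population convention
    if sd == 0:
        raise ValueError("all in-mask degrees equal; z-transform undefined")
    z = np.zeros(dmap.degree.shape, dtype=float)
    z[dmap.mask] = (vals - vals.mean()) / sd
    return DegreeMap(degree=dmap.degree, mask=dmap.mask,
                     r_threshold=dmap.r_threshold, z_degree=z)


def hub_map(
    z_maps: list[DegreeMap], t_cutoff: float = 6.0
) -> tuple[np.ndarray, np.ndarray]:
    """Voxelwise one-sample t of z-degree against 0 across subjects.

    Returns ``(t_volume, hub_volume)`` where the hub volume marks voxels with
    t above ``t_cutoff``.  All maps must share one mask.
    """
    if len(z_maps) < 2:
        raise ValueError("need at least 2 subjects for a one-sample t-test")
    mask = z_maps[0].mask
    for m in z_maps[1:]:
        if not np.array_equal(m.mask, mask):
            raise ValueError("z-degree maps have incongruent masks")
    stacked = np.stack([m.z_degree[mask] for m in z_maps])  # (subjects, voxels)
    t, _ = sps.ttest_1samp(stacked, 0.0, axis=0)
    t_vol = np.zeros(mask.shape)
    t_vol[mask] = t
    return t_vol, (t_vol > t_cutoff) & mask
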