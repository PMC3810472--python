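"""Temporal preprocessing of voxel time series.

Two stages, applied in this order: ordinary-least-squares removal of nuisance
signals (six motion parameters plus optional white-matter and ventricle mean
signals), then a zero-phase temporal bandpass filter restricting the data to
the low-frequency band carrying resting-state fluctuations (0.01-0.08 Hz by
default).  The filter is a forward-backward Butterworth: zero phase shift
preserves the zero-lag correlation structure that all downstream connectivity
estimates rely on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .datasets import BoldDataset
from .motion import MotionTrace

__all__ = ["NuisanceSet", "nuisance_regression", "bandpass_filter", "preprocess"]


@dataclass
class NuisanceSet:
    """Frame-indexed nuisance regressors, each column zero-mean.

    Build with :meth:`from_parts`; an intercept is always added by the
    regression itself and must not be included here.
    """

    regressors: np.ndarray  # (n_frames, n_regressors)
    names: list[str]

    def __post_init__(self) -> None:
        self.regressors = np.atleast_2d(np.asarray(self.regressors, dtype=float))
        if self.regressors.ndim != 2:
            raise ValueError("regressors must be a 2D (frames x columns) array")
        if len(self.names) != self.regressors.shape[1]:
            raise ValueError("one name per regressor column required")
        # columns are centred so the intercept absorbs all mean structure
        self.regressors = self.regressors - self.regressors.mean(axis=0, keepdims=True)

    @classmethod
    def from_parts(
        cls,
        motion: MotionTrace | None = None,
        white_matter: np.ndarray | None = None,
        ventricles: np.ndarray | None = None,
    ) -> "NuisanceSet":
        cols, names = [], []
        if motion is not None:
            cols.append(motion.params)
            names += ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
        if white_matter is not None:
            cols.append(np.asarray(white_matter, dtype=float)[:, None])
            names.append("white_matter")
        if ventricles is not None:
            cols.append(np.asarray(ventricles, dtype=float)[:, None])
            names.append("ventricles")
        if not cols:
            raise ValueError("empty nuisance set; pass at least one component")
        return cls(np.hstack(cols), names)

    @property
    def n_frames(self) -> int:
        return self.regressors.shape[0]


def _design_matrix(nuisance: NuisanceSet | None, n_frames: int) -> tuple[np.ndarray, list[str]]:
    if nuisance is None:
        return np.ones((n_frames, 1)), ["intercept"]
    if nuisance.n_frames != n_frames:
        raise ValueError(
            f"nuisance rows ({nuisance.n_frames}) != data frames ({n_frames})"
        )
    X = np.column_stack([np.ones(n_frames), nuisance.regressors])
    return X, ["intercept"] + list(nuisance.names)


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return
    # identify columns involved in the collinearity by dropping one at a time
    collinear = []
    for j in range(X.shape[1]):
        Xj = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(Xj) == rank:
            collinear.append(names[j])
    raise ValueError(f"rank-deficient nuisance design; collinear columns: {collinear}")


def nuisance_regression(dataset: BoldDataset, nuisance: NuisanceSet | None) -> BoldDataset:
    """Regress the nuisance set (plus intercept) out of every in-mask voxel.

    Returns the residual dataset; each residual series has mean ~0.  With an
    empty nuisance set (``None``) the output is simply the demeaned input.
    """
    X, names = _design_matrix(nuisance, dataset.n_frames)
    _check_full_rank(X, names)
    Y = dataset.in_mask_series().T  # (frames, voxels)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    out = np.zeros_like(dataset.data)
    out[dataset.mask] = resid.T
    return dataset.with_data(out)


def bandpass_filter(
    dataset: BoldDataset,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
    order: int = 2,
) -> BoldDataset:
    """Zero-phase Butterworth bandpass of every in-mask voxel series.

    ``order`` is the per-pass filter order; the forward-backward application
    doubles the effective attenuation and cancels phase.  ``high_hz`` must be
    below the Nyquist frequency 1/(2 TR).
    """
    nyquist = 1.0 / (2.0 * dataset.tr_seconds)
    if not 0 < low_hz < high_hz:
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz >= nyquist:
        raise ValueError(
            f"high_hz={high_hz} Hz is not below the Nyquist frequency {nyquist} Hz "
            f"for TR={dataset.tr_seconds}s"
        )
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass",
                        fs=1.0 / dataset.tr_seconds, output="sos")
    Y = dataset.in_mask_series()
    filtered = signal.sosfiltfilt(sos, Y, axis=1)
    out = np.zeros_like(dataset.data)
    out[dataset.mask] = filtered
    return dataset.with_data(out)


def preprocess(
    dataset: BoldDataset,
    nuisance: NuisanceSet | None,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
    order: int = 2,
) -> BoldDataset:
    """Nuisance regression followed by bandpass filtering (in that order)."""
    return bandpass_filter(nuisance_regression(dataset, nuisance),
                           low_hz=low_hz, high_hz=high_hz, order=order)
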