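"""Head-motion quality control.

Six rigid-body realignment parameters per frame (three translations in mm,
three rotations in degrees, all relative to the first frame) are summarised
into four scalar motion indices and a per-frame framewise displacement (FD)
series.  Rotations are converted to millimetres as arc length on a sphere of
radius 50 mm, approximating the mean distance of the cortex from the head
centre.  Subjects are excluded on per-parameter min-to-max range or peak FD;
a confound audit correlates motion indices with edge-level connectivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "MotionTrace",
    "MotionSummary",
    "ExclusionRule",
    "framewise_displacement",
    "motion_summaries",
    "apply_exclusion",
    "motion_confound_audit",
    "read_motion_file",
    "write_motion_file",
]

PARAM_NAMES = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")


@dataclass
class MotionTrace:
    """Per-frame six rigid-body parameters relative to the first frame.

    ``params`` has shape (n_frames, 6): columns are x/y/z translation in mm
    followed by x/y/z rotation in degrees.
    """

    params: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError(f"params must be (n_frames, 6), got {self.params.shape}")
        if self.n_frames < 2:
            raise ValueError("a motion trace needs at least 2 frames")
        if not np.all(np.isfinite(self.params)):
            raise ValueError("non-finite motion parameters")

    @property
    def n_frames(self) -> int:
        return self.params.shape[0]

    def rebased(self) -> "MotionTrace":
        """Trace re-expressed relative to its first frame."""
        return MotionTrace(self.params - self.params[0])


@dataclass
class MotionSummary:
    """Scalar motion indices, all in mm (rotations converted by arc length)."""

    d_max: float
    d_rms: float
    fd_max: float
    fd_rms: float
    fd_series: np.ndarray

    def as_dict(self) -> dict:
        return {
            "d_max": self.d_max,
            "d_rms": self.d_rms,
            "fd_max": self.fd_max,
            "fd_rms": self.fd_rms,
        }


@dataclass
class ExclusionRule:
    """Motion exclusion cutoffs.

    A subject is excluded when any translation's min-to-max range exceeds
    ``max_translation`` mm, any rotation's range exceeds ``max_rotation``
    degrees, or peak framewise displacement exceeds ``max_fd`` mm.
    """

    max_translation: float = 3.0
    max_rotation: float = 3.0
    max_fd: float = 2.5
    sphere_radius: float = 50.0

    def __post_init__(self) -> None:
        for name in ("max_translation", "max_rotation", "max_fd", "sphere_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def _radius_converted(params: np.ndarray, sphere_radius: float) -> np.ndarray:
    """All six parameters in mm: rotations as arc length theta(rad) * R."""
    out = params.copy()
    out[:, 3:] = np.deg2rad(out[:, 3:]) * sphere_radius
    return out


def framewise_displacement(trace: MotionTrace, sphere_radius: float = 50.0) -> np.ndarray:
    """Per-frame framewise displacement (Power convention), length n_frames - 1.

    FD(i) = sum_j |d_j(i) - d_j(i-1)| with rotation differences converted from
    degrees to mm via arc length on a sphere of the given radius.
    """
    d = _radius_converted(trace.params, sphere_radius)
    return np.abs(np.diff(d, axis=0)).sum(axis=1)


def motion_summaries(
    trace: MotionTrace,
    sphere_radius: float = 50.0,
    rms_variant: str = "pooled",
) -> MotionSummary:
    """Compute the four motion indices from a trace.

    d_max is the largest absolute radius-converted parameter value over all
    frames.  d_rms with the default ``pooled`` variant is
    sqrt( (1/N) sum_i sum_j d_j(i)^2 ); the ``euclidean`` variant takes the
    RMS over frames of the per-frame Euclidean displacement norm — both are
    monotone summaries of overall motion and differ only by a fixed pooling
    convention.
    """
    d = _radius_converted(trace.params, sphere_radius)
    fd = framewise_displacement(trace, sphere_radius)
    if rms_variant == "pooled":
        d_rms = float(np.sqrt(np.mean(np.sum(d**2, axis=1))))
    elif rms_variant == "euclidean":
        d_rms = float(np.sqrt(np.mean(np.linalg.norm(d, axis=1) ** 2)))
    else:
        raise ValueError(f"unknown rms_variant {rms_variant!r}")
    return MotionSummary(
        d_max=float(np.max(np.abs(d))),
        d_rms=d_rms,
        fd_max=float(fd.max()),
        fd_rms=float(np.sqrt(np.mean(fd**2))),
        fd_series=fd,
    )


def apply_exclusion(
    summary: MotionSummary, trace: MotionTrace, rule: ExclusionRule | None = None
) -> tuple[str, list[str]]:
    """Decide include/exclude for one subject.

    Returns ``("include" | "exclude", reasons)`` where every violated
    criterion is listed.  Translation and rotation cutoffs act on each
    parameter's min-to-max range in its native unit (mm / degrees); the FD
    cutoff acts on the peak of the FD series.
    """
    if rule is None:
        rule = ExclusionRule()
    reasons: list[str] = []
    ranges = trace.params.max(axis=0) - trace.params.min(axis=0)
    for j in range(3):
        if ranges[j] > rule.max_translation:
            reasons.append(
                f"translation {PARAM_NAMES[j]} range {ranges[j]:.3f} mm > {rule.max_translation} mm"
            )
    for j in range(3, 6):
        if ranges[j] > rule.max_rotation:
            reasons.append(
                f"rotation {PARAM_NAMES[j]} range {ranges[j]:.3f} deg > {rule.max_rotation} deg"
            )
    if summary.fd_max > rule.max_fd:
        reasons.append(
            f"framewise displacement max {summary.fd_max:.3f} mm > {rule.max_fd} mm"
        )
    return ("exclude" if reasons else "include", reasons)


def motion_confound_audit(
    edge_values: pd.DataFrame,
    summaries: list[MotionSummary],
    alpha: float = 0.01,
) -> tuple[pd.DataFrame, dict]:
    """Correlate motion indices with edge connectivity across subjects.

    ``edge_values`` is a subjects x edges table of Fisher-z connectivity for
    candidate edges (typically those with a significant group effect);
    ``summaries`` is the per-subject motion summary in the same row order.
    Each of the four indices is Pearson-correlated with each edge; the count
    of significant correlations at ``alpha`` is compared against the count
    expected under the null (alpha * n_tests).  Pairs with a zero-variance
    side are flagged undefined and excluded from the counts.
    """
    if len(summaries) != len(edge_values):
        raise ValueError("edge_values rows and summaries must align one per subject")
    if len(summaries) < 4:
        raise ValueError("need at least 4 subjects for a meaningful correlation")
    motion = pd.DataFrame([s.as_dict() for s in summaries])
    rows = []
    for mname in motion.columns:
        mcol = motion[mname].to_numpy()
        for ename in edge_values.columns:
            ecol = edge_values[ename].to_numpy(dtype=float)
            if np.ptp(mcol) == 0 or np.ptp(ecol) == 0:
                rows.append(
                    {"motion_index": mname, "edge": ename, "r": np.nan,
                     "p": np.nan, "defined": False, "significant": False}
                )
                continue
            r, p = sps.pearsonr(mcol, ecol)
            rows.append(
                {"motion_index": mname, "edge": ename, "r": r, "p": p,
                 "defined": True, "significant": bool(p < alpha)}
            )
    table = pd.DataFrame(rows)
    defined = table[table["defined"]]
    n_tests = len(defined)
    counts = {
        "n_tests": n_tests,
        "n_significant": int(defined["significant"].sum()),
        "n_expected_null": alpha * n_tests,
        "n_undefined": int((~table["defined"]).sum()),
        "alpha": alpha,
        "n_negative_significant": int(
            (defined["significant"] & (defined["r"] < 0)).sum()
        ),
    }
    return table, counts


def read_motion_file(
    path: str | Path,
    dialect: str = "deg",
    sphere_radius: float = 50.0,
) -> MotionTrace:
    """Read a whitespace-delimited six-column motion parameter file.

    ``dialect='deg'`` expects translations in mm then rotations in degrees.
    ``dialect='spm'`` expects SPM realignment files (rotations in radians)
    and converts them to degrees.  Traces are rebased to the first frame.
    """
    arr = np.loadtxt(str(path), ndmin=2)
    if arr.shape[1] != 6:
        raise ValueError(f"motion file {path} must have 6 columns, got {arr.shape[1]}")
    if dialect == "spm":
        arr = arr.copy()
        arr[:, 3:] = np.rad2deg(arr[:, 3:])
    elif dialect != "deg":
        raise ValueError(f"unknown motion file dialect {dialect!r}")
    return MotionTrace(arr).rebased()


def write_motion_file(trace: MotionTrace, path: str | Path) -> None:
    np.savetxt(str(path), trace.params, fmt="%.8f")
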