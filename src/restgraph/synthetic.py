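"""Seeded synthetic cohorts with planted network structure.

The generator emulates the statistical structure the analysis assumes: voxel
time series with modular correlation structure nested inside atlas regions
(network module > anatomical region > functional sub-region), two groups that
differ in coupling (one module's within-module coupling raised, one module's
between-module coupling lowered in the "patient" group), realistic
random-walk motion traces with optional spikes, and planted-partition graphs
for community-detection fixtures.

Time series follow a latent-factor construction: voxel v in sub-region k of
region r in network module m is

    x_v = sqrt(c_b) H + sqrt(c_w - c_b) E_m + sqrt(c_s - c_w) U_rk
          + [sqrt(g) G] + noise_sd * eps_v

with i.i.d. standard-normal latents per frame (H shared across module m's
cross-module coupling, E_m per module, U_rk per sub-region, G an optional
global signal, eps_v private).  This guarantees a positive semi-definite
implied correlation structure with expected ordering

    corr(within sub-region) > corr(within module) > corr(between modules)

whenever c_s > c_w > c_b, and lets group differences be planted by changing
c_w or c_b per module and group.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .datasets import BoldDataset
from .graph import BinaryGraph
from .motion import MotionTrace

__all__ = [
    "SyntheticConfig",
    "default_demo_config",
    "generate_toy_atlas",
    "planted_subregion_labels",
    "generate_modular_timeseries",
    "generate_cohort",
    "generate_motion_trace",
    "planted_partition_graph",
]


def _default_module_assignment() -> dict[str, tuple[int, ...]]:
    # four network-module analogues over eight regions, two regions each
    return {
        "default_mode": (1, 2),
        "visual": (3, 4),
        "sensorimotor": (5, 6),
        "attention": (7, 8),
    }


@dataclass
class SyntheticConfig:
    """Study-condition parameters for the synthetic cohort.

    Couplings are squared latent loadings in [0, 1): ``subregion_coupling``
    (c_s) sets the common signal share of voxels in one functional
    sub-region, ``within_module_coupling`` (c_w, per module per group) the
    share common to a whole network module, ``between_module_coupling``
    (c_b, per module per group) the share shared across modules.  The
    implied voxel-pair correlation at noise_sd = 1 is c / (c_s + 1).

    Defaults plant the two group effects the analysis is meant to detect:
    the sensorimotor analogue couples more strongly *within* its module in
    the patient group (0.30 -> 0.45), and the visual analogue couples less
    strongly *between* modules in the patient group (0.10 -> 0.02).
    """

    grid_shape: tuple[int, int, int] = (16, 16, 16)
    n_frames: int = 168  # usable frames of a 6-min TR-2s run after discards
    tr_seconds: float = 2.0
    n_regions: int = 8
    modules_per_region: int = 2
    module_assignment: dict[str, tuple[int, ...]] = field(
        default_factory=_default_module_assignment
    )
    within_module_coupling: dict[tuple[str, str], float] = field(default_factory=dict)
    between_module_coupling: dict[tuple[str, str], float] = field(default_factory=dict)
    default_within_coupling: float = 0.30
    default_between_coupling: float = 0.10
    subregion_coupling: float = 0.60
    global_signal_coupling: float = 0.0  # off: no global-signal component
    noise_sd: float = 1.0
    n_subjects_per_group: int = 12
    groups: tuple[str, str] = ("control", "patient")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if any(s < 1 for s in self.grid_shape):
            raise ValueError("grid_shape axes must be positive")
        assigned = [r for regions in self.module_assignment.values() for r in regions]
        if sorted(assigned) != list(range(1, self.n_regions + 1)):
            raise ValueError(
                "every region 1..n_regions must belong to exactly one network module"
            )

    def module_of_region(self, region: int) -> str:
        for module, regions in self.module_assignment.items():
            if region in regions:
                return module
        raise KeyError(region)

    def within(self, module: str, group: str) -> float:
        return self.within_module_coupling.get((module, group),
                                               self.default_within_coupling)

    def between(self, module: str, group: str) -> float:
        return self.between_module_coupling.get((module, group),
                                                self.default_between_coupling)


def default_demo_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """The demo cohort: 12 + 12 subjects on a 16^3 grid with planted effects."""
    cfg = SyntheticConfig(
        within_module_coupling={("sensorimotor", "patient"): 0.45},
        between_module_coupling={("visual", "patient"): 0.02},
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# atlas

def _block_factorisation(grid_shape, n_regions) -> tuple[int, int, int]:
    """Factor n_regions into per-axis block counts dividing each axis."""
    best = None
    for fa in range(1, n_regions + 1):
        if n_regions % fa:
            continue
        for fb in range(1, n_regions // fa + 1):
            if (n_regions // fa) % fb:
                continue
            fc = n_regions // (fa * fb)
            if grid_shape[0] % fa or grid_shape[1] % fb or grid_shape[2] % fc:
                continue
            cand = (fa, fb, fc)
            # prefer the most cube-like split
            score = max(cand) - min(cand)
            if best is None or score < best[0]:
                best = (score, cand)
    if best is None:
        raise ValueError(
            f"grid {grid_shape} cannot be divided into {n_regions} equal "
            f"contiguous blocks (no axis factorisation of {n_regions} divides "
            f"axes {grid_shape})"
        )
    return best[1]


def generate_toy_atlas(config: SyntheticConfig) -> np.ndarray:
    """Integer label volume: labels 1..n_regions, each a contiguous block."""
    fa, fb, fc = _block_factorisation(config.grid_shape, config.n_regions)
    nx, ny, nz = config.grid_shape
    atlas = np.zeros(config.grid_shape, dtype=int)
    label = 0
    for a in range(fa):
        for b in range(fb):
            for c in range(fc):
                label += 1
                atlas[a * nx // fa:(a + 1) * nx // fa,
                      b * ny // fb:(b + 1) * ny // fb,
                      c * nz // fc:(c + 1) * nz // fc] = label
    return atlas


def planted_subregion_labels(config: SyntheticConfig, atlas: np.ndarray) -> np.ndarray:
    """Ground-truth sub-region labels: each region split into equal chunks.

    Voxels of each region (in C flat order) are split into
    ``modules_per_region`` contiguous chunks; labels are dense 1..K over the
    whole volume, region-major.
    """
    labels = np.zeros(atlas.shape, dtype=int)  # C-order: flat view below
    flat = labels.reshape(-1)
    flat_atlas = atlas.reshape(-1)
    next_label = 0
    for region in range(1, config.n_regions + 1):
        vox = np.flatnonzero(flat_atlas == region)
        for chunk in np.array_split(vox, config.modules_per_region):
            next_label += 1
            flat[chunk] = next_label
    return labels


# ---------------------------------------------------------------------------
# time series

def generate_modular_timeseries(
    config: SyntheticConfig,
    group: str,
    subject_seed: int,
    atlas: np.ndarray | None = None,
    subject_id: str = "",
) -> BoldDataset:
    """One subject's BOLD-like volume with the planted correlation structure.

    Deterministic for a given ``subject_seed``; the group label selects the
    coupling set.  ``atlas`` defaults to :func:`generate_toy_atlas`.
    """
    if config.noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if atlas is None:
        atlas = generate_toy_atlas(config)
    sub_labels = planted_subregion_labels(config, atlas)
    rng = np.random.default_rng(subject_seed)
    T = config.n_frames
    modules = list(config.module_assignment)
    hub = rng.standard_normal(T)                    # cross-module shared latent
    module_latent = {m: rng.standard_normal(T) for m in modules}
    n_sub = int(sub_labels.max())
    sub_latent = rng.standard_normal((n_sub, T))
    global_latent = rng.standard_normal(T)
    noise = rng.standard_normal((*config.grid_shape, T)) * config.noise_sd

    data = np.zeros((*config.grid_shape, T))
    g = config.global_signal_coupling
    for region in range(1, config.n_regions + 1):
        module = config.module_of_region(region)
        c_w = config.within(module, group)
        c_b = config.between(module, group)
        c_s = config.subregion_coupling
        if not 0 <= c_b <= c_w <= c_s < 1:
            raise ValueError(
                f"couplings must satisfy 0 <= between <= within <= subregion < 1; "
                f"got ({c_b}, {c_w}, {c_s}) for module {module!r}, group {group!r}"
            )
        base = (np.sqrt(c_b) * hub
                + np.sqrt(c_w - c_b) * module_latent[module])
        in_region = atlas == region
        for sub in np.unique(sub_labels[in_region]):
            sel = sub_labels == sub
            sig = base + np.sqrt(c_s - c_w) * sub_latent[sub - 1]
            data[sel] = sig
    if g > 0:
        data += np.sqrt(g) * global_latent
    data += noise
    mask = atlas > 0
    return BoldDataset(data=data, mask=mask, tr_seconds=config.tr_seconds,
                       subject_id=subject_id, group=group)


def generate_cohort(
    config: SyntheticConfig, atlas: np.ndarray | None = None
) -> list[dict]:
    """Generate the full two-group cohort with per-subject motion traces.

    Returns a list of records ``{"dataset", "motion", "subject_id", "group"}``.
    Subject seeds are forked deterministically from ``config.seed``.
    """
    if atlas is None:
        atlas = generate_toy_atlas(config)
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(2 * config.n_subjects_per_group)
    cohort = []
    idx = 0
    for group in config.groups:
        for k in range(config.n_subjects_per_group):
            ss = children[idx]
            idx += 1
            data_seed, motion_seed = ss.generate_state(2) >> np.uint32(1)
            subject_id = f"{group[:3]}-{k + 1:02d}"
            ds = generate_modular_timeseries(
                config, group, int(data_seed), atlas=atlas, subject_id=subject_id
            )
            motion = generate_motion_trace(
                config.n_frames,
                step_sd=np.full(6, 0.01),
                seed=int(motion_seed),
            )
            cohort.append({"dataset": ds, "motion": motion,
                           "subject_id": subject_id, "group": group})
    return cohort


# ---------------------------------------------------------------------------
# motion

def generate_motion_trace(
    n_frames: int,
    step_sd: np.ndarray | float = 0.01,
    spike: tuple[int, np.ndarray | float] | None = None,
    seed: int | None = None,
) -> MotionTrace:
    """Random-walk motion trace starting at zero.

    ``step_sd`` gives the per-frame step standard deviation per parameter
    (scalar or 6-vector; translations in mm, rotations in degrees).
    ``spike=(frame, magnitudes)`` adds a transient excursion at one frame
    (scalar magnitude goes into the x translation).
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    step_sd = np.broadcast_to(np.asarray(step_sd, dtype=float), (6,))
    rng = np.random.default_rng(seed)
    steps = rng.standard_normal((n_frames - 1, 6)) * step_sd
    params = np.vstack([np.zeros(6), np.cumsum(steps, axis=0)])
    if spike is not None:
        frame, mag = spike
        if not 0 <= frame < n_frames:
            raise ValueError(f"spike frame {frame} out of range [0, {n_frames})")
        mag = np.asarray(mag, dtype=float)
        if mag.ndim == 0:
            vec = np.zeros(6)
            vec[0] = float(mag)
        else:
            vec = np.broadcast_to(mag, (6,)).astype(float)
        params[frame] = params[frame] + vec
    return MotionTrace(params)


# ---------------------------------------------------------------------------
# planted-partition graphs

def planted_partition_graph(
    n_modules: int,
    nodes_per_module: int,
    p_in: float,
    p_out: float,
    seed: int | None = None,
) -> tuple[BinaryGraph, np.ndarray]:
    """Undirected planted-partition graph and its ground-truth assignment.

    Within-module edges appear with probability ``p_in``, between-module
    edges with ``p_out``; requires 0 <= p_out < p_in <= 1.
    """
    if not 0 <= p_out < p_in <= 1:
        raise ValueError(f"need 0 <= p_out < p_in <= 1, got p_in={p_in}, p_out={p_out}")
    n = n_modules * nodes_per_module
    labels = np.repeat(np.arange(1, n_modules + 1), nodes_per_module)
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n, 1)
    same = labels[iu] == labels[ju]
    p = np.where(same, p_in, p_out)
    present = rng.random(len(p)) < p
    A = np.zeros((n, n), dtype=np.int8)
    A[iu[present], ju[present]] = 1
    A += A.T
    return BinaryGraph(adjacency=A), labels
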