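"""Group inference: permutation tests, FDR, edge tests, cluster-extent maps.

Between-group differences in graph metrics are tested with nonparametric
permutation tests on the difference of group means (exact enumeration when
the number of distinct group splits is small enough, Monte-Carlo otherwise).
Node/module results are corrected with Benjamini-Hochberg FDR.  Edge-level
differences use two-sample t-tests on Fisher-z connectivity.  Voxelwise
z-degree contrasts are assessed by cluster-extent inference: supra-threshold
clusters (cluster-defining p = 0.005 by default, 6-connectivity) are
assigned p-values from a permutation null of the maximum cluster size, then
BH-FDR corrected across clusters.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PermutationResult",
    "permutation_test",
    "fdr_adjust",
    "edge_group_test",
    "top_edges",
    "ClusterResult",
    "voxel_degree_group_test",
]


@dataclass
class PermutationResult:
    statistic: float  # mean(a) - mean(b)
    p: float
    n_perm: int
    exact: bool


def _perm_pvalue(obs: float, null: np.ndarray, alternative: str, exact: bool) -> float:
    eps = 1e-12
    if alternative == "two-sided":
        hits = np.abs(null) >= abs(obs) - eps
    elif alternative == "greater":
        hits = null >= obs - eps
    elif alternative == "less":
        hits = null <= obs + eps
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    if exact:
        return float(hits.mean())
    return float((1 + hits.sum()) / (len(null) + 1))


def permutation_test(
    values_a: np.ndarray,
    values_b: np.ndarray,
    n_perm: int = 10000,
    seed: int | None = None,
    alternative: str = "two-sided",
) -> PermutationResult:
    """Two-sample permutation test on the difference of group means.

    When the total number of group relabellings C(n_a + n_b, n_a) does not
    exceed ``n_perm`` the null is enumerated exactly; otherwise ``n_perm``
    random relabellings give the Monte-Carlo p-value (1 + hits)/(n_perm + 1).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 observations")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    obs = float(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    n, na = len(pooled), len(a)
    total = math.comb(n, na)
    if total <= n_perm:
        null = np.empty(total)
        idx_all = np.arange(n)
        for i, combo in enumerate(combinations(range(n), na)):
            sel = np.zeros(n, dtype=bool)
            sel[list(combo)] = True
            null[i] = pooled[sel].mean() - pooled[~sel].mean()
        return PermutationResult(obs, _perm_pvalue(obs, null, alternative, True),
                                 total, True)
    rng = np.random.default_rng(seed)
    # vectorised random relabellings: argsort of uniforms is a random permutation
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    perm = pooled[order]
    null = perm[:, :na].mean(axis=1) - perm[:, na:].mean(axis=1)
    return PermutationResult(obs, _perm_pvalue(obs, null, alternative, False),
                             n_perm, False)


def fdr_adjust(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: returns (adjusted p, rejection mask at q)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, p_adj <= q


def edge_group_test(
    matrices_a: list,
    matrices_b: list,
    alpha: float = 0.05,
    scope: np.ndarray | list | None = None,
    equal_var: bool = True,
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Two-sample t-test per edge on Fisher-z connectivity.

    ``matrices_a/b`` are lists of :class:`~restgraph.graph.ConnectivityMatrix`
    (or plain symmetric arrays) with identical node order.  ``scope``
    optionally restricts testing to edges incident to the given 0-based node
    set.  Edges constant in both groups get ``defined = False`` and NaN
    statistics.  Returns a tidy table: node_i, node_j, mean_a, mean_b, t, p,
    significant (at ``alpha``), defined.
    """

    def stack(mats):
        out = []
        ids = None
        for m in mats:
            z = m.z if hasattr(m, "z") else np.asarray(m, dtype=float)
            mids = getattr(m, "node_ids", None)
            if ids is None:
                ids = mids
            elif mids is not None and not np.array_equal(ids, mids):
                raise ValueError("node order mismatch between connectivity matrices")
            out.append(z)
        return np.stack(out), ids

    Za, ids_a = stack(matrices_a)
    Zb, ids_b = stack(matrices_b)
    if Za.shape[1:] != Zb.shape[1:]:
        raise ValueError("matrix dimensions differ between groups")
    if ids_a is not None and ids_b is not None and not np.array_equal(ids_a, ids_b):
        raise ValueError("node order mismatch between groups")
    if Za.shape[0] < 2 or Zb.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    n = Za.shape[1]
    iu, ju = np.triu_indices(n, 1)
    if scope is not None:
        scope = np.asarray(scope)
        keep = np.isin(iu, scope) | np.isin(ju, scope)
        iu, ju = iu[keep], ju[keep]
    ea, eb = Za[:, iu, ju], Zb[:, iu, ju]
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = sps.ttest_ind(ea, eb, axis=0, equal_var=equal_var,
                             alternative=alternative)
    defined = np.isfinite(t)
    df = pd.DataFrame({
        "node_i": iu, "node_j": ju,
        "mean_a": ea.mean(axis=0), "mean_b": eb.mean(axis=0),
        "t": t, "p": p, "defined": defined,
    })
    df["significant"] = defined & (df["p"] < alpha)
    return df


def top_edges(
    comparisons: pd.DataFrame, k: int = 10, node_names: dict[int, str] | None = None
) -> pd.DataFrame:
    """The k edges with the smallest p, deterministic (p, node_i, node_j) order."""
    valid = comparisons[comparisons["defined"] & comparisons["p"].notna()]
    if len(valid) < k:
        warnings.warn(f"only {len(valid)} testable edges available, requested {k}")
    ranked = valid.sort_values(["p", "node_i", "node_j"], kind="mergesort").head(k)
    ranked = ranked.reset_index(drop=True)
    if node_names:
        ranked.insert(0, "name_j", ranked["node_j"].map(lambda i: node_names.get(i, str(i))))
        ranked.insert(0, "name_i", ranked["node_i"].map(lambda i: node_names.get(i, str(i))))
    return ranked


@dataclass
class ClusterResult:
    """Cluster-extent inference result for one contrast direction pair."""

    clusters: pd.DataFrame  # direction, size, peak_t, peak coordinates, p, p_adj
    cluster_forming_p: float
    critical_size: int | None  # smallest surviving cluster size, None if none


_CONNECTIVITY_STRUCTURES = {6: 1, 18: 2, 26: 3}


def _label_clusters(binary: np.ndarray, connectivity: int) -> tuple[np.ndarray, int]:
    structure = ndimage.generate_binary_structure(
        binary.ndim, _CONNECTIVITY_STRUCTURES[connectivity]
    )
    return ndimage.label(binary, structure=structure)


def _two_sample_t(stack_a: np.ndarray, stack_b: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t per column; NaN where variance degenerates."""
    na, nb = len(stack_a), len(stack_b)
    ma, mb = stack_a.mean(axis=0), stack_b.mean(axis=0)
    va = stack_a.var(axis=0, ddof=1)
    vb = stack_b.var(axis=0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (ma - mb) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    return t


def voxel_degree_group_test(
    zmaps_a: list[np.ndarray],
    zmaps_b: list[np.ndarray],
    mask: np.ndarray,
    cluster_forming_p: float = 0.005,
    cluster_alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int | None = None,
    connectivity: int = 6,
) -> tuple[np.ndarray, ClusterResult]:
    """Voxelwise two-sample t-map with permutation cluster-extent inference.

    Both one-sided contrasts (A > B and B > A) are thresholded at the t
    quantile of ``cluster_forming_p``; face-connected supra-threshold
    clusters receive p-values from a group-relabelling null of the maximum
    cluster size (both directions pooled into the maximum), then BH-FDR is
    applied across all observed clusters.  Degenerate-variance voxels are
    masked out.  Returns the t volume and a :class:`ClusterResult`.
    """
    if connectivity not in _CONNECTIVITY_STRUCTURES:
        raise ValueError("connectivity must be 6, 18 or 26")
    if len(zmaps_a) < 2 or len(zmaps_b) < 2:
        raise ValueError("need at least 2 subjects per group")
    mask = np.asarray(mask, dtype=bool)
    A = np.stack([np.asarray(m)[mask] for m in zmaps_a])
    B = np.stack([np.asarray(m)[mask] for m in zmaps_b])
    na, nb = len(A), len(B)
    t_obs = _two_sample_t(A, B)
    degenerate = ~np.isfinite(t_obs)
    t_obs = np.where(degenerate, 0.0, t_obs)
    dof = na + nb - 2
    t_crit = float(sps.t.ppf(1.0 - cluster_forming_p, dof))

    def cluster_sizes_and_labels(t_flat):
        vol = np.zeros(mask.shape)
        vol[mask] = t_flat
        out = []
        for direction, supra in (("A>B", vol > t_crit), ("B>A", vol < -t_crit)):
            supra &= mask
            lab, n_lab = _label_clusters(supra, connectivity)
            out.append((direction, vol, lab, n_lab))
        return out

    observed = cluster_sizes_and_labels(t_obs)
    rows = []
    for direction, vol, lab, n_lab in observed:
        for c in range(1, n_lab + 1):
            sel = lab == c
            k = int(sel.sum())
            signed = vol if direction == "A>B" else -vol
            peak_flat = np.argmax(np.where(sel, signed, -np.inf))
            peak = np.unravel_index(peak_flat, mask.shape)
            rows.append({
                "direction": direction, "size": k,
                "peak_t": float(signed.reshape(-1)[peak_flat]),
                "peak_x": int(peak[0]), "peak_y": int(peak[1]), "peak_z": int(peak[2]),
            })
    clusters = pd.DataFrame(rows, columns=["direction", "size", "peak_t",
                                           "peak_x", "peak_y", "peak_z"])

    # permutation null of the maximum supra-threshold cluster size
    pooled = np.concatenate([A, B])
    rng = np.random.default_rng(seed)
    max_sizes = np.zeros(n_perm, dtype=int)
    n = na + nb
    for i in range(n_perm):
        idx = rng.permutation(n)
        t_perm = _two_sample_t(pooled[idx[:na]], pooled[idx[na:]])
        t_perm = np.where(np.isfinite(t_perm), t_perm, 0.0)
        best = 0
        for supra_flat in (t_perm > t_crit, t_perm < -t_crit):
            vol = np.zeros(mask.shape, dtype=bool)
            vol[mask] = supra_flat
            lab, n_lab = _label_clusters(vol, connectivity)
            if n_lab:
                best = max(best, int(np.bincount(lab.reshape(-1))[1:].max()))
        max_sizes[i] = best

    if len(clusters):
        clusters["p"] = [
            float((1 + (max_sizes >= k).sum()) / (n_perm + 1))
            for k in clusters["size"]
        ]
        p_adj, reject = fdr_adjust(clusters["p"].to_numpy(), q=cluster_alpha)
        clusters["p_adjusted"] = p_adj
        clusters["significant"] = reject
        surviving = clusters.loc[clusters["significant"], "size"]
        critical = int(surviving.min()) if len(surviving) else None
    else:
        clusters["p"] = clusters["p_adjusted"] = pd.Series(dtype=float)
        clusters["significant"] = pd.Series(dtype=bool)
        critical = None
    t_vol = np.zeros(mask.shape)
    t_vol[mask] = t_obs
    return t_vol, ClusterResult(clusters=clusters,
                                cluster_forming_p=cluster_forming_p,
                                critical_size=critical)
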