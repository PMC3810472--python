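"""Binary graph construction and network metrics.

ROI time courses become a Fisher-z correlation matrix; proportional
thresholding at sparsity S keeps the top S fraction of weights and yields an
undirected binary graph.  On such graphs this module computes degree (raw and
z-scored), the Watts-Strogatz clustering coefficient, characteristic path
length, the small-world ratios gamma and lambda against degree-preserving
rewired null networks, modular structure by Newman's spectral algorithm with
Kernighan-Lin-style fine-tuning, and the participation coefficient.

All metrics operate on binary graphs by design; weighted variants are out of
scope.  Ties in proportional thresholding are broken lexicographically by
node-pair index, so thresholding is deterministic and monotone in S.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csgraph
from scipy.sparse import csr_matrix

__all__ = [
    "ConnectivityMatrix",
    "BinaryGraph",
    "Partition",
    "GlobalMetrics",
    "fisher_z",
    "extract_roi_timeseries",
    "connectivity_matrix",
    "threshold_proportional",
    "degree_and_z",
    "clustering_coefficients",
    "characteristic_path_length",
    "random_reference",
    "normalized_global_metrics",
    "modularity",
    "detect_communities",
    "participation_coefficients",
    "module_summaries",
]

#: correlations are clipped to +-(1 - 1e-7) before the Fisher transform so
#: degenerate r = +-1 pairs map to a large finite value instead of infinity
R_CAP = 1.0 - 1e-7
Z_CAP = float(np.arctanh(R_CAP))


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Variance-stabilising Fisher transform atanh(r), capped at |r| = 1 - 1e-7."""
    return np.arctanh(np.clip(r, -R_CAP, R_CAP))


@dataclass
class ConnectivityMatrix:
    """Symmetric node x node Fisher-z correlation matrix, zero diagonal."""

    z: np.ndarray
    node_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        n = self.z.shape[0]
        if self.z.ndim != 2 or self.z.shape[1] != n:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(self.z, self.z.T, atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("connectivity matrix must be finite (apply the z cap)")
        np.fill_diagonal(self.z, 0.0)
        if self.node_ids is None:
            self.node_ids = np.arange(1, n + 1)
        else:
            self.node_ids = np.asarray(self.node_ids)
            if len(self.node_ids) != n:
                raise ValueError("node_ids length must match matrix dimension")

    @property
    def n_nodes(self) -> int:
        return self.z.shape[0]


@dataclass
class BinaryGraph:
    """Undirected simple graph as a symmetric 0/1 adjacency with its sparsity."""

    adjacency: np.ndarray
    sparsity: float | None = None

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency must be symmetric")
        A = (A != 0).astype(np.int8)
        np.fill_diagonal(A, 0)
        self.adjacency = A
        if self.sparsity is None:
            n = A.shape[0]
            self.sparsity = float(self.n_edges / (n * (n - 1) / 2)) if n > 1 else 0.0

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)

    def edge_array(self) -> np.ndarray:
        """(n_edges, 2) array of upper-triangle edges in lexicographic order."""
        iu = np.triu_indices(self.n_nodes, 1)
        present = self.adjacency[iu] != 0
        return np.column_stack([iu[0][present], iu[1][present]])

    def is_connected(self) -> bool:
        if self.n_nodes == 0:
            return False
        n_comp, _ = csgraph.connected_components(
            csr_matrix(self.adjacency), directed=False
        )
        return n_comp == 1


@dataclass
class Partition:
    """Node -> module assignment with the modularity Q of that assignment."""

    assignment: np.ndarray
    q: float

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=int)

    @property
    def n_modules(self) -> int:
        return len(np.unique(self.assignment))

    def module_nodes(self) -> dict[int, np.ndarray]:
        return {m: np.flatnonzero(self.assignment == m)
                for m in np.unique(self.assignment)}


@dataclass
class GlobalMetrics:
    """Per-graph global metrics and their rewired-null normalisations."""

    clustering: float
    path_length: float
    gamma: float
    lam: float
    sigma: float
    n_random_used: int


# ---------------------------------------------------------------------------
# construction

def extract_roi_timeseries(dataset, parcellation) -> np.ndarray:
    """Node x frame matrix of sub-region mean time courses.

    ``parcellation`` is a :class:`~restgraph.parcellation.SubParcellation`;
    each row is the mean over the node's in-mask voxels.
    """
    labels = parcellation.labels
    ts = np.empty((parcellation.n_nodes, dataset.n_frames))
    for node in range(1, parcellation.n_nodes + 1):
        sel = (labels == node) & dataset.mask
        if not sel.any():
            raise ValueError(
                f"node {node} ({parcellation.names.get(node, '?')}) has no in-mask voxels"
            )
        ts[node - 1] = dataset.data[sel].mean(axis=0)
    return ts


def connectivity_matrix(ts: np.ndarray, node_ids=None) -> ConnectivityMatrix:
    """Pairwise zero-lag Pearson correlation of ROI series, Fisher-z transformed."""
    ts = np.asarray(ts, dtype=float)
    if ts.shape[1] < 3:
        raise ValueError("need at least 3 frames to correlate")
    sd = ts.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"zero-variance time series for node rows {bad.tolist()}")
    r = np.corrcoef(ts)
    z = fisher_z(r)
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0  # exact symmetry against float round-off
    return ConnectivityMatrix(z=z, node_ids=node_ids)


def _ranked_edges(weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle pairs ordered by descending weight, ties by (i, j)."""
    n = weights.shape[0]
    iu, ju = np.triu_indices(n, 1)
    w = weights[iu, ju]
    order = np.lexsort((ju, iu, -w))
    return iu[order], ju[order]


def threshold_proportional(
    matrix: ConnectivityMatrix | np.ndarray, sparsity: float
) -> BinaryGraph:
    """Keep the round(S * n(n-1)/2) largest off-diagonal weights.

    Deterministic: equal weights are ranked by lexicographic node-pair order,
    which also makes the retained edge set monotone in S.
    """
    if not 0 < sparsity <= 1:
        raise ValueError(f"sparsity must be in (0, 1], got {sparsity}")
    w = matrix.z if isinstance(matrix, ConnectivityMatrix) else np.asarray(matrix, dtype=float)
    n = w.shape[0]
    k = int(round(sparsity * n * (n - 1) / 2))
    ii, jj = _ranked_edges(w)
    A = np.zeros((n, n), dtype=np.int8)
    A[ii[:k], jj[:k]] = 1
    A += A.T
    return BinaryGraph(adjacency=A, sparsity=sparsity)


# ---------------------------------------------------------------------------
# node and global metrics

def degree_and_z(graph: BinaryGraph) -> tuple[np.ndarray, np.ndarray]:
    """Node degrees and their z-scores (population mean/SD over nodes)."""
    if graph.n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    D = graph.degrees()
    sd = D.std()  # population convention
    if sd == 0:
        raise ValueError("degree distribution has zero spread; z-degree undefined")
    return D, (D - D.mean()) / sd


def clustering_coefficients(graph: BinaryGraph) -> tuple[np.ndarray, float]:
    """Watts-Strogatz binary clustering per node and its mean.

    C_i = (closed triples through i) / (D_i (D_i - 1)); nodes of degree < 2
    are assigned C_i = 0 and included in the mean.
    """
    A = graph.adjacency.astype(float)
    D = graph.degrees().astype(float)
    closed = np.einsum("ij,jk,ki->i", A, A, A)  # 2 * triangles per node
    denom = D * (D - 1)
    C = np.where(denom > 0, np.divide(closed, denom, out=np.zeros_like(closed),
                                      where=denom > 0), 0.0)
    return C, float(C.mean()) if len(C) else 0.0


def characteristic_path_length(graph: BinaryGraph) -> float:
    """Mean shortest hop-count path over all ordered node pairs.

    Requires a connected graph; disconnected input is an error rather than a
    silent substitution of infinity or a harmonic mean.
    """
    if graph.n_nodes < 2:
        raise ValueError("path length needs at least 2 nodes")
    if not graph.is_connected():
        raise ValueError("graph is disconnected; characteristic path length undefined")
    dist = csgraph.shortest_path(csr_matrix(graph.adjacency), method="D",
                                 unweighted=True, directed=False)
    n = graph.n_nodes
    return float(dist.sum() / (n * (n - 1)))


def random_reference(
    graph: BinaryGraph, n_swaps_per_edge: int = 10, seed: int | None = None
) -> BinaryGraph:
    """Degree-preserving randomisation by double-edge swaps (Maslov-Sneppen).

    Repeatedly picks two edges (a,b), (c,d) and rewires to (a,d), (c,b);
    swaps creating self-loops or multi-edges are rejected, so the degree
    sequence is conserved exactly.  If no valid swap can be found the input
    is returned unchanged with a warning.
    """
    rng = np.random.default_rng(seed)
    A = graph.adjacency.copy()
    edges = graph.edge_array()
    m = len(edges)
    if m < 2:
        warnings.warn("fewer than 2 edges; returning the graph unchanged")
        return BinaryGraph(adjacency=A, sparsity=graph.sparsity)
    target = n_swaps_per_edge * m
    max_attempts = 100 * target
    performed = attempts = 0
    while performed < target and attempts < max_attempts:
        attempts += 1
        e1, e2 = rng.integers(0, m, size=2)
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if rng.random() < 0.5:
            c, d = d, c
        # propose (a,b),(c,d) -> (a,d),(c,b)
        if a == d or c == b or A[a, d] or A[c, b]:
            continue
        A[a, b] = A[b, a] = 0
        A[c, d] = A[d, c] = 0
        A[a, d] = A[d, a] = 1
        A[c, b] = A[b, c] = 1
        edges[e1] = sorted((a, d))
        edges[e2] = sorted((c, b))
        performed += 1
    if performed == 0:
        warnings.warn("no valid degree-preserving swap found; graph returned unchanged")
    return BinaryGraph(adjacency=A, sparsity=graph.sparsity)


def normalized_global_metrics(
    graph: BinaryGraph,
    n_random: int = 20,
    n_swaps_per_edge: int = 10,
    seed: int | None = None,
) -> GlobalMetrics:
    """Mean clustering and path length normalised by rewired null networks.

    gamma = C / mean(C_random) and lambda = L / mean(L_random) over
    ``n_random`` seeded degree-preserving references; references that come
    out disconnected are skipped (their path length is undefined).
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    _, C = clustering_coefficients(graph)
    L = characteristic_path_length(graph)
    seeds = np.random.SeedSequence(seed).spawn(n_random)
    c_rand, l_rand = [], []
    for ss in seeds:
        ref = random_reference(graph, n_swaps_per_edge=n_swaps_per_edge,
                               seed=np.random.default_rng(ss))
        if not ref.is_connected():
            continue
        _, c = clustering_coefficients(ref)
        c_rand.append(c)
        l_rand.append(characteristic_path_length(ref))
    if not c_rand:
        raise ValueError("all rewired reference networks were disconnected")
    gamma = C / float(np.mean(c_rand))
    lam = L / float(np.mean(l_rand))
    return GlobalMetrics(clustering=C, path_length=L, gamma=gamma, lam=lam,
                         sigma=gamma / lam, n_random_used=len(c_rand))


# ---------------------------------------------------------------------------
# community structure

def modularity(graph: BinaryGraph | np.ndarray, assignment: np.ndarray) -> float:
    """Newman-Girvan modularity Q = sum_m (l_m/m - (d_m/2m)^2) of a partition."""
    A = graph.adjacency if isinstance(graph, BinaryGraph) else np.asarray(graph)
    assignment = np.asarray(assignment)
    two_m = A.sum()
    if two_m == 0:
        return 0.0
    deg = A.sum(axis=1)
    q = 0.0
    for mod in np.unique(assignment):
        sel = assignment == mod
        l_m = A[np.ix_(sel, sel)].sum() / 2.0
        d_m = deg[sel].sum()
        q += l_m / (two_m / 2.0) - (d_m / two_m) ** 2
    return float(q)


def _leading_eigenpair(Bg: np.ndarray) -> tuple[float, np.ndarray]:
    """Largest eigenvalue/eigenvector of a symmetric matrix.

    Dense eigh for small matrices; Lanczos (eigsh) above that, with a dense
    fallback if the iteration fails to converge.
    """
    n = Bg.shape[0]
    if n >= 128:
        try:
            from scipy.sparse.linalg import eigsh

            vals, vecs = eigsh(Bg, k=1, which="LA", tol=1e-8)
            return float(vals[0]), vecs[:, 0]
        except Exception:
            pass
    vals, vecs = np.linalg.eigh(Bg)
    return float(vals[-1]), vecs[:, -1]


def _fine_tune_split(Bg: np.ndarray, s: np.ndarray, max_passes: int = 100) -> np.ndarray:
    """Kernighan-Lin-style refinement of a bisection vector s in {-1, +1}.

    Each pass moves every node exactly once (greedily, best gain first, gains
    may be negative) and keeps the best intermediate state; passes repeat
    while the objective s' Bg s improves.  The objective of the candidate
    state is recomputed exactly at the end of each pass — incremental gains
    accumulate float round-off, and accepting that noise as improvement
    would cycle forever.
    """
    n = len(s)
    diag = np.diag(Bg)
    s = s.copy()
    q_cur = float(s @ (Bg @ s))
    for _ in range(max_passes):
        s_work = s.copy()
        Bs = Bg @ s_work
        running = q_cur
        best_gain = 0.0
        best_state = None
        moved = np.zeros(n, dtype=bool)
        for _ in range(n):
            gains = -4.0 * s_work * Bs + 4.0 * diag
            gains[moved] = -np.inf
            i = int(np.argmax(gains))
            running += gains[i]
            Bs = Bs - 2.0 * s_work[i] * Bg[:, i]
            s_work[i] = -s_work[i]
            moved[i] = True
            if running - q_cur > best_gain:
                best_gain = running - q_cur
                best_state = s_work.copy()
        if best_state is None:
            return s
        q_new = float(best_state @ (Bg @ best_state))
        if q_new <= q_cur + 1e-9 * max(1.0, abs(q_cur)):
            return s
        s, q_cur = best_state, q_new
    return s


def detect_communities(
    graph: BinaryGraph | ConnectivityMatrix | np.ndarray,
    sparsity: float | None = None,
    fine_tune: bool = True,
    tol: float = 1e-9,
) -> Partition:
    """Newman's spectral modularity maximisation.

    Recursive bisection by the sign of the leading eigenvector of the
    (generalised) modularity matrix, with optional Kernighan-Lin-style node
    moving after each division; division stops when no split increases Q.
    A weighted :class:`ConnectivityMatrix` must be accompanied by a sparsity
    at which it is proportionally thresholded first.

    Module labels are 1..K, ordered by each module's smallest node index.
    """
    if not isinstance(graph, BinaryGraph):
        if sparsity is not None:
            graph = threshold_proportional(graph, sparsity)
        elif isinstance(graph, ConnectivityMatrix):
            raise ValueError("a weighted matrix requires a sparsity for thresholding")
        else:
            graph = BinaryGraph(adjacency=np.asarray(graph))
    A = graph.adjacency.astype(float)
    n = graph.n_nodes
    if n < 1:
        raise ValueError("empty graph")
    deg = A.sum(axis=1)
    two_m = deg.sum()
    if two_m == 0:
        return Partition(assignment=np.ones(n, dtype=int), q=0.0)
    B = A - np.outer(deg, deg) / two_m
    final_groups: list[np.ndarray] = []
    stack: list[np.ndarray] = [np.arange(n)]
    while stack:
        g = stack.pop()
        if len(g) == 1:
            final_groups.append(g)
            continue
        Bg = B[np.ix_(g, g)]
        Bg = Bg - np.diag(Bg.sum(axis=1))  # generalised modularity matrix
        lead_val, lead_vec = _leading_eigenpair(Bg)
        if lead_val <= tol:
            final_groups.append(g)
            continue
        s = np.where(lead_vec >= 0, 1.0, -1.0)
        if fine_tune:
            s = _fine_tune_split(Bg, s)
        delta_q = float(s @ (Bg @ s)) / (2.0 * two_m)
        if delta_q <= tol or np.all(s > 0) or np.all(s < 0):
            final_groups.append(g)
            continue
        stack.append(g[s > 0])
        stack.append(g[s < 0])
    final_groups.sort(key=lambda g: int(g.min()))
    assignment = np.empty(n, dtype=int)
    for label, g in enumerate(final_groups, start=1):
        assignment[g] = label
    return Partition(assignment=assignment, q=modularity(graph, assignment))


def participation_coefficients(graph: BinaryGraph, partition: Partition) -> np.ndarray:
    """Participation coefficient P_i = 1 - sum_m (k_im / D_i)^2.

    0 when all of a node's edges stay in its own module (and for isolated
    nodes), approaching 1 when edges spread evenly across modules.
    """
    if len(partition.assignment) != graph.n_nodes:
        raise ValueError("partition must cover every node")
    A = graph.adjacency
    D = graph.degrees().astype(float)
    modules = np.unique(partition.assignment)
    k_im = np.zeros((graph.n_nodes, len(modules)))
    for col, mod in enumerate(modules):
        k_im[:, col] = A[:, partition.assignment == mod].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(D[:, None] > 0, k_im / D[:, None], 0.0)
    P = 1.0 - (frac**2).sum(axis=1)
    P[D == 0] = 0.0
    return P


def module_summaries(
    node_metrics: pd.DataFrame, partition: Partition
) -> pd.DataFrame:
    """Arithmetic module means of per-node metrics.

    ``node_metrics`` is a tidy table with a ``node`` column (0-based index
    into the partition) plus any numeric metric columns; grouping keys such
    as subject/sparsity columns are preserved.
    """
    df = node_metrics.copy()
    modules = partition.assignment
    present = set(np.unique(modules).tolist())
    if present != set(range(1, max(present) + 1)):
        raise ValueError(f"partition has empty module labels: "
                         f"{sorted(set(range(1, max(present) + 1)) - present)}")
    df["module"] = modules[df["node"].to_numpy()]
    keys = [c for c in ("subject_id", "group", "sparsity") if c in df.columns]
    value_cols = [c for c in df.columns
                  if c not in keys + ["node", "module"] and np.issubdtype(df[c].dtype, np.number)]
    return df.groupby(keys + ["module"], as_index=False)[value_cols].mean()
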