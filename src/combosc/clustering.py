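"""Drug-response-driven clustering of malignant cells.

Instead of fixing the community-detection resolution r by hand, the method
scans a grid of resolutions inside the open interval (T/10000, T/2000) for T
malignant cells and keeps the one maximising

    J(r) = M(r)/10 + sum_i S(i) * cell_number(i) / T

where M(r) is the cluster count, S(i) = 1 iff the cluster's maximum
cell-to-line similarity exceeds alpha, subject to the responses of distinct
clusters diverging:

    sum_k sum_{i>j} (W_ki - W_kj)^2 > eps

which stops the resolution from growing without bound (splitting a cluster
into copies with identical transferred responses gains nothing).  Clusters
whose best similarity stays at or below the ignore threshold contribute
all-zero response columns to W.

Community detection is modularity-based (RBConfiguration Leiden via
python-igraph) on a Jaccard-weighted kNN graph over a PCA embedding, with a
fixed seed for determinism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .config import Config
from .expression import ValidationError
from .transfer import (DrugResponseAssignment, ReferencePanel, assign_response,
                       cell_line_similarity, similarity)


def resolution_bounds(T: int) -> tuple[float, float]:
    """Open interval of admissible resolutions for T malignant cells."""
    if T < 1:
        raise ValidationError("T must be at least 1")
    return (T / 10000.0, T / 2000.0)


def resolution_grid(T: int, n: int = 25) -> np.ndarray:
    """n resolutions strictly inside the open interval (T/10000, T/2000)."""
    low, high = resolution_bounds(T)
    return low + (high - low) * np.arange(1, n + 1) / (n + 1)


def objective_J(M: int, S_indicators, cell_numbers, T: int) -> float:
    """J = M/10 + (cells in similarity-supported clusters)/T."""
    S = np.asarray(S_indicators, dtype=bool)
    sizes = np.asarray(cell_numbers, dtype=float)
    if len(S) != M or len(sizes) != M:
        raise ValidationError(
            f"expected {M} clusters, got {len(S)} indicators and "
            f"{len(sizes)} sizes"
        )
    if sizes.sum() != T:
        raise ValidationError("cluster sizes must sum to T")
    return M / 10.0 + float(sizes[S].sum()) / T


def divergence_constraint(W: np.ndarray, eps: float) -> bool:
    """Whether sum_k sum_{i>j} (W_ki - W_kj)^2 exceeds eps.

    With fewer than two clusters the sum is empty (0), so the constraint can
    only hold for negative eps.
    """
    W = np.atleast_2d(np.asarray(W, dtype=float))
    M = W.shape[1]
    if M < 2:
        return 0.0 > eps
    # per drug row w: sum_{i<j}(w_i - w_j)^2 = M*sum(w^2) - (sum w)^2
    total = float((M * (W ** 2).sum(axis=1) - W.sum(axis=1) ** 2).sum())
    return total > eps


def build_knn_graph(norm: np.ndarray, n_pcs: int = 50, k: int = 20,
                    seed: int = 0) -> ig.Graph:
    """Jaccard-weighted shared-nearest-neighbor graph on a PCA embedding."""
    X = np.asarray(norm, dtype=float)
    n = X.shape[0]
    n_pcs = min(n_pcs, n - 1, X.shape[1])
    if n_pcs >= 1:
        X = PCA(n_components=n_pcs, svd_solver="full",
                random_state=seed).fit_transform(X)
    k = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k).fit(X)
    A = nn.kneighbors_graph(X, mode="connectivity")
    shared = A @ A.T
    union = sparse.triu(((A + A.T) > 0).astype(np.int8), k=1).tocoo()
    s = np.asarray(shared[union.row, union.col]).ravel()
    jac = s / (2 * k - s)
    keep = jac > 0
    g = ig.Graph(n=n, edges=list(zip(union.row[keep], union.col[keep])))
    g.es["weight"] = jac[keep].tolist()
    return g


def run_leiden(graph: ig.Graph, resolution: float, seed: int = 0) -> np.ndarray:
    """Modularity community detection at a given resolution, relabelled by size."""
    part = leidenalg.find_partition(
        graph, leidenalg.RBConfigurationVertexPartition,
        weights="weight", resolution_parameter=float(resolution),
        seed=int(seed), n_iterations=2,
    )
    labels = np.asarray(part.membership)
    # stable relabel: clusters ordered by size desc then first occurrence
    ids, counts = np.unique(labels, return_counts=True)
    first = np.array([np.argmax(labels == i) for i in ids])
    order = ids[np.lexsort((first, -counts))]
    remap = {old: new for new, old in enumerate(order)}
    return np.array([remap[v] for v in labels])


@dataclass
class ClusteringProblem:
    cells_norm: pd.DataFrame  # malignant cells x genes, normalised
    panel: ReferencePanel
    alpha: float = 0.4
    eps: float = 1.0
    resolution_grid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.cells_norm) == 0:
            raise ValidationError("no malignant cells provided")
        low, high = resolution_bounds(self.T)
        if self.resolution_grid is None:
            self.resolution_grid = resolution_grid(self.T)
        grid = np.asarray(self.resolution_grid, dtype=float)
        if grid.size == 0 or grid.min() <= low or grid.max() >= high:
            raise ValidationError(
                f"resolution grid must lie strictly inside ({low:g}, {high:g})"
            )
        self.resolution_grid = grid

    @property
    def T(self) -> int:
        return len(self.cells_norm)


@dataclass
class ClusteringResult:
    r_star: float
    labels: np.ndarray
    M: int
    J_trace: pd.DataFrame  # columns r, J, M, divergence, feasible
    W: pd.DataFrame  # drugs x clusters
    S_indicators: np.ndarray
    sims: np.ndarray  # per-cluster max cell-line similarity
    cell_numbers: np.ndarray
    assignments: list[DrugResponseAssignment] = field(default_factory=list)


def _evaluate_labels(labels: np.ndarray, problem: ClusteringProblem,
                     cell_sims: pd.DataFrame, cfg: Config):
    """Per-cluster similarity, W columns and assignments for fixed labels."""
    M = int(labels.max()) + 1
    sizes = np.bincount(labels, minlength=M)
    sims = np.array([
        float(cell_sims.to_numpy()[labels == i].max()) for i in range(M)
    ])
    S = sims > problem.alpha
    drugs = problem.panel.drug_ids
    W = np.zeros((len(drugs), M))
    assignments = []
    norm = problem.cells_norm
    for i in range(M):
        prof = norm.loc[labels == i].median(axis=0)
        prof = prof[[g for g in problem.panel.gene_ids if g in prof.index]]
        simvec = similarity(prof, problem.panel,
                            n_features=cfg.n_similarity_features)
        asg = assign_response(simvec, problem.panel, cfg, cluster_id=i)
        assignments.append(asg)
        if asg.response is not None:
            W[:, i] = asg.response.to_numpy(dtype=float)
    return M, sizes, sims, S, W, assignments


def optimize_resolution(problem: ClusteringProblem,
                        graph: ig.Graph | None = None,
                        seed: int = 0,
                        cfg: Config | None = None) -> ClusteringResult:
    """Scan the resolution grid and return the clustering maximising J.

    Feasibility at each r is the response-divergence constraint; the best
    feasible r wins (ties go to the smallest r).  If no grid point is
    feasible, the point nearest the interval midpoint is returned with a
    warning.
    """
    cfg = cfg or Config()
    if problem.T < 2:
        raise ValidationError("need at least 2 malignant cells to cluster")
    if graph is None:
        graph = build_knn_graph(problem.cells_norm.to_numpy(dtype=float),
                                n_pcs=cfg.n_pcs, k=cfg.knn_neighbors,
                                seed=seed)
    cell_sims = cell_line_similarity(problem.cells_norm, problem.panel,
                                     n_features=cfg.n_similarity_features)
    rows, evaluations = [], {}
    for r in problem.resolution_grid:
        labels = run_leiden(graph, r, seed=seed)
        M, sizes, sims, S, W, assignments = _evaluate_labels(
            labels, problem, cell_sims, cfg
        )
        J = objective_J(M, S, sizes, problem.T)
        div = divergence_constraint(W, problem.eps)
        rows.append({"r": float(r), "J": J, "M": M,
                     "feasible": bool(div)})
        evaluations[float(r)] = (labels, M, sizes, sims, S, W, assignments)
    trace = pd.DataFrame(rows)
    feasible = trace[trace["feasible"]]
    if len(feasible):
        best_J = feasible["J"].max()
        r_star = float(feasible.loc[feasible["J"] == best_J, "r"].min())
    else:
        low, high = resolution_bounds(problem.T)
        mid = (low + high) / 2.0
        r_star = float(trace.loc[(trace["r"] - mid).abs().idxmin(), "r"])
        warnings.warn(
            "no resolution satisfies the response-divergence constraint; "
            f"falling back to the grid point nearest the midpoint (r={r_star:g})"
        )
    labels, M, sizes, sims, S, W, assignments = evaluations[r_star]
    return ClusteringResult(
        r_star=r_star, labels=labels, M=M, J_trace=trace,
        W=pd.DataFrame(W, index=problem.panel.drug_ids,
                       columns=range(M)),
        S_indicators=S, sims=sims, cell_numbers=sizes,
        assignments=assignments,
    )
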