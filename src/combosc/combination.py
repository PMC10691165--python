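"""Bipartite drug / cell-group combination optimization.

Cell groups (malignant clusters, or exhaustion trajectories for
middle-immune samples) form one side of a bipartite graph and candidate
drugs the other; edges carry the transferred sensitivity W_ij in [0, 1].
Each group j is weighted by

    C_j = t_j / T + V_j / (M * T)

combining its current size t_j with its RNA-velocity net inflow V_j (a
positive V_j marks a group expected to grow and raises its weight).  A
selection S of at most two drugs is scored by

    J(S) = sum_{i in S} [ sum_j C_j W_ij (1 - lambda * eps_i) + 10 R_i / T ]

where R_i counts cells in groups whose sensitivity to drug i exceeds the
respond threshold, and eps_i is a binary toxicity flag: 1 when the drug has
more than ten side effects reported at frequency above 30%.  The
cardinality bound makes exhaustive enumeration of singletons and pairs
exact and quadratic in the number of drugs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ValidationError

SIDE_EFFECT_MIN_COUNT = 10   # strictly more than this many effects ...
SIDE_EFFECT_FREQUENCY = 0.30  # ... each at frequency strictly above this


def cluster_weight(t_j: int, V_j: float, M: int, T: int) -> float:
    """C_j = t_j/T + V_j/(M*T); negative net outflow lowers the weight."""
    if T <= 0 or M <= 0:
        raise ValidationError("T and M must be positive")
    return t_j / T + V_j / (M * T)


def side_effect_indicator(table: pd.DataFrame | None, drug: str) -> int:
    """1 iff the drug has more than ten side effects above 30% frequency.

    Drugs absent from the table (or a missing table) get 0: no reported
    evidence, no penalty.
    """
    if table is None or len(table) == 0:
        return 0
    for col in ("drug", "frequency"):
        if col not in table.columns:
            raise ValidationError(f"side-effect table missing column {col!r}")
    freqs = table.loc[table["drug"] == drug, "frequency"].to_numpy(dtype=float)
    if len(freqs) and (freqs.min() < 0 or freqs.max() > 1):
        raise ValidationError("side-effect frequencies must lie in [0, 1]")
    return int((freqs > SIDE_EFFECT_FREQUENCY).sum() > SIDE_EFFECT_MIN_COUNT)


def read_side_effects(path: str | Path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t")
    missing = [c for c in ("drug", "effect", "frequency")
               if c not in tab.columns]
    if missing:
        raise ValidationError(f"side-effect table missing columns {missing}")
    return tab


@dataclass
class BipartiteProblem:
    drug_ids: list[str]
    cluster_ids: list
    T: int
    t: np.ndarray            # per-cluster cell counts
    W: np.ndarray            # N drugs x M clusters, in [0, 1]
    V: np.ndarray | None = None  # per-cluster velocity net flow, default 0
    epsilon: np.ndarray | None = None  # per-drug toxicity indicator
    lam: float = 0.1
    respond_threshold: float = 0.5
    max_combo_size: int = 2

    def __post_init__(self) -> None:
        self.drug_ids = [str(d) for d in self.drug_ids]
        self.t = np.asarray(self.t, dtype=float)
        self.W = np.atleast_2d(np.asarray(self.W, dtype=float))
        N, M = self.W.shape
        if N != len(self.drug_ids) or M != len(self.cluster_ids):
            raise ValidationError(
                f"W shape {self.W.shape} does not match {len(self.drug_ids)} "
                f"drugs x {len(self.cluster_ids)} clusters"
            )
        if len(self.t) != M:
            raise ValidationError("t must have one entry per cluster")
        if self.t.sum() != self.T:
            raise ValidationError("cluster cell counts must sum to T")
        if not np.all(np.isfinite(self.W)) or self.W.min() < 0 or self.W.max() > 1:
            raise ValidationError("W must be finite and lie in [0, 1]")
        self.V = (np.zeros(M) if self.V is None
                  else np.asarray(self.V, dtype=float))
        if len(self.V) != M:
            raise ValidationError("V must have one entry per cluster")
        self.epsilon = (np.zeros(N, dtype=int) if self.epsilon is None
                        else np.asarray(self.epsilon, dtype=int))
        if len(self.epsilon) != N:
            raise ValidationError("epsilon must have one entry per drug")
        if not set(np.unique(self.epsilon)) <= {0, 1}:
            raise ValidationError("epsilon entries must be 0 or 1")
        if self.lam < 0:
            raise ValidationError("lambda must be non-negative")
        if not 0 < self.respond_threshold < 1:
            raise ValidationError("respond_threshold must lie in (0, 1)")

    @property
    def N(self) -> int:
        return self.W.shape[0]

    @property
    def M(self) -> int:
        return self.W.shape[1]

    def cluster_weights(self) -> np.ndarray:
        return np.array([
            cluster_weight(self.t[j], self.V[j], self.M, self.T)
            for j in range(self.M)
        ])


def from_response_matrix(W: pd.DataFrame, t, T: int | None = None,
                         V=None, side_effects: pd.DataFrame | None = None,
                         lam: float = 0.1,
                         respond_threshold: float = 0.5) -> BipartiteProblem:
    """Build a problem from a drugs x clusters response DataFrame."""
    t = np.asarray(t, dtype=float)
    T = int(t.sum()) if T is None else T
    eps = np.array([side_effect_indicator(side_effects, d)
                    for d in W.index])
    return BipartiteProblem(
        drug_ids=list(W.index), cluster_ids=list(W.columns), T=T, t=t,
        W=W.to_numpy(dtype=float), V=V, epsilon=eps, lam=lam,
        respond_threshold=respond_threshold,
    )


def responsive_cells(problem: BipartiteProblem, drug_index: int) -> int:
    """R_i: cells in clusters whose W_ij strictly exceeds the threshold."""
    responding = problem.W[drug_index] > problem.respond_threshold
    return int(problem.t[responding].sum())


def objective(problem: BipartiteProblem, selected) -> float:
    """J over a selected drug-index set (restricted to selected drugs)."""
    selected = tuple(selected)
    if len(selected) > problem.max_combo_size:
        raise ValidationError(
            f"selection exceeds max combination size {problem.max_combo_size}"
        )
    C = problem.cluster_weights()
    J = 0.0
    for i in selected:
        J += float(C @ problem.W[i]) * (1.0 - problem.lam * problem.epsilon[i])
        J += 10.0 * responsive_cells(problem, i) / problem.T
    return J


@dataclass
class CombinationSolution:
    selected: list[str]
    J: float
    per_drug_R: dict[str, int]
    coverage_fraction: float
    ranking: pd.DataFrame  # rank, drug_1, drug_2, J, coverage_fraction


def _coverage(problem: BipartiteProblem, selected) -> float:
    """Fraction of cells in clusters responsive to at least one selected drug."""
    if not selected:
        return 0.0
    mask = np.zeros(problem.M, dtype=bool)
    for i in selected:
        mask |= problem.W[i] > problem.respond_threshold
    return float(problem.t[mask].sum() / problem.T)


def solve(problem: BipartiteProblem) -> CombinationSolution:
    """Exhaustive search over all singletons and unordered pairs.

    Candidates are ranked by J descending; ties break lexicographically on
    the sorted drug-id tuple.  O(N^2 * M).
    """
    if problem.N < 1:
        raise ValidationError("no drugs to select from")
    idx = range(problem.N)
    candidates = [(i,) for i in idx]
    if problem.max_combo_size >= 2:
        candidates += list(combinations(idx, 2))
    rows = []
    for sel in candidates:
        ids = tuple(sorted(problem.drug_ids[i] for i in sel))
        rows.append({
            "drugs": ids,
            "indices": sel,
            "J": objective(problem, sel),
            "coverage_fraction": _coverage(problem, sel),
        })
    rows.sort(key=lambda r: (-r["J"], r["drugs"]))
    best = rows[0]
    ranking = pd.DataFrame({
        "rank": np.arange(1, len(rows) + 1),
        "drug_1": [r["drugs"][0] for r in rows],
        "drug_2": [r["drugs"][1] if len(r["drugs"]) > 1 else "" for r in rows],
        "J": [r["J"] for r in rows],
        "coverage_fraction": [r["coverage_fraction"] for r in rows],
    })
    return CombinationSolution(
        selected=list(best["drugs"]),
        J=float(best["J"]),
        per_drug_R={problem.drug_ids[i]: responsive_cells(problem, i)
                    for i in best["indices"]},
        coverage_fraction=float(best["coverage_fraction"]),
        ranking=ranking,
    )
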