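"""Immune-exhaustion trajectories and perturbation-signature reversal.

For samples with a middle immune score the method targets four recurrent
exhaustion transitions of the tumor microenvironment — active T cell
exhaustion, memory T cell exhaustion, tumor-associated macrophage (TAM)
differentiation and cancer-associated fibroblast (CAF) differentiation —
each defined by a start and an end cell-type label.  A trajectory "exists"
in a sample when both endpoints have at least ``min_cells`` cells; its score
is n_end / n_start, and NA otherwise.

The differential signature of an existing trajectory (end vs start,
two-sided Wilcoxon rank-sum, raw p < 1e-5 and fold change > 2) is then
queried against a drug perturbation signature library in reversal mode:
drugs whose signed signature opposes the exhaustion signature score high
(cosine of the query against the negated drug signature on shared genes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix, ValidationError

DEG_P_THRESHOLD = 1e-5
DEG_FC_THRESHOLD = 2.0

TRAJECTORY_NAMES = ("active_t_exhaustion", "memory_t_exhaustion",
                    "tam_differentiation", "caf_differentiation")


@dataclass(frozen=True)
class TrajectoryDef:
    name: str
    start_label: str
    end_label: str

    def __post_init__(self) -> None:
        if self.start_label == self.end_label:
            raise ValidationError(
                f"trajectory {self.name!r}: start and end labels coincide"
            )


DEFAULT_TRAJECTORIES = (
    TrajectoryDef("active_t_exhaustion", "T_active", "T_exhausted"),
    TrajectoryDef("memory_t_exhaustion", "T_memory", "T_exhausted"),
    TrajectoryDef("tam_differentiation", "Macrophage", "TAM"),
    TrajectoryDef("caf_differentiation", "Fibroblast", "CAF"),
)


@dataclass
class SignatureLibrary:
    """Drugs x genes signed perturbation signatures (+ up-, - down-regulated)."""

    signatures: pd.DataFrame

    def __post_init__(self) -> None:
        self.signatures = self.signatures.fillna(0.0).astype(float)
        self.signatures.columns = [str(g).upper()
                                   for g in self.signatures.columns]
        if self.signatures.index.duplicated().any():
            raise ValidationError("duplicate drug ids in signature library")
        empty = self.signatures.index[
            (self.signatures != 0).sum(axis=1) == 0
        ]
        if len(empty):
            raise ValidationError(
                f"drugs with empty signatures: {list(empty)[:5]}"
            )

    @property
    def drug_ids(self) -> list[str]:
        return list(self.signatures.index)


def read_signature_library(path: str | Path) -> SignatureLibrary:
    """Read a long-format TSV (drug, gene, weight)."""
    tab = pd.read_csv(path, sep="\t")
    for col in ("drug", "gene", "weight"):
        if col not in tab.columns:
            raise ValidationError(f"signature table is missing column {col!r}")
    wide = tab.pivot_table(index="drug", columns="gene", values="weight",
                           fill_value=0.0, aggfunc="sum")
    return SignatureLibrary(signatures=wide)


def write_signature_library(lib: SignatureLibrary, path: str | Path) -> None:
    long = lib.signatures.stack().rename_axis(["drug", "gene"]) \
        .reset_index(name="weight")
    long = long[long["weight"] != 0]
    long.to_csv(path, sep="\t", index=False)


def trajectory_score(meta: pd.DataFrame, td: TrajectoryDef,
                     min_cells: int = 10) -> float:
    """n_end / n_start when both endpoints have >= min_cells cells, else NaN."""
    n_start = int((meta["cell_type"] == td.start_label).sum())
    n_end = int((meta["cell_type"] == td.end_label).sum())
    if n_start < min_cells or n_end < min_cells:
        return float("nan")
    return n_end / n_start


def trajectory_degs(m: ExpressionMatrix, meta: pd.DataFrame,
                    td: TrajectoryDef,
                    p_threshold: float = DEG_P_THRESHOLD,
                    fc_threshold: float = DEG_FC_THRESHOLD) -> pd.DataFrame:
    """Differential genes between trajectory end and start cells.

    Two-sided Wilcoxon rank-sum per gene on normalised values, BH-adjusted p
    reported alongside; the signature keeps genes with raw p below
    ``p_threshold`` and fold change above ``fc_threshold`` in either
    direction.  Fold change is computed on de-logged mean expression with a
    pseudocount of 1; direction is the sign of the change end vs start.
    """
    norm = m.norm_frame()
    idx = meta[meta["cell_id"].isin(set(m.cell_ids))].set_index("cell_id")
    start_cells = idx.index[idx["cell_type"] == td.start_label]
    end_cells = idx.index[idx["cell_type"] == td.end_label]
    if len(start_cells) < 3 or len(end_cells) < 3:
        raise ValidationError(
            f"trajectory {td.name!r} needs at least 3 cells per endpoint "
            f"(got {len(start_cells)} start, {len(end_cells)} end)"
        )
    start = norm.loc[list(start_cells)].to_numpy(dtype=float)
    end = norm.loc[list(end_cells)].to_numpy(dtype=float)
    res = stats.mannwhitneyu(end, start, axis=0, alternative="two-sided",
                             method="asymptotic")
    p = np.asarray(res.pvalue, dtype=float)
    p = np.nan_to_num(p, nan=1.0)
    adj_p = multipletests(p, method="fdr_bh")[1]
    lin_end = np.expm1(end * np.log(2)).mean(axis=0)  # undo log2
    lin_start = np.expm1(start * np.log(2)).mean(axis=0)
    fc = (lin_end + 1.0) / (lin_start + 1.0)
    log2fc = np.log2(fc)
    out = pd.DataFrame({
        "gene": norm.columns,
        "log2fc": log2fc,
        "p": p,
        "adj_p": adj_p,
        "direction": np.sign(log2fc).astype(int),
    })
    keep = (out["p"] < p_threshold) & (
        np.maximum(fc, 1.0 / fc) > fc_threshold
    )
    return out[keep].reset_index(drop=True)


def reversal_score(degs: pd.DataFrame, lib: SignatureLibrary,
                   drug: str) -> float:
    """Cosine of the query signature against the negated drug signature.

    The query assigns +1 to trajectory-up genes and -1 to down genes; scoring
    is restricted to genes shared with the drug's signature.  +1 is perfect
    reversal, -1 perfect mimicry, 0 no relation (or no overlap).
    """
    if drug not in lib.signatures.index:
        raise ValidationError(f"drug {drug!r} not in signature library")
    sig = lib.signatures.loc[drug]
    sig = sig[sig != 0]
    if sig.empty:
        raise ValidationError(f"drug {drug!r} has an empty signature")
    q = pd.Series(degs["direction"].to_numpy(dtype=float),
                  index=[str(g).upper() for g in degs["gene"]])
    shared = [g for g in q.index if g in set(sig.index)]
    if not shared:
        warnings.warn(f"no overlap between query genes and {drug!r} "
                      "signature; score set to 0")
        return 0.0
    qv = q[shared].to_numpy(dtype=float)
    sv = -sig[shared].to_numpy(dtype=float)
    denom = np.linalg.norm(qv) * np.linalg.norm(sv)
    if denom == 0:
        return 0.0
    return float(qv @ sv / denom)


@dataclass
class TrajectoryResult:
    name: str
    score: float  # NaN encodes NA
    n_start: int
    n_end: int
    degs: pd.DataFrame | None = None

    @property
    def exists(self) -> bool:
        return np.isfinite(self.score)


def analyze_trajectories(m: ExpressionMatrix, meta: pd.DataFrame,
                         trajectories=DEFAULT_TRAJECTORIES,
                         min_cells: int = 10) -> list[TrajectoryResult]:
    """Score each trajectory and extract DEGs for the ones that exist."""
    out = []
    for td in trajectories:
        n_start = int((meta["cell_type"] == td.start_label).sum())
        n_end = int((meta["cell_type"] == td.end_label).sum())
        score = trajectory_score(meta, td, min_cells=min_cells)
        degs = None
        if np.isfinite(score):
            degs = trajectory_degs(m, meta, td)
        out.append(TrajectoryResult(td.name, score, n_start, n_end, degs))
    return out


def trajectory_drug_matrix(results: list[TrajectoryResult],
                           lib: SignatureLibrary) -> pd.DataFrame:
    """Drugs x trajectories reversal scores mapped to [0, 1].

    NA trajectories are dropped; scores are shifted as (cosine + 1) / 2 so
    that they live on the same bounded sensitivity scale as cell-line
    transferred responses.
    """
    live = [r for r in results if r.exists]
    if not live:
        raise ValidationError(
            "every trajectory is NA; use the malignant-cluster pathway instead"
        )
    cols = {}
    for r in live:
        cols[r.name] = [
            (reversal_score(r.degs, lib, drug) + 1.0) / 2.0
            for drug in lib.drug_ids
        ]
    return pd.DataFrame(cols, index=lib.drug_ids)
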