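"""Projection of malignant cell clusters onto a reference cell-line panel.

A cluster is represented by the per-gene median of its normalised profiles
and compared with each reference line by a consensus kernel: the mean of
cosine similarity and Spearman rank correlation over the most variable panel
genes (unsupervised feature selection).  Sensitivities are then transferred
by tiered rules on the best similarity: above 0.8 the best line's response
vector is copied directly; between 0.4 and 0.8 a similarity-weighted average
of the top-k lines is used; at or below 0.4 the cluster is ignored (no
reference support).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .config import Config
from .expression import ExpressionMatrix, ValidationError

DIRECT_THRESHOLD = 0.8
IGNORE_THRESHOLD = 0.4


@dataclass
class ReferencePanel:
    """Cell-line expression profiles with matched drug sensitivities.

    ``profiles``: lines x genes log-normalised expression.
    ``sensitivity``: lines x drugs reals in [0, 1], higher = more sensitive.
    """

    profiles: pd.DataFrame
    sensitivity: pd.DataFrame

    def __post_init__(self) -> None:
        self.profiles = self.profiles.copy()
        self.profiles.columns = [str(g).upper() for g in self.profiles.columns]
        if self.profiles.index.duplicated().any():
            raise ValidationError("duplicate cell-line ids in profiles")
        if pd.Index(self.profiles.columns).duplicated().any():
            raise ValidationError("duplicate gene ids in profiles")
        if self.sensitivity.index.duplicated().any():
            raise ValidationError("duplicate cell-line ids in sensitivity")
        if self.sensitivity.columns.duplicated().any():
            raise ValidationError("duplicate drug ids in sensitivity")
        missing = set(self.profiles.index) ^ set(self.sensitivity.index)
        if missing:
            raise ValidationError(
                f"profiles and sensitivity disagree on lines: {sorted(missing)[:5]}"
            )
        self.sensitivity = self.sensitivity.loc[self.profiles.index]
        vals = self.sensitivity.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValidationError("sensitivity values must be finite")
        if vals.min() < 0 or vals.max() > 1:
            raise ValidationError("sensitivity values must lie in [0, 1]")

    @property
    def line_ids(self) -> list[str]:
        return list(self.profiles.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.profiles.columns)

    @property
    def drug_ids(self) -> list[str]:
        return list(self.sensitivity.columns)


def sensitivity_from_ic50(ic50: pd.DataFrame) -> pd.DataFrame:
    """Map raw ln(IC50) values to [0, 1] sensitivities.

    Per drug, sensitivity = 1 - rank-normalised ln(IC50) across lines
    (lower IC50 = more sensitive), clipped to [0, 1].
    """
    out = {}
    for drug in ic50.columns:
        v = ic50[drug].to_numpy(dtype=float)
        if len(v) == 1:
            out[drug] = np.array([0.5])
            continue
        r = rankdata(v, method="average")
        out[drug] = 1.0 - (r - 1.0) / (len(v) - 1.0)
    return pd.DataFrame(out, index=ic50.index).clip(0.0, 1.0)


def read_panel(profiles_path: str | Path, sensitivity_path: str | Path,
               ic50: bool = False) -> ReferencePanel:
    """Read a panel from two TSVs (lines x genes, lines x drugs)."""
    prof = pd.read_csv(profiles_path, sep="\t", index_col=0)
    sens = pd.read_csv(sensitivity_path, sep="\t", index_col=0)
    if ic50:
        sens = sensitivity_from_ic50(sens)
    return ReferencePanel(profiles=prof, sensitivity=sens)


def select_features(panel: ReferencePanel, n_features: int) -> list[str]:
    """The n_features genes most variable across panel lines (ties by name)."""
    var = panel.profiles.var(axis=0, ddof=0)
    order = var.sort_values(ascending=False, kind="stable")
    return list(order.index[:n_features])


def _shared_genes(gene_ids, panel: ReferencePanel) -> list[str]:
    shared = [g for g in panel.gene_ids if g in set(map(str, gene_ids))]
    if not shared:
        raise ValidationError(
            f"no genes shared between query ({len(gene_ids)} genes) and "
            f"panel ({len(panel.gene_ids)} genes)"
        )
    return shared


def cluster_profile(m: ExpressionMatrix, meta: pd.DataFrame,
                    cluster_id: int, panel: ReferencePanel) -> pd.Series:
    """Per-gene median normalised expression of one cluster, on shared genes.

    Even-sized clusters use the midpoint of the two central values.
    """
    norm = m.norm_frame()
    cells = meta.loc[meta["cluster"] == cluster_id, "cell_id"]
    if len(cells) == 0:
        raise ValidationError(f"cluster {cluster_id} is empty")
    shared = _shared_genes(m.gene_ids, panel)
    return norm.loc[list(cells), shared].median(axis=0)


def similarity_kernel(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pairwise mean of cosine similarity and Spearman correlation.

    X: queries x features, Y: lines x features.  Rows with zero norm or zero
    rank variance contribute 0 for the affected component.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))

    def _unit(a: np.ndarray) -> np.ndarray:
        n = np.linalg.norm(a, axis=1, keepdims=True)
        return np.divide(a, n, out=np.zeros_like(a), where=n > 0)

    cos = _unit(X) @ _unit(Y).T

    def _rank_center(a: np.ndarray) -> np.ndarray:
        r = np.apply_along_axis(rankdata, 1, a)
        r -= r.mean(axis=1, keepdims=True)
        return _unit(r)

    spear = _rank_center(X) @ _rank_center(Y).T
    return (cos + spear) / 2.0


def similarity(profile: pd.Series, panel: ReferencePanel,
               n_features: int | None = None) -> pd.Series:
    """Consensus similarity of one profile to every panel line."""
    shared = _shared_genes(profile.index, panel)
    feats = [g for g in select_features(panel, n_features or len(shared))
             if g in set(shared)]
    if not feats:
        raise ValidationError("feature selection left no shared genes")
    x = profile[feats].to_numpy(dtype=float)[None, :]
    if np.ptp(x) == 0:
        warnings.warn("query profile has zero variance on selected features; "
                      "similarity set to 0 for every line")
        return pd.Series(0.0, index=panel.line_ids)
    sims = similarity_kernel(x, panel.profiles[feats].to_numpy(dtype=float))
    return pd.Series(sims.ravel(), index=panel.line_ids)


def cell_line_similarity(cells_norm: pd.DataFrame, panel: ReferencePanel,
                         n_features: int | None = None) -> pd.DataFrame:
    """Similarity of every cell to every panel line (shared-gene kernel)."""
    shared = _shared_genes(cells_norm.columns, panel)
    feats = [g for g in select_features(panel, n_features or len(shared))
             if g in set(shared)]
    if not feats:
        raise ValidationError("feature selection left no shared genes")
    sims = similarity_kernel(cells_norm[feats].to_numpy(dtype=float),
                             panel.profiles[feats].to_numpy(dtype=float))
    return pd.DataFrame(sims, index=cells_norm.index, columns=panel.line_ids)


def max_cell_similarity(cells_norm: pd.DataFrame, panel: ReferencePanel,
                        n_features: int | None = None) -> float:
    """Maximum similarity over all (cell, line) pairs of one cluster."""
    if len(cells_norm) == 0:
        raise ValidationError("cluster is empty")
    return float(cell_line_similarity(cells_norm, panel, n_features)
                 .to_numpy().max())


@dataclass
class DrugResponseAssignment:
    cluster_id: int
    best_line: str
    best_similarity: float
    tier: str  # direct | refined | ignored
    response: pd.Series | None = None


def assign_response(sims: pd.Series, panel: ReferencePanel,
                    cfg: Config | None = None,
                    cluster_id: int = -1) -> DrugResponseAssignment:
    """Tiered sensitivity transfer from the similarity vector.

    best > 0.8: copy the best line's responses (direct).
    0.4 < best <= 0.8: similarity-weighted mean of the top-k lines (refined).
    best <= 0.4: no transferable response (ignored).
    """
    cfg = cfg or Config()
    best_line = str(sims.sort_index().idxmax())  # ties by line id
    best = float(sims[best_line])
    if best > DIRECT_THRESHOLD:
        return DrugResponseAssignment(
            cluster_id, best_line, best, "direct",
            response=panel.sensitivity.loc[best_line].copy(),
        )
    if best > IGNORE_THRESHOLD:
        top = sims.sort_values(ascending=False, kind="stable").head(
            cfg.refine_top_k
        )
        w = np.clip(top.to_numpy(dtype=float), 0.0, None)
        w = w / w.sum()
        resp = pd.Series(
            w @ panel.sensitivity.loc[top.index].to_numpy(dtype=float),
            index=panel.drug_ids,
        )
        return DrugResponseAssignment(cluster_id, best_line, best, "refined",
                                      response=resp)
    return DrugResponseAssignment(cluster_id, best_line, best, "ignored")
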